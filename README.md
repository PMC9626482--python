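# plasmadose

Dose-rate assessment for low-temperature plasma (LTP). The package builds a
physics-guided predictive model of plasma-induced DNA damage from a
design-of-experiments (DoE) table, inverts it to find the irradiation time at
which LTP matches a given damage level, converts dose–DNA-damage
correlations into LTP dose rates (`dose_rate = dose / t_irr`), clusters the
rates, and compares the lowest-rate cluster against configured reference
dose rates.

Because the original experimental tables are not public, a first-class
synthetic-data module generates seeded stand-ins with the same statistical
structure (saturating monotone damage kinetics; between-study heterogeneity
in damage-per-Gy sensitivity). All reference dose rates shipped in default
configs are clearly-labeled placeholders, never literature values.

## Layout

| module | purpose |
| --- | --- |
| `plasmadose.synthetic_data` | seeded DoE tables and dose–damage databases, CSV I/O |
| `plasmadose.damage_model` | train/test split, minority-region SMOTE, physics-guided network (numpy MLP + monotonicity hinge), baseline regressors, leakage-safe grid-search CV, metrics, consistency audit |
| `plasmadose.itf` | irradiation-time finder: bracket + bisection inversion of a predictor |
| `plasmadose.dose_rate` | dose-rate extraction, 1-D K-means, Tukey outlier treatment, cluster summaries |
| `plasmadose.comparison` | (voltage, frequency) sweeps of lowest-cluster centroids, deviation grids, reference comparison |
| `plasmadose.pipeline` | end-to-end orchestration with per-stage seeds and a checksummed manifest |

## CLI

```bash
plasmadose simulate --seed 1 --doe-out doe.csv --db-out db.csv
plasmadose train    --doe doe.csv --algorithm pgnn --out predictor.json
plasmadose audit    --predictor predictor.json
plasmadose itf      --predictor predictor.json --voltage 8 --frequency 1 --flow 2 --target 18.1
plasmadose extract  --predictor predictor.json --db db.csv --k 4
plasmadose sweep    --predictor predictor.json --db db.csv --radiation-type gamma
plasmadose compare  --predictor predictor.json --db db.csv --references refs.yaml
plasmadose run      --config run.yaml
```

`run.yaml` nests the per-stage settings (all optional; defaults shown in
`plasmadose.pipeline.RunConfig`):

```yaml
seed: 1
outdir: runs/demo
levels: {voltages: [7, 8, 9, 10, 11], frequencies: [0.5, 1, 2, 3, 4], flows: [1, 2, 3], times: [5, 10, 20, 30, 40, 60]}
model: {algorithm: pgnn, epochs: 2000, phys_weight: 1000.0}
references: {gamma: 0.02, xray: 0.05, proton: 0.2, ion: 0.5}   # supply real values
```

A run writes `doe.csv`, `dose_damage_db.csv`, `predictor.json`,
`fit_result.json`, `consistency_report.json`, per-type estimate/sweep/
deviation CSVs, `cluster_summary.json`, `comparison.json` and a
`manifest.json` with SHA-256 checksums; reruns with the same config and seed
reproduce every checksum.

## Notes on the predictor

The physics-guided network is a 3×50 tanh MLP trained with Adam on
`MSE + λ · PHYLOSS`, where PHYLOSS is a mean hinge penalty on every
consecutive-time decrease of the prediction over a collocation set of
unlabeled operating points (random anchors plus the corners of the feature
box). The hinge is inactive wherever the prediction is already
non-decreasing, so a large default λ (1000) enforces monotonicity without
hurting accuracy. Inputs are z-scored and predictions clipped to [0, 100] at
the public boundary only.
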