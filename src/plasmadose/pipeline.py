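"""End-to-end orchestration: simulate -> train -> audit -> extract -> sweep -> compare.

One YAML config drives the whole run.  A single global seed fans out to
per-stage seeds through a stable stage-name hash, so each stage is
independently reproducible; every artifact lands in the output directory
and is listed with its SHA-256 in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .comparison import (
    comparison_summary,
    parameter_sweep,
    plot_deviation_heatmap,
    relative_deviation_grid,
    write_sweep_csv,
)
from .damage_model import (
    CollocationSpec,
    MinorityRegionSpec,
    ModelConfig,
    check_physical_consistency,
    evaluate_model,
    fit_model,
    grid_search_cv,
    split_data,
    train_pgnn,
)
from .dose_rate import cluster_estimates, extract_dose_rates, write_estimates_csv
from .errors import ConfigurationError
from .itf import InversionSettings
from .synthetic_data import (
    DoELevels,
    KineticsConfig,
    LiteratureDBConfig,
    generate_doe_dataset,
    generate_literature_db,
    write_db_csv,
    write_doe_csv,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_config"]

log = logging.getLogger("plasmadose")

STAGES = ("simulate", "train", "audit", "extract", "sweep", "compare")

# placeholder reference dose rates (Gy/s) — NOT literature values; users
# must supply real references for any scientific comparison
PLACEHOLDER_REFERENCES = {"gamma": 0.02, "xray": 0.05, "proton": 0.2, "ion": 0.5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32("<stage>:<seed>")."""
    return zlib.crc32(f"{stage}:{global_seed}".encode())


@dataclass
class RunConfig:
    """Everything needed for one reproducible run."""

    seed: int = 0
    outdir: str = "runs/default"
    label: str = "default"
    make_plots: bool = True
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    levels: DoELevels = field(default_factory=DoELevels)
    replicates: int = 3
    literature: LiteratureDBConfig = field(default_factory=LiteratureDBConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    minority: MinorityRegionSpec = field(default_factory=MinorityRegionSpec)
    train_fraction: float = 0.75
    use_grid_search: bool = False
    inversion: InversionSettings = field(default_factory=InversionSettings)
    k_clusters: int = 4
    restarts: int = 10
    extract_voltage: float = 8.0
    extract_frequency: float = 1.0
    extract_flow: float = 2.0
    sweep_voltages: tuple[float, ...] = (7.0, 8.0, 9.0)
    sweep_frequencies: tuple[float, ...] = tuple(np.arange(0.5, 4.0 + 1e-9, 0.25))
    sweep_flow: float = 2.0
    references: dict[str, float] = field(
        default_factory=lambda: dict(PLACEHOLDER_REFERENCES)
    )
    references_are_placeholders: bool = True


def _build(cls, data: dict | None, **extra):
    data = dict(data or {})
    data.update(extra)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "runs/default")),
        label=str(raw.get("label", "default")),
        make_plots=bool(raw.get("make_plots", True)),
        kinetics=_build(KineticsConfig, raw.get("kinetics")),
        levels=_build(DoELevels, raw.get("levels")),
        replicates=int(raw.get("replicates", 3)),
        literature=_build(LiteratureDBConfig, raw.get("literature")),
        model=_build(
            ModelConfig,
            {
                k: v
                for k, v in (raw.get("model") or {}).items()
                if k != "collocation"
            },
            collocation=_build(
                CollocationSpec, (raw.get("model") or {}).get("collocation")
            ),
        ),
        minority=_build(MinorityRegionSpec, raw.get("minority")),
        train_fraction=float(raw.get("train_fraction", 0.75)),
        use_grid_search=bool(raw.get("use_grid_search", False)),
        inversion=_build(InversionSettings, raw.get("inversion")),
        k_clusters=int(raw.get("k_clusters", 4)),
        restarts=int(raw.get("restarts", 10)),
        extract_voltage=float(raw.get("extract_voltage", 8.0)),
        extract_frequency=float(raw.get("extract_frequency", 1.0)),
        extract_flow=float(raw.get("extract_flow", 2.0)),
        sweep_voltages=tuple(raw.get("sweep_voltages", (7.0, 8.0, 9.0))),
        sweep_frequencies=tuple(
            raw.get("sweep_frequencies", np.arange(0.5, 4.0 + 1e-9, 0.25).tolist())
        ),
        sweep_flow=float(raw.get("sweep_flow", 2.0)),
        references=dict(raw.get("references", PLACEHOLDER_REFERENCES)),
        references_are_placeholders="references" not in raw,
    )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return (and persist) the run manifest.

    Any stage failure aborts the run with the stage named in the error and
    a partial manifest already written to disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(config.seed, stage) for stage in STAGES}
    manifest: dict[str, Any] = {
        "label": config.label,
        "version": __version__,
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": _config_hash(config),
        "stages_completed": [],
        "files": {},
    }

    def register(path: Path) -> None:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    def flush(failed: str | None = None) -> None:
        if failed:
            manifest["failed_stage"] = failed
        _dump_json(manifest, outdir / "manifest.json")

    stage = "simulate"
    try:
        log.info("stage %s (seed %d)", stage, seeds[stage])
        doe = generate_doe_dataset(
            config.levels, config.kinetics, config.replicates, seed=seeds[stage]
        )
        db_cfg = dataclasses.replace(config.literature, seed=seeds[stage] + 1)
        db = generate_literature_db(db_cfg)
        write_doe_csv(doe, outdir / "doe.csv")
        write_db_csv(db, outdir / "dose_damage_db.csv", include_provenance=True)
        register(outdir / "doe.csv")
        register(outdir / "dose_damage_db.csv")
        manifest["stages_completed"].append(stage)

        stage = "train"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        train, test = split_data(doe, config.train_fraction, seed=seeds[stage])
        model_cfg = dataclasses.replace(config.model, seed=seeds[stage])
        if config.use_grid_search and config.model.grid:
            search = grid_search_cv(
                config.model.algorithm,
                train,
                config.model.grid,
                n_folds=5,
                spec=config.minority,
                seed=seeds[stage],
            )
            model_cfg = dataclasses.replace(model_cfg, **search.best_params)
            predictor = fit_model(
                config.model.algorithm,
                train,
                search.best_params,
                seed=seeds[stage],
            )
            best_params = search.best_params
            cv_scores = [gp.mean_rmse for gp in search.table]
        else:
            predictor = (
                train_pgnn(train, model_cfg)
                if config.model.algorithm == "pgnn"
                else fit_model(config.model.algorithm, train, seed=seeds[stage])
            )
            best_params, cv_scores = None, None
        fit = evaluate_model(predictor, test)
        fit.best_params = best_params
        fit.cv_scores = cv_scores
        _dump_json(fit.to_dict(), outdir / "fit_result.json")
        register(outdir / "fit_result.json")
        if hasattr(predictor, "to_dict"):
            _dump_json(predictor.to_dict(), outdir / "predictor.json")
            register(outdir / "predictor.json")
        manifest["stages_completed"].append(stage)

        stage = "audit"
        log.info("stage %s", stage)
        t_lo = min(config.levels.times)
        t_hi = max(config.levels.times)
        time_grid = np.linspace(t_lo, t_hi, 80)
        anchors = [
            (v, f, q)
            for v in config.levels.voltages
            for f in config.levels.frequencies
            for q in config.levels.flows
        ]
        report = check_physical_consistency(predictor, anchors, time_grid)
        _dump_json(report.to_dict(), outdir / "consistency_report.json")
        register(outdir / "consistency_report.json")
        manifest["stages_completed"].append(stage)

        stage = "extract"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        cluster_payload = {}
        for rtype in config.literature.radiation_types:
            db_t = [p for p in db if p.radiation_type == rtype]
            estimates = extract_dose_rates(
                predictor,
                config.extract_voltage,
                config.extract_frequency,
                config.extract_flow,
                db_t,
                config.inversion,
            )
            estimates, summaries = cluster_estimates(
                estimates, k=config.k_clusters, restarts=config.restarts,
                seed=seeds[stage],
            )
            write_estimates_csv(
                estimates,
                outdir / f"estimates_{rtype}.csv",
                sidecar_path=outdir / f"unreachable_{rtype}.csv",
            )
            register(outdir / f"estimates_{rtype}.csv")
            register(outdir / f"unreachable_{rtype}.csv")
            cluster_payload[rtype] = [s.to_dict() for s in summaries]
        _dump_json(cluster_payload, outdir / "cluster_summary.json")
        register(outdir / "cluster_summary.json")
        manifest["stages_completed"].append(stage)

        stage = "sweep"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        sweeps = {}
        for rtype in config.literature.radiation_types:
            db_t = [p for p in db if p.radiation_type == rtype]
            sweep = parameter_sweep(
                predictor,
                db_t,
                config.sweep_voltages,
                config.sweep_frequencies,
                config.sweep_flow,
                k=config.k_clusters,
                restarts=config.restarts,
                seed=seeds[stage],
                settings=config.inversion,
            )
            sweeps[rtype] = sweep
            write_sweep_csv(sweep, outdir / f"sweep_{rtype}.csv")
            register(outdir / f"sweep_{rtype}.csv")
        manifest["stages_completed"].append(stage)

        stage = "compare"
        log.info("stage %s", stage)
        summary = comparison_summary(sweeps, config.references)
        payload = {
            "references_are_placeholders": config.references_are_placeholders,
            "types": {t: c.to_dict() for t, c in summary.items()},
        }
        _dump_json(payload, outdir / "comparison.json")
        register(outdir / "comparison.json")
        for rtype, sweep in sweeps.items():
            if rtype not in summary:
                continue
            dev = relative_deviation_grid(sweep, config.references[rtype])
            write_sweep_csv(sweep, outdir / f"deviation_{rtype}.csv", values=dev)
            register(outdir / f"deviation_{rtype}.csv")
            if config.make_plots:
                png = outdir / f"deviation_{rtype}.png"
                plot_deviation_heatmap(
                    sweep, dev, png, title=f"relative deviation vs {rtype}"
                )
                register(png)
        manifest["stages_completed"].append(stage)
    except Exception as err:
        flush(failed=stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    flush()
    return manifest
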