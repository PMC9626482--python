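"""Exception and warning types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object violates its invariants."""


class InsufficientDataError(ValueError):
    """Too few records to carry out the requested operation."""


class TrainingDivergedError(RuntimeError):
    """Non-finite loss encountered during network training."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class UnreachableTargetError(ValueError):
    """The requested damage level cannot be reached on the time domain.

    ``code`` is ``"below_range"`` when the target lies under the curve at
    the lower end of the domain and ``"above_range"`` when it exceeds the
    curve at the upper end.
    """

    def __init__(self, code: str, message: str):
        assert code in ("below_range", "above_range")
        self.code = code
        super().__init__(message)


class ConsistencyViolationWarning(UserWarning):
    """A predictor decreased with time where it should not."""


class OversamplingWarning(UserWarning):
    """Degenerate region encountered during oversampling (e.g. one record)."""
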