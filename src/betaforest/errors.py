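"""Exception types shared across the pipeline stages."""


class BetaForestError(Exception):
    """Base class for all package-specific errors."""


class ZeroVarianceError(BetaForestError):
    """A variable has zero (weighted) variance and cannot be standardized."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"zero-variance variable: {column!r}")


class InsufficientDataError(BetaForestError):
    """Fewer complete rows than the minimum required for a fit."""


class SchemaError(BetaForestError):
    """A table is missing required columns or contains unparseable cells."""


class PoolingError(BetaForestError):
    """Invalid input to the pooling of per-plausible-value fits."""


class BootstrapError(BetaForestError):
    """Bootstrap resampling could not produce the requested draws."""


class SimulationError(BetaForestError):
    """Invalid simulation configuration."""


class PlotError(BetaForestError):
    """Invalid input to a plotting routine."""
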