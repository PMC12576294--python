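"""Exception hierarchy shared across the package."""


class EdiiRiskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EdiiRiskError):
    """An invalid generator or pipeline configuration field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class InvalidRecordError(EdiiRiskError):
    """A dietary record that cannot be energy-adjusted (e.g. energy <= 0)."""


class SchemaError(EdiiRiskError):
    """A required column or component is missing from an input table."""


class DegenerateExposureError(EdiiRiskError):
    """An exposure with zero variance cannot be standardized or cut."""


class InvalidPanelError(EdiiRiskError):
    """A blood panel with negative entries."""


class UndefinedIndexError(EdiiRiskError):
    """An index whose denominator (lymphocyte count) is non-positive."""


class HarmonizationError(EdiiRiskError):
    """Variants that cannot be allele-aligned between dosages and effects."""

    def __init__(self, variant_ids):
        self.variant_ids = list(variant_ids)
        super().__init__(
            "cannot harmonize alleles for variants: " + ", ".join(self.variant_ids)
        )


class DegenerateScoreError(EdiiRiskError):
    """A polygenic score with zero variance cannot be cut into quantile groups."""


class UndefinedMetricError(EdiiRiskError):
    """A discrimination metric that needs at least one event and one non-event."""


class CollinearityError(EdiiRiskError):
    """Rank-deficient design matrix in a regression model."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__("collinear design columns: " + ", ".join(self.columns))


class ConvergenceError(EdiiRiskError):
    """Model fitting failed to converge (e.g. monotone partial likelihood)."""


class SplineUnavailableError(EdiiRiskError):
    """Too few distinct exposure values to build a spline basis."""


class CutpointRangeError(EdiiRiskError):
    """No candidate cutpoints inside the requested quantile range."""


class StageError(EdiiRiskError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
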