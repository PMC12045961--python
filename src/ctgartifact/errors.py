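"""Exception hierarchy shared across the package."""


class CTGArtifactError(Exception):
    """Base class for all package errors."""


class TraceParseError(CTGArtifactError):
    """A trace file is malformed; the message names the offending field/row."""


class UndefinedMetricError(CTGArtifactError):
    """A signal metric has an empty denominator (no acquisition-active samples)."""


class ConfigurationError(CTGArtifactError):
    """Invalid analysis configuration (bin counts, thresholds, covariate lists)."""


class SeparationError(CTGArtifactError):
    """Quasi-complete separation detected while fitting a logistic model."""


class RankDeficiencyError(CTGArtifactError):
    """Design matrix is rank deficient; the message names collinear columns."""


class PositivityError(CTGArtifactError):
    """A propensity score of exactly 0 or 1 makes inverse weighting undefined."""


class CalibrationError(CTGArtifactError):
    """Intercept calibration of the synthetic generator failed to converge."""


class EmptyCohortError(CTGArtifactError):
    """A pipeline filter removed every record; the message names the filter."""
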