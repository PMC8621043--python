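"""Exception taxonomy.

``ValidationError`` and its subclasses signal malformed input (CLI exit
code 2); the degenerate-estimation errors are raised per transit by the
inverse solvers and are caught and flagged — never fatal — when running a
whole recording.
"""


class ApTrackError(Exception):
    """Base class for all package errors."""


class ValidationError(ApTrackError, ValueError):
    """Invalid parameter, model or file content."""


class ConfigError(ValidationError):
    """Unknown or ill-typed configuration key."""


class SchemaError(ValidationError):
    """Recording/probe file does not match the expected schema."""


class SamplingError(ValidationError):
    """Time column is irregular beyond tolerance."""


class InvalidWaveformError(ValidationError):
    """Charge waveform produced non-finite values."""


class SingularityError(ApTrackError):
    """Potential requested at zero source-electrode distance."""


class DegenerateGeometryError(ApTrackError):
    """Electrode triad is collinear (or rotated positions coincide)."""


class DegenerateDirectionError(DegenerateGeometryError):
    """Zero velocity vector cannot define a local frame."""


class UnresolvableVelocityError(ApTrackError):
    """All peak-time differences are zero: speed beyond the resolution limit."""


class InconsistentAmplitudesError(ApTrackError):
    """Amplitude triplet admits no real source height (all Z^2 < 0)."""


class BatchDegenerateError(ApTrackError):
    """Every transit in a batch failed with a degenerate-input error."""
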