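"""Exception hierarchy for the patreat pipeline.

Every stage raises a subclass of :class:`PatreatError` so callers (and the
CLI) can distinguish user error from numeric trouble.
"""


class PatreatError(Exception):
    """Base class for all patreat errors."""


class ValidationError(PatreatError, ValueError):
    """A spec/parameter object failed validation before any compute ran."""


class GeometryError(ValidationError):
    """A simulated object does not fit inside the requested volume."""


class AlignmentError(PatreatError, ValueError):
    """Two volumes that must be co-registered have mismatched shapes."""


class ConfigurationError(PatreatError, ValueError):
    """An ill-posed configuration, e.g. a singular extinction matrix."""


class NumericDomainError(PatreatError, ValueError):
    """An input leaves the numeric domain of an operation (e.g. zero fluence)."""


class EmptyROIError(PatreatError, ValueError):
    """An ROI mask selects no voxels."""


class InsufficientDataError(PatreatError, ValueError):
    """Too few observations for the requested estimate."""
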