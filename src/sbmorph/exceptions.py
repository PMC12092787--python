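"""Exception hierarchy for sbmorph.

All package errors derive from :class:`SbmError` so callers can catch the
package's failures without masking programming errors.  Validation problems
(bad parameters, malformed inputs, inconsistent metadata) derive from
:class:`ValidationError`, which is also a ``ValueError``.
"""


class SbmError(Exception):
    """Base class for all sbmorph errors."""


class ValidationError(SbmError, ValueError):
    """Invalid parameter value or malformed/inconsistent input data."""


class ShapeMismatchError(ValidationError):
    """Volumes or arrays whose grids/shapes do not agree."""


class MetadataError(ValidationError):
    """Participants table inconsistent with the supplied volumes."""


class MaskError(ValidationError):
    """Brain mask is empty or incompatible with the volume grid."""


class DegenerateComponentError(SbmError):
    """A source map has zero variance and cannot be standardized."""


class ConvergenceError(SbmError):
    """Iterative algorithm failed to converge after all restarts."""


class ConfigError(ValidationError):
    """Pipeline configuration failed validation."""
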