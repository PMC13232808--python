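"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`NicheKitError` so callers can trap
pipeline failures without catching unrelated bugs.
"""


class NicheKitError(Exception):
    """Base class for all package errors."""


class AlignmentError(NicheKitError):
    """Raster layers or maps do not share grid shape, cell size, origin or CRS."""


class ResolutionError(NicheKitError):
    """Requested cell size is not commensurable with the current grid."""


class InsufficientDataError(NicheKitError):
    """Too few valid cells or records for the requested computation."""


class EmptySetError(NicheKitError):
    """An occurrence set became empty after formatting; modelling cannot proceed."""


class SamplingError(NicheKitError):
    """Fewer eligible cells than requested sample size."""


class DegenerateLabelsError(NicheKitError):
    """Score/label vectors contain a single class; threshold metrics undefined."""


class UndefinedMetricError(NicheKitError):
    """A confusion-matrix metric is undefined (empty class or p_e = 1)."""


class NoEnsembleError(NicheKitError):
    """No member model passed the AUC gate."""


class SchemaError(NicheKitError):
    """Prediction inputs do not provide the variables the model was trained on."""


class UndefinedRCIError(NicheKitError):
    """Baseline suitable area is zero; the range change index is undefined."""


class UndefinedOverlapError(NicheKitError):
    """A map with zero total cannot be normalized for overlap."""


class EmptyRangeError(NicheKitError):
    """A binary map has no suitable cells; centroids are undefined."""


class SpecificationError(NicheKitError):
    """A virtual-species response or scenario references unknown variables."""


class ConfigError(NicheKitError):
    """Run configuration is missing keys, has unknown keys, or out-of-range values."""


class DependencyError(NicheKitError):
    """A pipeline stage was run before the artifacts it consumes exist."""
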