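"""Exception hierarchy shared across the pipeline."""


class MeniscoqError(Exception):
    """Base class for all package errors."""


class ValidationError(MeniscoqError, ValueError):
    """A parameter or input value violates its contract."""


class GeometryError(MeniscoqError, ValueError):
    """Image geometries (shape / spacing / affine) are inconsistent."""


class BoundsError(GeometryError):
    """A generated object does not fit inside the voxel grid."""


class SchemaError(MeniscoqError, ValueError):
    """A structured file (JSON landmarks, config) is missing required fields."""


class EmptyRegionError(MeniscoqError, ValueError):
    """A region contains no usable voxels after masking/convergence filtering."""


class MeasurementError(MeniscoqError, ValueError):
    """A geometric measurement cannot be taken (e.g. empty slice)."""


class ModelError(MeniscoqError, ValueError):
    """A statistical model cannot be fit (singular design, too few data)."""
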