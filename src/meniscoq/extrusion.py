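"""Meniscal extrusion measurement on a coronal reference plane.

Extrusion is the medial displacement of the meniscal body beyond the
peripheral margin of the tibial plateau, measured between two vertical
lines on a single coronal image: one at the plateau margin, one at the most
peripheral aspect of the meniscal body.  The conventional pathological
threshold is 2 mm, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, MeasurementError, ValidationError

EXTRUSION_THRESHOLD_MM = 2.0


@dataclass
class ExtrusionMeasurement:
    """Signed medial distance (mm) past the plateau margin and the ≥2 mm flag.

    The distance is negative when the meniscus lies entirely within the
    plateau; the flag alone applies the clinical rule.
    """

    distance_mm: float
    extruded: bool
    coronal_index: int


def measure_extrusion(
    meniscus_mask: np.ndarray,
    plateau_margin_mm: np.ndarray,
    coronal_index: int,
    affine: np.ndarray,
    medial_direction: np.ndarray,
    coronal_axis: int = 1,
) -> ExtrusionMeasurement:
    """Measure extrusion of ``meniscus_mask`` on one coronal slice.

    The coronal plane is the slice ``coronal_index`` along ``coronal_axis``
    (the anterior–posterior voxel axis, 1 by default).  The distance is the
    maximum, over masked voxels of that slice, of the offset of the voxel
    centre from the plateau-margin landmark along ``medial_direction``.
    """
    mask = np.asarray(meniscus_mask).astype(bool)
    if mask.ndim != 3:
        raise GeometryError("meniscus mask must be 3-D")
    if plateau_margin_mm is None:
        raise ValidationError("plateau margin landmark is required")
    margin = np.asarray(plateau_margin_mm, dtype=float)
    direction = np.asarray(medial_direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValidationError("medial_direction must be a nonzero vector")
    direction = direction / norm
    if not 0 <= coronal_index < mask.shape[coronal_axis]:
        raise MeasurementError(
            f"coronal index {coronal_index} outside axis of length {mask.shape[coronal_axis]}"
        )

    idx = np.argwhere(np.take(mask, coronal_index, axis=coronal_axis))
    if idx.size == 0:
        raise MeasurementError(
            f"coronal slice {coronal_index} does not intersect the meniscus mask"
        )
    # re-insert the fixed coronal coordinate to get full 3-D indices
    full = np.insert(idx, coronal_axis, coronal_index, axis=1)
    affine = np.asarray(affine, dtype=float)
    coords = full @ affine[:3, :3].T + affine[:3, 3]
    distance = float(np.max((coords - margin) @ direction))
    return ExtrusionMeasurement(
        distance_mm=distance,
        extruded=distance >= EXTRUSION_THRESHOLD_MM,
        coronal_index=int(coronal_index),
    )
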