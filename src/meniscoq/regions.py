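"""Angular four-region partition of a meniscus mask.

The segmented meniscus is divided, by angle relative to the line connecting
the anterior and posterior horns, into anterior horn (0°–45°), anterior body
(45°–90°), posterior body (90°–135°) and posterior horn (135°–180°).  Angles
are measured in the axial plane from the vertex of the horn-to-horn segment
(midpoint by default), starting at the direction of the anterior horn and
sweeping through the meniscal arc — i.e. through the side of the line that
contains the mask centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, GeometryError, ValidationError
from .relaxometry import ParameterMaps, median_t2star

log = logging.getLogger(__name__)

REGION_NAMES = ("AH", "AB", "PB", "PH")
REGION_CODES = {"AH": 1, "AB": 2, "PB": 3, "PH": 4}
CODE_TO_NAME = {v: k for k, v in REGION_CODES.items()}


@dataclass
class RegionPartition:
    """Region label grid (1 AH, 2 AB, 3 PB, 4 PH) plus per-region volumes."""

    labels: np.ndarray
    origin_mm: np.ndarray
    reference_axis: np.ndarray  # in-plane unit vector toward the anterior horn
    volumes_px: dict[str, int]
    volumes_mm3: dict[str, float]

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == REGION_CODES[region]

    @property
    def total_voxels(self) -> int:
        return sum(self.volumes_px.values())


def _voxel_world_coords(idx: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return idx @ affine[:3, :3].T + affine[:3, 3]


def partition_regions(
    mask: np.ndarray,
    anterior_horn_mm: np.ndarray,
    posterior_horn_mm: np.ndarray,
    affine: np.ndarray,
    vertex: str = "midpoint",
) -> RegionPartition:
    """Partition ``mask`` into AH/AB/PB/PH by horn-relative angle.

    Bins are half-open [0°,45°), [45°,90°), [90°,135°), [135°,180°]: a
    boundary voxel goes to the more posterior region.  Voxels projecting to
    the far side of the horn-to-horn line are clamped into the nearest
    terminal bin (AH or PH).  ``vertex`` selects the angular origin:
    ``"midpoint"`` of the horn segment (default) or the mask ``"centroid"``.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    A = np.asarray(anterior_horn_mm, dtype=float)
    P = np.asarray(posterior_horn_mm, dtype=float)
    affine = np.asarray(affine, dtype=float)
    scale = max(np.linalg.norm(A - P), 1.0)
    if np.linalg.norm(A - P) < 1e-9:
        raise GeometryError("anterior and posterior horn landmarks coincide")

    idx = np.argwhere(mask)
    coords = _voxel_world_coords(idx, affine)
    centroid = coords.mean(axis=0)

    if vertex == "midpoint":
        origin = (A + P) / 2.0
    elif vertex == "centroid":
        origin = centroid.copy()
    else:
        raise ValidationError(f"unknown vertex convention: {vertex!r}")

    # axial plane: project out the supero-inferior (world z) axis
    a2 = (A - origin)[:2]
    na = np.linalg.norm(a2)
    if na < 1e-9:
        raise GeometryError("anterior horn projects onto the angular origin")
    a2 = a2 / na
    n2 = np.array([-a2[1], a2[0]])  # in-plane normal to the horn line
    # sweep side is defined by the horn-to-horn line itself (its midpoint),
    # independent of the vertex convention
    midpoint = (A + P) / 2.0
    side = float(np.dot(centroid[:2] - midpoint[:2], n2))
    if abs(side) < 1e-9 * scale:
        raise GeometryError(
            "mask centroid lies on the horn-to-horn line; sweep side is ambiguous"
        )
    n2 = n2 * np.sign(side)

    v = coords[:, :2] - origin[:2]
    theta = np.degrees(np.arctan2(v @ n2, v @ a2))  # (-180, 180]
    # far side of the line: clamp into nearest terminal bin
    theta = np.where(theta < 0, np.where(theta > -90.0, 0.0, 180.0), theta)
    codes = np.minimum(theta // 45.0, 3.0).astype(np.int8) + 1

    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[tuple(idx.T)] = codes

    voxvol = float(abs(np.linalg.det(affine[:3, :3])))
    counts = np.bincount(codes, minlength=5)
    volumes_px = {name: int(counts[code]) for name, code in REGION_CODES.items()}
    volumes_mm3 = {name: n * voxvol for name, n in volumes_px.items()}
    return RegionPartition(
        labels=labels,
        origin_mm=origin,
        reference_axis=a2,
        volumes_px=volumes_px,
        volumes_mm3=volumes_mm3,
    )


def region_table(
    maps: ParameterMaps,
    part: RegionPartition,
    subject_id: str,
    side: str,
) -> pd.DataFrame:
    """Per-region medians and pixel-count volumes as one tidy table.

    One row per region: median T2*, median NRMSE, voxel count and volume in
    mm³ (count × voxel volume).  An empty region yields a row of NaNs and a
    logged warning rather than an error, so batch runs survive degenerate
    masks.
    """
    if maps.t2star_ms.shape != part.labels.shape:
        raise GeometryError("parameter maps and partition shapes differ")
    if side not in ("medial", "lateral"):
        raise ValidationError("side must be 'medial' or 'lateral'")
    rows = []
    for name in REGION_NAMES:
        rmask = part.region_mask(name)
        try:
            summ = median_t2star(maps, rmask)
            med, mednrmse, n = summ.median_t2star_ms, summ.median_nrmse, summ.n_voxels
        except EmptyRegionError:
            log.warning("region %s (%s, %s) is empty after convergence filtering",
                        name, subject_id, side)
            med, mednrmse, n = np.nan, np.nan, 0
        rows.append(
            {
                "subject_id": subject_id,
                "side": side,
                "region": name,
                "median_t2star_ms": med,
                "median_nrmse": mednrmse,
                "voxels": int(part.volumes_px[name]),
                "volume_mm3": part.volumes_mm3[name],
                "fitted_voxels": n,
            }
        )
    return pd.DataFrame(rows)
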