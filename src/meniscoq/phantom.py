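"""Synthetic multi-echo knee phantom with known ground truth.

Two C-shaped menisci (half-annuli in the axial plane, with a supero-inferior
thickness) are voxelized onto a grid matching the T2*-mapping protocol:
0.44 × 0.44 mm in-plane, 1.0 mm slices, seven echo times between 3.1 and
21.4 ms.  Each meniscus carries per-region ground-truth T2* values on the
scale observed in menisci at 7 T (≈7–13 ms), and the scene includes the
landmarks downstream stages need: anterior/posterior horn points per
meniscus, the medial tibial-plateau margin on a reference coronal plane, and
the most peripheral point of the medial meniscal body.  A prescribed
``extrusion_mm`` displaces the medial meniscus medially beyond the plateau
margin.

The geometry is an idealized annulus, not anatomy: it gives every downstream
stage (fitting, angular partition, extrusion, statistics) an input with an
exactly known answer.

Conventions: world coordinates are RAS millimetres with the affine mapping
0-based voxel indices to voxel centres; +x is the medial direction of the
medial compartment, +y posterior, +z superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import regions as _regions
from .errors import BoundsError, ValidationError
from .regions import REGION_CODES, REGION_NAMES
from .relaxometry import MultiEchoVolume

DEFAULT_TE_MS = (3.1, 6.1, 9.2, 12.2, 15.3, 18.4, 21.4)
DEFAULT_VOXEL_SIZE_MM = (0.44, 0.44, 1.0)
DEFAULT_GRID_SHAPE = (120, 120, 40)

# Published group summaries (mean of per-subject regional median T2*, ms)
# used to parameterize simulations; (mean, SD) per region.
PATIENT_MEDIAL_T2STAR_MS = {"AH": (9.57, 1.05), "AB": (9.53, 1.24),
                            "PB": (11.95, 1.88), "PH": (12.68, 1.31)}
CONTROL_MEDIAL_T2STAR_MS = {"AH": (7.74, 0.98), "AB": (8.25, 0.88),
                            "PB": (9.19, 1.35), "PH": (8.82, 1.46)}
PATIENT_LATERAL_T2STAR_MS = {"AH": (8.89, 1.37), "AB": (8.17, 1.18),
                             "PB": (8.01, 1.01), "PH": (9.06, 1.00)}
CONTROL_LATERAL_T2STAR_MS = {"AH": (7.75, 0.87), "AB": (7.38, 0.77),
                             "PB": (7.31, 0.65), "PH": (7.70, 0.67)}

BACKGROUND_S0_FRACTION = 0.05  # fixture constant: keeps masks separable
BACKGROUND_T2STAR_MS = 25.0


@dataclass(frozen=True)
class MeniscusShapeSpec:
    """Idealized C-shaped meniscus: a half-annulus with uniform thickness.

    ``body_direction`` is the in-plane unit vector from the arc centre
    toward the meniscal body (the peripheral rim apex); the arc sweeps
    ``arc_span_deg`` symmetrically about it, horns at the ends.  The root
    gaps trim tissue at the arc ends, emulating segmentation that starts
    1 mm distal to the anterior root attachment and stops one in-plane pixel
    (0.44 mm) proximal to the posterior root.  The default outer radius is
    27 in-plane voxels (11.88 mm) so the peripheral rim lands on the
    voxel-centre lattice.
    """

    center_mm: tuple[float, float, float]
    body_direction: tuple[float, float] = (1.0, 0.0)
    inner_radius_mm: float = 7.0
    outer_radius_mm: float = 11.88
    arc_span_deg: float = 180.0
    thickness_mm: float = 8.0
    region_t2star_ms: Mapping[str, float] = field(
        default_factory=lambda: {r: m for r, (m, _) in PATIENT_MEDIAL_T2STAR_MS.items()}
    )
    s0: float = 100.0
    anterior_root_gap_mm: float = 1.0
    posterior_root_gap_mm: float = 0.44
    taper: float = 0.0  # 0 = uniform thickness; 1 = wedge vanishing at the inner rim

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValidationError("need 0 < inner_radius_mm < outer_radius_mm")
        if set(self.region_t2star_ms) != set(REGION_NAMES):
            raise ValidationError(f"region_t2star_ms must have exactly {REGION_NAMES}")
        if any(v <= 0 for v in self.region_t2star_ms.values()):
            raise ValidationError("all region T2* values must be positive")
        if not 0 < self.arc_span_deg <= 360:
            raise ValidationError("arc_span_deg must be in (0, 360]")
        if self.thickness_mm <= 0 or self.s0 <= 0:
            raise ValidationError("thickness_mm and s0 must be positive")
        if not 0 <= self.taper <= 1:
            raise ValidationError("taper must be in [0, 1]")

    @property
    def mid_radius_mm(self) -> float:
        return 0.5 * (self.inner_radius_mm + self.outer_radius_mm)


def _default_menisci() -> dict[str, MeniscusShapeSpec]:
    return {
        # centres sit a tenth of a millimetre off the in-plane voxel lattice so
        # that no voxel lands exactly on a 45-degree bin boundary ray
        "medial": MeniscusShapeSpec(
            center_mm=(34.42, 26.4, 20.0), body_direction=(1.0, 0.0),
            region_t2star_ms={r: m for r, (m, _) in PATIENT_MEDIAL_T2STAR_MS.items()},
        ),
        "lateral": MeniscusShapeSpec(
            center_mm=(13.1, 26.4, 20.0), body_direction=(-1.0, 0.0),
            region_t2star_ms={r: m for r, (m, _) in PATIENT_LATERAL_T2STAR_MS.items()},
        ),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full scene description: grid, protocol, menisci, noise, extrusion."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    te_ms: tuple[float, ...] = DEFAULT_TE_MS
    menisci: Mapping[str, MeniscusShapeSpec] = field(default_factory=_default_menisci)
    noise_sigma: float = 2.0
    seed: int = 0
    extrusion_mm: float = 0.0

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if te.size == 0 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValidationError("te_ms must be positive and strictly increasing")
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValidationError("grid_shape must be three positive integers")
        if any(h <= 0 for h in self.voxel_size_mm):
            raise ValidationError("voxel_size_mm must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be nonnegative")
        if set(self.menisci) != {"medial", "lateral"}:
            raise ValidationError("menisci must contain exactly 'medial' and 'lateral'")
        if self.extrusion_mm < 0:
            raise ValidationError("extrusion_mm must be nonnegative")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class LandmarkSet:
    """World-millimetre landmarks driving regionalization and extrusion."""

    anterior_horn_mm: dict[str, np.ndarray]
    posterior_horn_mm: dict[str, np.ndarray]
    tibial_plateau_margin_mm: np.ndarray
    meniscal_body_peripheral_mm: np.ndarray
    coronal_reference_index: int
    medial_direction: np.ndarray


@dataclass
class PhantomTruth:
    """Ground-truth grids + landmarks: the recovery oracle for the pipeline."""

    t2star_map: np.ndarray
    s0_map: np.ndarray
    region_labels: dict[str, np.ndarray]
    landmarks: LandmarkSet
    spec: PhantomSpec

    @property
    def affine(self) -> np.ndarray:
        return self.spec.affine

    def mask(self, side: str) -> np.ndarray:
        return self.region_labels[side] > 0

    def combined_mask(self) -> np.ndarray:
        return self.mask("medial") | self.mask("lateral")


def _perp_posterior(b: np.ndarray) -> np.ndarray:
    """In-plane unit vector perpendicular to ``b`` pointing posteriorly (+y)."""
    p = np.array([-b[1], b[0]])
    if p[1] < 0:
        p = -p
    if abs(p[1]) < 1e-12:
        raise ValidationError("body_direction may not point along the A-P axis")
    return p


def _voxelize_meniscus(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    m: MeniscusShapeSpec,
    center: np.ndarray,
) -> np.ndarray:
    """Surface-inclusive voxelization: a voxel belongs to the meniscus when
    the annulus passes through it (boundary dilated by half a voxel radially
    and axially)."""
    hx, hy, hz = voxel
    if abs(hx - hy) > 1e-9:
        raise ValidationError("phantom voxelization assumes isotropic in-plane spacing")
    b = np.asarray(m.body_direction, dtype=float)
    b = b / np.linalg.norm(b)
    p = _perp_posterior(b)

    xs = np.arange(shape[0]) * hx
    ys = np.arange(shape[1]) * hy
    zs = np.arange(shape[2]) * hz
    dx = xs[:, None] - center[0]
    dy = ys[None, :] - center[1]
    rho = np.sqrt(dx * dx + dy * dy)
    half = 0.5 * hx
    radial_ok = (rho >= m.inner_radius_mm - half) & (rho <= m.outer_radius_mm + half)

    # arc angle psi in (-180, 180], 0 at the body apex, horns at +/- span/2
    along_b = dx * b[0] + dy * b[1]
    along_p = dx * p[0] + dy * p[1]
    psi = np.degrees(np.arctan2(along_p, along_b))
    gap_a = np.degrees(m.anterior_root_gap_mm / m.mid_radius_mm)
    gap_p = np.degrees(m.posterior_root_gap_mm / m.mid_radius_mm)
    lo = -m.arc_span_deg / 2.0 + gap_a  # anterior end (negative psi side)
    hi = m.arc_span_deg / 2.0 - gap_p
    angular_ok = (psi >= lo) & (psi <= hi)

    if m.taper > 0:
        frac = np.clip((m.outer_radius_mm - rho) / (m.outer_radius_mm - m.inner_radius_mm), 0, 1)
        local_thick = m.thickness_mm * (1.0 - m.taper * frac)
    else:
        local_thick = np.full_like(rho, m.thickness_mm)
    dz = np.abs(zs[None, None, :] - center[2])
    axial_ok = dz <= (local_thick / 2.0)[:, :, None] + 0.5 * hz

    # bounds check on the analytic envelope
    for ax, (c, r, n, h) in enumerate(
        [(center[0], m.outer_radius_mm + half, shape[0], hx),
         (center[1], m.outer_radius_mm + half, shape[1], hy),
         (center[2], m.thickness_mm / 2.0 + 0.5 * hz, shape[2], hz)]
    ):
        if c - r < -h / 2 - 1e-9 or c + r > (n - 1) * h + h / 2 + 1e-9:
            raise BoundsError(f"meniscus annulus exceeds the grid along axis {ax}")

    return (radial_ok & angular_ok)[:, :, None] & axial_ok


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the ground-truth scene for ``spec`` (deterministic, no RNG).

    The medial meniscus (and its horn landmarks) is displaced medially by
    ``spec.extrusion_mm``; the tibial-plateau margin landmark stays at the
    un-displaced peripheral rim, so the prescribed displacement equals the
    ground-truth extrusion.  Region labels are produced by the same angular
    rule as :func:`meniscoq.regions.partition_regions`, applied to the
    ground-truth landmarks.
    """
    affine = spec.affine
    t2 = np.full(spec.grid_shape, BACKGROUND_T2STAR_MS)
    max_s0 = max(m.s0 for m in spec.menisci.values())
    s0 = np.full(spec.grid_shape, BACKGROUND_S0_FRACTION * max_s0)

    labels: dict[str, np.ndarray] = {}
    ah: dict[str, np.ndarray] = {}
    ph: dict[str, np.ndarray] = {}
    for side, m in spec.menisci.items():
        center = np.asarray(m.center_mm, dtype=float)
        if side == "medial" and spec.extrusion_mm > 0:
            b = np.asarray(m.body_direction, dtype=float)
            b = b / np.linalg.norm(b)
            center = center + spec.extrusion_mm * np.array([b[0], b[1], 0.0])
        mask = _voxelize_meniscus(spec.grid_shape, spec.voxel_size_mm, m, center)
        b = np.asarray(m.body_direction, dtype=float)
        b = b / np.linalg.norm(b)
        p = _perp_posterior(b)
        half_span = np.radians(m.arc_span_deg / 2.0)
        arm = m.mid_radius_mm * (np.cos(half_span) * b - np.sin(half_span) * p)
        ah[side] = np.array([center[0] + arm[0], center[1] + arm[1], center[2]])
        arm_p = m.mid_radius_mm * (np.cos(half_span) * b + np.sin(half_span) * p)
        ph[side] = np.array([center[0] + arm_p[0], center[1] + arm_p[1], center[2]])

        part = _regions.partition_regions(mask, ah[side], ph[side], affine)
        labels[side] = part.labels
        for name in REGION_NAMES:
            rmask = part.labels == REGION_CODES[name]
            t2[rmask] = m.region_t2star_ms[name]
            s0[rmask] = m.s0

    med = spec.menisci["medial"]
    bmed = np.asarray(med.body_direction, dtype=float)
    bmed = bmed / np.linalg.norm(bmed)
    cen = np.asarray(med.center_mm, dtype=float)
    margin = cen + med.outer_radius_mm * np.array([bmed[0], bmed[1], 0.0])
    peripheral = margin + spec.extrusion_mm * np.array([bmed[0], bmed[1], 0.0])
    coronal_index = int(round(cen[1] / spec.voxel_size_mm[1]))

    lm = LandmarkSet(
        anterior_horn_mm=ah,
        posterior_horn_mm=ph,
        tibial_plateau_margin_mm=margin,
        meniscal_body_peripheral_mm=peripheral,
        coronal_reference_index=coronal_index,
        medial_direction=np.array([bmed[0], bmed[1], 0.0]),
    )
    _check_landmarks_inside(lm, spec)
    return PhantomTruth(t2star_map=t2, s0_map=s0, region_labels=labels,
                        landmarks=lm, spec=spec)


def _check_landmarks_inside(lm: LandmarkSet, spec: PhantomSpec) -> None:
    extent = [(n - 1) * h for n, h in zip(spec.grid_shape, spec.voxel_size_mm)]
    pts = list(lm.anterior_horn_mm.values()) + list(lm.posterior_horn_mm.values())
    pts += [lm.tibial_plateau_margin_mm, lm.meniscal_body_peripheral_mm]
    for pt in pts:
        if np.any(np.asarray(pt) < -1e-9) or np.any(np.asarray(pt) > np.asarray(extent) + 1e-9):
            raise BoundsError(f"landmark {pt} falls outside the phantom grid")


def simulate_multiecho(
    truth: PhantomTruth,
    te_ms=None,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> MultiEchoVolume:
    """Forward-simulate magnitude GRE signals S0·exp(−TE/T2*) with Rician noise.

    With ``noise_sigma > 0`` each sample is the magnitude of the noiseless
    signal perturbed by complex Gaussian noise of per-channel SD
    ``noise_sigma`` — the standard model for magnitude MRI.  Reproducible
    for a fixed seed.
    """
    spec = truth.spec
    te = np.asarray(spec.te_ms if te_ms is None else te_ms, dtype=float)
    sigma = spec.noise_sigma if noise_sigma is None else float(noise_sigma)
    if sigma < 0:
        raise ValidationError("noise_sigma must be nonnegative")
    if te.size == 0:
        raise ValidationError("te_ms must be nonempty")
    s = int(spec.seed if seed is None else seed)

    signal = truth.s0_map[..., None] * np.exp(-te[None, None, None, :] / truth.t2star_map[..., None])
    if sigma > 0:
        rng = np.random.default_rng(s)
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt(re * re + im * im)
    return MultiEchoVolume(
        data=signal, te_ms=te, voxel_size_mm=spec.voxel_size_mm, affine=spec.affine
    )


def patient_spec(extrusion_mm: float = 3.0, noise_sigma: float = 2.0, seed: int = 0) -> PhantomSpec:
    """Phantom parameterized by the patient-group regional means (both menisci)."""
    return PhantomSpec(noise_sigma=noise_sigma, seed=seed, extrusion_mm=extrusion_mm)


def control_spec(noise_sigma: float = 2.0, seed: int = 0) -> PhantomSpec:
    """Phantom parameterized by the control-group regional means (both menisci)."""
    menisci = {
        "medial": replace(
            _default_menisci()["medial"],
            region_t2star_ms={r: m for r, (m, _) in CONTROL_MEDIAL_T2STAR_MS.items()},
        ),
        "lateral": replace(
            _default_menisci()["lateral"],
            region_t2star_ms={r: m for r, (m, _) in CONTROL_LATERAL_T2STAR_MS.items()},
        ),
    }
    return PhantomSpec(menisci=menisci, noise_sigma=noise_sigma, seed=seed, extrusion_mm=0.0)
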