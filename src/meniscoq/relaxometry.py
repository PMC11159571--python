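"""Voxel-wise mono-exponential T2* relaxometry.

The signal of a multi-echo gradient-recalled-echo (GRE) acquisition decays
with echo time TE as

    S(TE) = S0 * exp(-TE / T2*)

where ``S0`` is the extrapolated signal at TE = 0 and ``T2*`` the effective
transverse relaxation time.  This module fits the two parameters voxel by
voxel with bounded least squares and reports a per-voxel fit-quality metric:
the root-mean-square error of the residuals normalized by the fitted S0
(NRMSE).

The nonlinear problem is separable: for fixed T2* the optimal S0 is a linear
least-squares solution.  The fit therefore reduces to a one-dimensional
search over T2* (variable projection), performed with a global log-spaced
grid followed by vectorized interval refinement — deterministic, robust to
local minima and fast enough to run on a full volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import EmptyRegionError, GeometryError, ValidationError

T2STAR_BOUNDS_MS = (0.1, 100.0)
FALLBACK_T2STAR_MS = 10.0  # mid-range tissue value used when log-linear init degenerates
_N_GRID = 128
_N_REFINE = 120  # ternary-search iterations; interval shrinks by (2/3)^n


def _check_te(te_ms: np.ndarray) -> np.ndarray:
    te = np.asarray(te_ms, dtype=float)
    if te.ndim != 1 or te.size == 0:
        raise ValidationError("te_ms must be a nonempty 1-D sequence")
    if np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ValidationError("te_ms must be strictly increasing and positive")
    return te


@dataclass
class MultiEchoVolume:
    """4-D magnitude image (x, y, z, echo) with its echo-time vector."""

    data: np.ndarray
    te_ms: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.te_ms = _check_te(self.te_ms)
        if self.data.ndim != 4:
            raise ValidationError("multi-echo data must be 4-D (x, y, z, echo)")
        if self.data.shape[-1] != self.te_ms.size:
            raise ValidationError(
                f"echo dimension {self.data.shape[-1]} does not match "
                f"len(te_ms) = {self.te_ms.size}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ParameterMaps:
    """Fitted S0 / T2* / NRMSE grids sharing the input geometry.

    Voxels outside the mask, or where the fit failed, carry NaN and
    ``converged = False``.
    """

    t2star_ms: np.ndarray
    s0: np.ndarray
    nrmse: np.ndarray
    converged: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    n_failed: int = 0

    def __post_init__(self) -> None:
        shapes = {self.t2star_ms.shape, self.s0.shape, self.nrmse.shape, self.converged.shape}
        if len(shapes) != 1:
            raise GeometryError("parameter map grids must share one shape")


class RegionSummary(NamedTuple):
    median_t2star_ms: float
    median_nrmse: float
    n_voxels: int


def loglinear_init(signal: np.ndarray, te_ms: np.ndarray) -> tuple[float, float]:
    """Log-linear (OLS of ln S on TE) starting estimate for one voxel.

    Nonpositive samples are excluded.  If fewer than two usable samples
    remain, or the fitted slope is nonnegative (no decay), the fallback
    ``(max(signal), 10 ms)`` is returned instead of raising.
    """
    s = np.asarray(signal, dtype=float)
    te = _check_te(te_ms)
    if s.shape != te.shape:
        raise ValidationError("signal and te_ms must have equal length")
    usable = s > 0
    fallback = (float(s.max(initial=0.0)), FALLBACK_T2STAR_MS)
    if usable.sum() < 2:
        return fallback
    x, y = te[usable], np.log(s[usable])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        return fallback
    return float(np.exp(intercept)), float(-1.0 / slope)


def _projected_gain(Y: np.ndarray, te: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Variable-projection objective gain a^2/b per voxel for per-voxel T2*.

    ``Y`` is (N, K), ``t2`` is (N,).  Maximizing the gain minimizes the SSR
    since SSR = sum(y^2) - a^2/b with a = sum(y w), b = sum(w^2),
    w = exp(-TE/T2*).  A nonpositive ``a`` implies the constrained optimum
    S0 -> 0, i.e. zero gain.
    """
    w = np.exp(-te[None, :] / t2[:, None])
    a = np.einsum("nk,nk->n", Y, w)
    b = np.einsum("nk,nk->n", w, w)
    return np.where(a > 0, a * a / b, 0.0)


def fit_monoexponential(
    vol: MultiEchoVolume,
    mask: np.ndarray,
    t2star_bounds_ms: tuple[float, float] = T2STAR_BOUNDS_MS,
) -> ParameterMaps:
    """Fit S(TE) = S0 exp(-TE/T2*) at every masked voxel.

    Minimizes the sum of squared residuals over (S0 > 0,
    T2* in ``t2star_bounds_ms``).  Unmasked voxels are left as NaN with
    ``converged = False``; voxels with no positive-signal solution are
    flagged failed and counted in ``n_failed``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape3d:
        raise GeometryError(
            f"mask shape {mask.shape} does not match volume shape {vol.shape3d}"
        )
    lo, hi = t2star_bounds_ms
    if not (0 < lo < hi):
        raise ValidationError("t2star_bounds_ms must satisfy 0 < lo < hi")

    te = vol.te_ms
    K = te.size
    Y = vol.data[mask]  # (N, K)
    N = Y.shape[0]

    shape = vol.shape3d
    t2_map = np.full(shape, np.nan)
    s0_map = np.full(shape, np.nan)
    nrmse_map = np.full(shape, np.nan)
    conv_map = np.zeros(shape, dtype=bool)

    if N > 0:
        # global coarse search on a log-spaced T2* grid
        grid = np.geomspace(lo, hi, _N_GRID)
        W = np.exp(-te[None, :] / grid[:, None])  # (G, K)
        gain = Y @ W.T  # a terms, (N, G)
        np.maximum(gain, 0.0, out=gain)
        gain = gain * gain / (W * W).sum(axis=1)[None, :]
        best = np.argmax(gain, axis=1)

        # refine inside the bracketing grid cells (log scale, ternary search)
        a = np.log(grid[np.maximum(best - 1, 0)])
        b = np.log(grid[np.minimum(best + 1, _N_GRID - 1)])
        for _ in range(_N_REFINE):
            m1 = a + (b - a) / 3.0
            m2 = b - (b - a) / 3.0
            f1 = _projected_gain(Y, te, np.exp(m1))
            f2 = _projected_gain(Y, te, np.exp(m2))
            take_right = f1 < f2
            a = np.where(take_right, m1, a)
            b = np.where(take_right, b, m2)

        t2 = np.exp(0.5 * (a + b))
        w = np.exp(-te[None, :] / t2[:, None])
        num = np.einsum("nk,nk->n", Y, w)
        den = np.einsum("nk,nk->n", w, w)
        s0 = num / den
        ssr = np.maximum(np.einsum("nk,nk->n", Y, Y) - num * num / den, 0.0)
        ok = (s0 > 0) & np.isfinite(s0)
        nrmse = np.full(N, np.nan)
        nrmse[ok] = np.sqrt(ssr[ok] / K) / s0[ok]

        t2_map[mask] = np.where(ok, t2, np.nan)
        s0_map[mask] = np.where(ok, s0, np.nan)
        nrmse_map[mask] = nrmse
        conv_map[mask] = ok

    n_failed = int(mask.sum() - conv_map.sum())
    return ParameterMaps(
        t2star_ms=t2_map,
        s0=s0_map,
        nrmse=nrmse_map,
        converged=conv_map,
        voxel_size_mm=vol.voxel_size_mm,
        affine=vol.affine,
        n_failed=n_failed,
    )


def median_t2star(maps: ParameterMaps, region_mask: np.ndarray) -> RegionSummary:
    """Median T2* (and NRMSE, voxel count) over the converged voxels of a region.

    The median of an even count is the mean of the two central order
    statistics.  An empty region (after convergence filtering) raises
    :class:`EmptyRegionError`.
    """
    region_mask = np.asarray(region_mask).astype(bool)
    if region_mask.shape != maps.t2star_ms.shape:
        raise GeometryError("region mask shape does not match parameter maps")
    included = region_mask & maps.converged
    n = int(included.sum())
    if n == 0:
        raise EmptyRegionError("region contains no converged voxels")
    return RegionSummary(
        median_t2star_ms=float(np.median(maps.t2star_ms[included])),
        median_nrmse=float(np.median(maps.nrmse[included])),
        n_voxels=n,
    )
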