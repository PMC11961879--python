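"""3D gamma-index analysis between a reference and an evaluated dose.

For every reference voxel above the low-dose threshold the gamma index is

    γ(r) = min over r' of sqrt( ‖r − r'‖² / Δd²  +  (D_eval(r') − D_ref(r))² / ΔD² )

with Δd the distance-to-agreement criterion (mm) and ΔD the dose criterion:
a percentage of the reference maximum under global normalization, or of the
local reference dose under local normalization.  The search runs over
candidate points within ``search_radius_factor × Δd`` of each voxel, with
the evaluated dose trilinearly refined on a ``1/subdivision`` voxel grid.
The passing rate (GPR) is the percentage of evaluated voxels with γ ≤ 1
(boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import VolumeGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_map", "gpr", "pass_fail"]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma evaluation settings (defaults: 3%/3 mm global, 10% threshold)."""

    dose_criterion: float = 3.0        # % of normalization dose
    distance_criterion: float = 3.0    # mm
    low_dose_threshold: float = 10.0   # % of reference max
    normalization: str = "global"      # "global" | "local"
    pass_threshold: float = 90.0       # % GPR for pass/fail
    search_radius_factor: float = 3.0  # search radius in multiples of Δd
    subdivision: int = 3               # sub-voxel refinement factor

    def validate(self) -> None:
        if self.dose_criterion <= 0 or self.distance_criterion <= 0:
            raise ValueError("dose and distance criteria must be positive")
        if self.low_dose_threshold < 0 or self.pass_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.normalization not in ("global", "local"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.search_radius_factor < 0:
            raise ValueError("search_radius_factor must be >= 0")
        if self.subdivision < 1:
            raise ValueError("subdivision must be >= 1")


@dataclass
class GammaResult:
    """Per-voxel gamma values, the evaluated-voxel mask and the passing rate.

    ``gamma`` holds NaN at voxels below the low-dose threshold; those voxels
    are excluded from the GPR.
    """

    gamma: np.ndarray
    evaluated: np.ndarray
    gpr: float
    pass_fail: bool
    criteria: GammaCriteria

    @property
    def n_evaluated(self) -> int:
        return int(self.evaluated.sum())


def _offsets_mm(crit: GammaCriteria, spacing) -> np.ndarray:
    """Candidate displacement vectors (mm), sorted by length, zero first."""
    radius = crit.search_radius_factor * crit.distance_criterion
    axes = []
    for s in spacing:
        step = s / crit.subdivision
        n = int(np.floor(radius / step + 1e-9))
        axes.append(np.arange(-n, n + 1) * step)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    offs = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    d2 = np.sum(offs**2, axis=1)
    keep = d2 <= radius**2 + 1e-9
    offs, d2 = offs[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offs[order]


def gamma_map(ref: VolumeGrid, evl: VolumeGrid, crit: GammaCriteria | None = None) -> GammaResult:
    """Gamma index of ``evl`` against ``ref`` on the shared grid.

    Both volumes must be on the same grid (resample upstream).  Candidate
    points that fall outside the evaluated grid are skipped.  Offsets are
    visited nearest-first with early termination once the pure distance term
    exceeds every remaining voxel's current minimum.
    """
    crit = crit if crit is not None else GammaCriteria()
    crit.validate()
    ref.require_same_geometry(evl, "reference and evaluated dose")
    ref_d = np.asarray(ref.data, dtype=np.float64)
    evl_d = np.asarray(evl.data, dtype=np.float64)
    spacing = np.asarray(ref.spacing, dtype=float)
    ref_max = float(ref_d.max())
    if ref_max <= 0:
        raise ValueError("reference volume has no positive dose")

    evaluated = ref_d >= crit.low_dose_threshold / 100.0 * ref_max
    if not evaluated.any():
        raise ValueError("no reference voxel exceeds the low-dose threshold")

    if crit.normalization == "global":
        dd_abs = np.full_like(ref_d, crit.dose_criterion / 100.0 * ref_max)
    else:
        dd_abs = crit.dose_criterion / 100.0 * ref_d
        dd_abs[~evaluated] = np.inf  # not used; avoids divide-by-zero

    dta2 = crit.distance_criterion**2
    shape = ref_d.shape
    gam2 = np.full(shape, np.inf)

    base_idx = [np.arange(n, dtype=float) for n in shape]
    for off in _offsets_mm(crit, spacing):
        dist_term = float(np.sum(off**2)) / dta2
        running_max = np.max(gam2[evaluated])
        if dist_term >= running_max:
            break
        voxel_off = off / spacing
        if np.allclose(voxel_off, np.round(voxel_off), atol=1e-9):
            shifted, valid = _integer_shift(evl_d, np.round(voxel_off).astype(int))
        else:
            shifted, valid = _fractional_shift(evl_d, base_idx, voxel_off)
        dose_term = (shifted - ref_d) ** 2 / dd_abs**2
        cand = dist_term + dose_term
        cand[~valid] = np.inf
        np.minimum(gam2, cand, out=gam2)

    gamma = np.sqrt(gam2)
    gamma[~evaluated] = np.nan
    rate = gpr_from_map(gamma, evaluated)
    return GammaResult(
        gamma=gamma,
        evaluated=evaluated,
        gpr=rate,
        pass_fail=bool(rate >= crit.pass_threshold),
        criteria=crit,
    )


def _integer_shift(evl_d: np.ndarray, shift: np.ndarray):
    """Values of ``evl_d`` at voxel + shift; validity mask for in-grid points."""
    shape = evl_d.shape
    shifted = np.zeros_like(evl_d)
    valid = np.zeros(shape, dtype=bool)
    src = []
    dst = []
    for ax in range(3):
        s = int(shift[ax])
        n = shape[ax]
        if abs(s) >= n:
            return shifted, valid
        if s >= 0:
            dst.append(slice(0, n - s))
            src.append(slice(s, n))
        else:
            dst.append(slice(-s, n))
            src.append(slice(0, n + s))
    shifted[tuple(dst)] = evl_d[tuple(src)]
    valid[tuple(dst)] = True
    return shifted, valid


def _fractional_shift(evl_d: np.ndarray, base_idx, voxel_off: np.ndarray):
    """Trilinear interpolation of ``evl_d`` at voxel + fractional shift."""
    cs = [base_idx[i] + voxel_off[i] for i in range(3)]
    ok = [(c >= -1e-9) & (c <= evl_d.shape[i] - 1 + 1e-9) for i, c in enumerate(cs)]
    valid = ok[0][:, None, None] & ok[1][None, :, None] & ok[2][None, None, :]
    grid = np.meshgrid(*cs, indexing="ij")
    shifted = ndimage.map_coordinates(evl_d, grid, order=1, mode="nearest", prefilter=False)
    return shifted, valid


def gpr_from_map(gamma: np.ndarray, evaluated: np.ndarray) -> float:
    vals = gamma[evaluated]
    return float(100.0 * np.mean(vals <= 1.0))


def gpr(result: GammaResult) -> float:
    """Gamma passing rate (%) over the evaluated voxels."""
    return result.gpr


def pass_fail(rate: float, crit: GammaCriteria | None = None) -> bool:
    """Plan passes iff GPR >= pass_threshold (boundary inclusive)."""
    crit = crit if crit is not None else GammaCriteria()
    return bool(rate >= crit.pass_threshold)
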