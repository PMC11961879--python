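"""Volume-level dose similarity metrics, difference maps and line profiles.

MAE and RMSE are reported in Gy.  PSNR uses the ground-truth maximum as the
peak (dose has no canonical dynamic range); a perfect match is reported as
``inf``.  SSIM uses 7x7x7 uniform windows with the standard stabilizers
(0.01 L)^2 and (0.03 L)^2, L = max(gt) − min(gt); UQI is the
zero-stabilizer special case on 8x8x8 windows.  SSIM/UQI/PSNR treat the
first argument as the reference; MAE/RMSE are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .core import VolumeGrid

__all__ = [
    "MetricReport",
    "mae",
    "rmse",
    "psnr",
    "ssim",
    "uqi",
    "diff_map",
    "profile",
    "metric_report",
]


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, VolumeGrid) and isinstance(b, VolumeGrid):
        a.require_same_geometry(b)
        a, b = a.data, b.data
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


@dataclass(frozen=True)
class MetricReport:
    """All five similarity metrics for one (reference, prediction) pair."""

    mae: float   # Gy
    rmse: float  # Gy
    psnr: float  # dB; inf on perfect match
    ssim: float
    uqi: float

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "psnr": self.psnr,
                "ssim": self.ssim, "uqi": self.uqi}


def mae(a, b) -> float:
    """Mean absolute difference (Gy)."""
    a, b = _pair(a, b)
    return float(np.mean(np.abs(a - b)))


def rmse(a, b) -> float:
    """Root mean square difference (Gy)."""
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(gt, pred) -> float:
    """20·log10(max(gt) / RMSE) in dB; ``inf`` when the volumes coincide."""
    g, p = _pair(gt, pred)
    peak = float(np.max(g))
    if peak <= 0:
        raise ValueError("PSNR undefined for a non-positive reference volume")
    r = rmse(g, p)
    if r == 0.0:
        return float("inf")
    return float(20.0 * np.log10(peak / r))


def _local_stats(x: np.ndarray, win: int):
    """Full-window local mean and mean-of-squares (interior region only)."""
    mx = uniform_filter(x, size=win, mode="constant")
    mx2 = uniform_filter(x * x, size=win, mode="constant")
    lo = win // 2
    hi_off = win - 1 - lo  # asymmetric for even windows
    sl = tuple(slice(lo, n - hi_off) for n in x.shape)
    return mx[sl], mx2[sl]


def _local_cross(x: np.ndarray, y: np.ndarray, win: int):
    mxy = uniform_filter(x * y, size=win, mode="constant")
    lo = win // 2
    hi_off = win - 1 - lo
    sl = tuple(slice(lo, n - hi_off) for n in x.shape)
    return mxy[sl]


def ssim(gt, pred, window: int = 7) -> float:
    """Mean local structural similarity over full sliding windows."""
    g, p = _pair(gt, pred)
    if any(n < window for n in g.shape):
        raise ValueError(f"volume shape {g.shape} smaller than SSIM window {window}")
    L = float(np.max(g) - np.min(g))
    if L == 0.0:
        return 1.0 if np.array_equal(g, p) else 0.0
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mg, mg2 = _local_stats(g, window)
    mp, mp2 = _local_stats(p, window)
    mgp = _local_cross(g, p, window)
    vg = mg2 - mg * mg
    vp = mp2 - mp * mp
    cov = mgp - mg * mp
    num = (2 * mg * mp + c1) * (2 * cov + c2)
    den = (mg * mg + mp * mp + c1) * (vg + vp + c2)
    return float(np.mean(num / den))


def uqi(gt, pred, window: int = 8) -> float:
    """Universal quality index: SSIM with zero stabilizers on 8^3 windows.

    Windows with a vanishing denominator are undefined and are dropped from
    the average; if every window is degenerate the result is 1.0 for
    identical volumes and 0.0 otherwise.
    """
    g, p = _pair(gt, pred)
    if any(n < window for n in g.shape):
        raise ValueError(f"volume shape {g.shape} smaller than UQI window {window}")
    mg, mg2 = _local_stats(g, window)
    mp, mp2 = _local_stats(p, window)
    mgp = _local_cross(g, p, window)
    vg = mg2 - mg * mg
    vp = mp2 - mp * mp
    cov = mgp - mg * mp
    num = 4.0 * cov * mg * mp
    den = (vg + vp) * (mg * mg + mp * mp)
    scale = max(float(np.max(np.abs(den))), 1.0)
    valid = np.abs(den) > 1e-12 * scale
    if not valid.any():
        return 1.0 if np.array_equal(g, p) else 0.0
    return float(np.mean(num[valid] / den[valid]))


def diff_map(gt, pred):
    """Signed voxelwise difference ``pred − gt``."""
    if isinstance(gt, VolumeGrid):
        g, p = _pair(gt, pred)
        return gt.copy_with(p - g)
    g, p = _pair(gt, pred)
    return p - g


def profile(volume, axis: int, index: tuple[int, int]) -> np.ndarray:
    """Extract one grid line along ``axis`` at the fixed off-axis ``index``.

    ``index`` gives the two remaining coordinates in (z, y, x) order with
    ``axis`` removed, e.g. ``profile(v, axis=2, index=(k, j))`` is row
    ``v[k, j, :]``.
    """
    data = volume.data if isinstance(volume, VolumeGrid) else np.asarray(volume)
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    sel: list = list(index)
    sel.insert(axis, slice(None))
    return data[tuple(sel)].copy()


def metric_report(gt, pred) -> MetricReport:
    """Compute all five metrics of one prediction against its reference."""
    return MetricReport(
        mae=mae(gt, pred),
        rmse=rmse(gt, pred),
        psnr=psnr(gt, pred),
        ssim=ssim(gt, pred),
        uqi=uqi(gt, pred),
    )
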