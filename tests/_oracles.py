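"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a quantity from its definition (explicit
loops, exhaustive search, sort-and-count), deliberately sharing no code with
the production implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_gamma(ref_data, evl_data, spacing, dose_pct, dist_mm, threshold_pct,
                radius_factor=3.0, normalization="global"):
    """Exhaustive per-voxel gamma search over integer voxel offsets.

    Returns the gamma map (NaN below threshold).  Matches a production run
    with subdivision 1.
    """
    rd = np.asarray(ref_data, dtype=float)
    ed = np.asarray(evl_data, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    rmax = rd.max()
    radius = radius_factor * dist_mm
    shape = rd.shape
    nmax = [int(np.floor(radius / s + 1e-9)) for s in sp]
    offsets = [
        o
        for o in itertools.product(*[range(-n, n + 1) for n in nmax])
        if sum((o[i] * sp[i]) ** 2 for i in range(3)) <= radius**2 + 1e-9
    ]
    gamma = np.full(shape, np.nan)
    thresh = threshold_pct / 100.0 * rmax
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if rd[z, y, x] < thresh:
                    continue
                if normalization == "global":
                    dd = dose_pct / 100.0 * rmax
                else:
                    dd = dose_pct / 100.0 * rd[z, y, x]
                best = np.inf
                for o in offsets:
                    zz, yy, xx = z + o[0], y + o[1], x + o[2]
                    if not (0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]):
                        continue
                    d2 = sum((o[i] * sp[i]) ** 2 for i in range(3))
                    g2 = d2 / dist_mm**2 + (ed[zz, yy, xx] - rd[z, y, x]) ** 2 / dd**2
                    if g2 < best:
                        best = g2
                gamma[z, y, x] = np.sqrt(best)
    return gamma


def brute_gpr(gamma_map_arr):
    vals = gamma_map_arr[~np.isnan(gamma_map_arr)]
    return 100.0 * np.mean(vals <= 1.0)


def sort_and_count_dvh_metrics(doses, prescription):
    """Dmean/Dmax/D2/D50/D98/V95/V100 from first principles on raw voxels."""
    d = np.sort(np.asarray(doses, dtype=float))[::-1]  # descending
    n = d.size

    def dx(x):
        # largest dose with coverage >= x%: walk every candidate dose
        best = None
        for cand in d:
            frac = 100.0 * np.sum(d >= cand) / n
            if frac >= x and (best is None or cand > best):
                best = cand
        return best

    def vx(x):
        return 100.0 * np.sum(d >= x / 100.0 * prescription) / n

    return {
        "Dmean": d.mean(),
        "Dmax": d.max(),
        "D2": dx(2.0),
        "D50": dx(50.0),
        "D98": dx(98.0),
        "V95": vx(95.0),
        "V100": vx(100.0),
    }


def windowed_ssim(gt, pred, window, c1, c2):
    """SSIM by explicit loops over every full window position."""
    g = np.asarray(gt, dtype=float)
    p = np.asarray(pred, dtype=float)
    vals = []
    for z in range(g.shape[0] - window + 1):
        for y in range(g.shape[1] - window + 1):
            for x in range(g.shape[2] - window + 1):
                wg = g[z : z + window, y : y + window, x : x + window]
                wp = p[z : z + window, y : y + window, x : x + window]
                mg, mp = wg.mean(), wp.mean()
                vg, vp = wg.var(), wp.var()
                cov = ((wg - mg) * (wp - mp)).mean()
                num = (2 * mg * mp + c1) * (2 * cov + c2)
                den = (mg**2 + mp**2 + c1) * (vg + vp + c2)
                vals.append((num, den))
    return vals


def windowed_ssim_mean(gt, pred, window, c1, c2):
    vals = windowed_ssim(gt, pred, window, c1, c2)
    return float(np.mean([n / d for n, d in vals]))


def windowed_uqi_mean(gt, pred, window):
    """UQI (zero stabilizers) dropping degenerate windows, as defined."""
    vals = windowed_ssim(gt, pred, window, 0.0, 0.0)
    dens = np.array([d for _, d in vals])
    nums = np.array([n for n, _ in vals])
    scale = max(float(np.max(np.abs(dens))), 1.0)
    ok = np.abs(dens) > 1e-12 * scale
    if not ok.any():
        return 1.0 if np.array_equal(gt, pred) else 0.0
    return float(np.mean(nums[ok] / dens[ok]))


def trilinear_at(data, spacing, origin, point_mm):
    """Trilinear interpolation at one physical point, from the definition."""
    idx = [(point_mm[a] - origin[a]) / spacing[a] for a in range(3)]
    lo = [int(np.floor(i)) for i in idx]
    frac = [i - l for i, l in zip(idx, lo)]
    val = 0.0
    for dz, dy, dx in itertools.product((0, 1), repeat=3):
        w = (
            (1 - frac[0] if dz == 0 else frac[0])
            * (1 - frac[1] if dy == 0 else frac[1])
            * (1 - frac[2] if dx == 0 else frac[2])
        )
        z, y, x = lo[0] + dz, lo[1] + dy, lo[2] + dx
        if 0 <= z < data.shape[0] and 0 <= y < data.shape[1] and 0 <= x < data.shape[2]:
            val += w * data[z, y, x]
    return val


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar f at array x."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
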