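"""Cumulative dose-volume histograms and clinical DVH metrics.

Voxel membership is whole-voxel ("in or out"): a voxel contributes to a
structure's statistics iff its center lies inside the structure mask.
Dx (dose received by at least x% of the volume) is computed bin-free on the
raw voxel doses with the nearest-rank convention: the largest dose d such
that at least x% of the voxels receive >= d.  Vx (percent of the volume
receiving at least x% of the prescription) uses an inclusive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import StructureSet, VolumeGrid

__all__ = [
    "DVHCurve",
    "DVHMetricsReport",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "metric_report",
    "PTV_METRICS",
    "OAR_METRICS",
]

PTV_METRICS = ("Dmean", "Dmax", "D2", "D50", "D98", "V95", "V100")
OAR_METRICS = ("Dmean", "Dmax", "D50")


def _masked_doses(dose, mask) -> np.ndarray:
    data = dose.data if isinstance(dose, VolumeGrid) else np.asarray(dose)
    mask = np.asarray(mask)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} != dose shape {data.shape}")
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("structure mask is empty")
    return np.asarray(data[mask], dtype=np.float64)


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving at least each threshold.

    ``volume_pct`` starts at 100% at 0 Gy, is non-increasing, and reaches 0%
    above the maximum voxel dose.
    """

    dose_gy: np.ndarray      # ascending thresholds
    volume_pct: np.ndarray   # non-increasing, percent
    structure: str = ""
    total_voxels: int = 0

    def dose_at(self, x: float) -> float:
        """Curve-based Dx read: largest tabulated threshold with coverage >= x%."""
        ok = np.nonzero(self.volume_pct >= x)[0]
        return float(self.dose_gy[ok[-1]]) if ok.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.dose_gy, "volume_pct": self.volume_pct})


def compute_dvh(dose, mask, bin_width: float = 0.05, structure: str = "") -> DVHCurve:
    """Cumulative DVH of the masked voxels with the given bin width (Gy)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    doses = _masked_doses(dose, mask)
    n_bins = int(np.floor(doses.max() / bin_width)) + 2
    thresholds = np.arange(n_bins) * bin_width
    sorted_doses = np.sort(doses)
    # fraction of voxels with dose >= t  (inclusive)
    idx = np.searchsorted(sorted_doses, thresholds, side="left")
    pct = 100.0 * (doses.size - idx) / doses.size
    return DVHCurve(thresholds, pct, structure=structure, total_voxels=doses.size)


def dose_at_volume(dose_or_curve, mask_or_x, x: float | None = None) -> float:
    """Dx: the dose received by at least x% of the structure volume.

    Either ``dose_at_volume(curve, x)`` (tabulated read) or
    ``dose_at_volume(dose, mask, x)`` (bin-free on raw voxel doses).
    """
    if isinstance(dose_or_curve, DVHCurve):
        x = float(mask_or_x)
        _check_x(x)
        return dose_or_curve.dose_at(x)
    if x is None:
        raise TypeError("dose_at_volume(dose, mask, x) requires three arguments")
    x = float(x)
    _check_x(x)
    doses = _masked_doses(dose_or_curve, mask_or_x)
    n = doses.size
    # smallest k with k/n >= x/100; D_x is the k-th largest dose
    k = int(np.ceil(n * x / 100.0 - 1e-9))
    k = max(k, 1)
    return float(np.sort(doses)[n - k])


def _check_x(x: float) -> None:
    if not (0.0 < x <= 100.0):
        raise ValueError(f"x must be in (0, 100], got {x}")


def volume_at_dose(dose, mask, x: float, prescription: float) -> float:
    """Vx: percent of the structure receiving at least x% of the prescription."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    doses = _masked_doses(dose, mask)
    threshold = x / 100.0 * prescription
    return float(100.0 * np.mean(doses >= threshold))


def _structure_metrics(doses: np.ndarray, metrics: Sequence[str], prescription: float) -> dict:
    out = {}
    n = doses.size
    s = np.sort(doses)
    for m in metrics:
        if m == "Dmean":
            out[m] = float(doses.mean())
        elif m == "Dmax":
            out[m] = float(doses.max())
        elif m.startswith("D"):
            x = float(m[1:])
            k = max(int(np.ceil(n * x / 100.0 - 1e-9)), 1)
            out[m] = float(s[n - k])
        elif m.startswith("V"):
            x = float(m[1:])
            out[m] = float(100.0 * np.mean(doses >= x / 100.0 * prescription))
        else:
            raise ValueError(f"unknown DVH metric {m!r}")
    return out


@dataclass
class DVHMetricsReport:
    """Per-structure DVH metrics for two dose sources and their differences."""

    table: pd.DataFrame  # columns: structure, metric, reference, prediction, abs_diff

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def max_abs_diff(self) -> float:
        return float(self.table["abs_diff"].max())


def metric_report(
    gt_dose,
    pred_dose,
    structures: StructureSet,
    prescription: float,
    ptv_metrics: Sequence[str] = PTV_METRICS,
    oar_metrics: Sequence[str] = OAR_METRICS,
) -> DVHMetricsReport:
    """Tabulate clinical DVH metrics for both dose sources per structure.

    Structures whose name starts with ``PTV`` get the full target metric set
    (Dmean, Dmax, D2, D50, D98, V95, V100); all others get the OAR set.
    """
    rows = []
    for name, mask in structures.items():
        if not mask.any():
            continue
        metrics = ptv_metrics if name.lower().startswith("ptv") else oar_metrics
        g = _masked_doses(gt_dose, mask)
        p = _masked_doses(pred_dose, mask)
        gm = _structure_metrics(g, metrics, prescription)
        pm = _structure_metrics(p, metrics, prescription)
        for m in metrics:
            rows.append(
                {
                    "structure": name,
                    "metric": m,
                    "reference": gm[m],
                    "prediction": pm[m],
                    "abs_diff": abs(gm[m] - pm[m]),
                }
            )
    return DVHMetricsReport(pd.DataFrame(rows))
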