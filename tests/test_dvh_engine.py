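"""DVH curves and clinical metrics against a sort-and-count reference."""

import numpy as np
import pytest

from mdoseqa.core import StructureSet, VolumeGrid
from mdoseqa.dvh_engine import (
    DVHCurve,
    compute_dvh,
    dose_at_volume,
    metric_report,
    volume_at_dose,
)

from _oracles import sort_and_count_dvh_metrics


def _vol(data):
    return VolumeGrid(np.asarray(data, dtype=float), (3.0, 3.0, 3.0))


class TestComputeDVH:
    def test_uniform_dose(self):
        dose = _vol(np.full((4, 4, 4), 60.0))
        mask = np.ones((4, 4, 4), bool)
        curve = compute_dvh(dose, mask, bin_width=0.5)
        below = curve.dose_gy <= 60.0
        assert np.allclose(curve.volume_pct[below], 100.0)
        assert np.allclose(curve.volume_pct[~below], 0.0)

    def test_two_level_dose(self):
        data = np.zeros((2, 2, 2))
        data.flat[:4] = 20.0
        data.flat[4:] = 40.0
        curve = compute_dvh(_vol(data), np.ones((2, 2, 2), bool), bin_width=1.0)
        t = curve.dose_gy
        assert np.allclose(curve.volume_pct[t <= 20.0], 100.0)
        assert np.allclose(curve.volume_pct[(t > 20.0) & (t <= 40.0)], 50.0)
        assert np.allclose(curve.volume_pct[t > 40.0], 0.0)

    def test_curve_shape_properties(self, rng):
        for _ in range(50):
            data = rng.random((4, 4, 4)) * 70
            mask = rng.random((4, 4, 4)) > 0.3
            if not mask.any():
                continue
            curve = compute_dvh(_vol(data), mask)
            assert curve.volume_pct[0] == 100.0
            assert (np.diff(curve.volume_pct) <= 1e-12).all()
            assert curve.volume_pct[-1] == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(_vol(np.ones((2, 2, 2))), np.zeros((2, 2, 2), bool))


class TestDoseAtVolume:
    def test_uniform_dose_all_x(self):
        dose = _vol(np.full((2, 2, 2), 60.0))
        mask = np.ones((2, 2, 2), bool)
        for x in (1e-6, 2, 50, 98, 100):
            assert dose_at_volume(dose, mask, x) == 60.0

    def test_four_voxel_nearest_rank(self):
        dose = _vol(np.array([10.0, 20.0, 30.0, 40.0]).reshape(1, 2, 2))
        mask = np.ones((1, 2, 2), bool)
        assert dose_at_volume(dose, mask, 50.0) == 30.0  # exactly half receive >= 30
        assert dose_at_volume(dose, mask, 100.0) == 10.0  # minimum
        assert dose_at_volume(dose, mask, 1e-9) == 40.0  # x -> 0+ gives maximum

    def test_exhaustive_definition_check(self, rng):
        """Dx = max dose with coverage >= x, checked over all candidate doses."""
        doses = rng.random(17) * 70
        vol = _vol(np.pad(doses, (0, 1)).reshape(2, 3, 3))
        mask = np.zeros((2, 3, 3), bool)
        mask.flat[:17] = True
        for x in (2, 25, 50, 75, 98, 100):
            d = dose_at_volume(vol, mask, x)
            frac = 100.0 * np.mean(doses >= d)
            assert frac >= x - 1e-9
            better = doses[doses > d]
            for cand in better:
                assert 100.0 * np.mean(doses >= cand) < x

    def test_curve_read_within_bin(self, rng):
        doses = rng.random(50) * 70
        vol = _vol(np.pad(doses, (0, 4)).reshape(3, 3, 6))
        mask = np.zeros((3, 3, 6), bool)
        mask.flat[:50] = True
        bin_width = 0.01
        curve = compute_dvh(vol, mask, bin_width)
        for x in (2, 50, 98):
            assert dose_at_volume(curve, x) == pytest.approx(
                dose_at_volume(vol, mask, x), abs=bin_width
            )

    def test_x_out_of_range(self):
        dose = _vol(np.ones((2, 2, 2)))
        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError):
            dose_at_volume(dose, mask, 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(dose, mask, 101.0)


class TestVolumeAtDose:
    def test_uniform_equals_prescription(self):
        dose = _vol(np.full((2, 2, 2), 70.0))
        mask = np.ones((2, 2, 2), bool)
        assert volume_at_dose(dose, mask, 95.0, 70.0) == 100.0
        assert volume_at_dose(dose, mask, 100.0, 70.0) == 100.0

    def test_slightly_under_prescription(self):
        dose = _vol(np.full((2, 2, 2), 0.97 * 70.0))
        mask = np.ones((2, 2, 2), bool)
        assert volume_at_dose(dose, mask, 95.0, 70.0) == 100.0
        assert volume_at_dose(dose, mask, 100.0, 70.0) == 0.0

    def test_mixed_mask_matches_count(self, rng):
        data = rng.random((3, 3, 3)) * 80
        mask = rng.random((3, 3, 3)) > 0.4
        got = volume_at_dose(_vol(data), mask, 95.0, 70.0)
        expected = 100.0 * np.sum(data[mask] >= 66.5) / mask.sum()
        assert got == pytest.approx(expected)


class TestShiftEquivariance:
    def test_constant_shift_moves_dx_exactly(self, rng):
        data = rng.random((3, 3, 3)) * 60
        mask = np.ones((3, 3, 3), bool)
        for x in (2, 50, 98):
            d0 = dose_at_volume(_vol(data), mask, x)
            d1 = dose_at_volume(_vol(data + 5.0), mask, x)
            assert d1 == pytest.approx(d0 + 5.0, abs=1e-12)


class TestOracleEquivalence:
    def test_sort_and_count_reference(self, rng):
        """All metrics equal the exhaustive reference on 50 random small masks."""
        for _ in range(50):
            n_vox = int(rng.integers(1, 101))
            doses = rng.random(n_vox) * 80
            side = int(np.ceil(n_vox ** (1 / 3))) + 1
            data = np.zeros(side**3)
            data[:n_vox] = doses
            data = data.reshape(side, side, side)
            mask = np.zeros(side**3, bool)
            mask[:n_vox] = True
            mask = mask.reshape(side, side, side)
            vol = _vol(data)
            ref = sort_and_count_dvh_metrics(doses, 70.0)
            assert dose_at_volume(vol, mask, 2.0) == ref["D2"]
            assert dose_at_volume(vol, mask, 50.0) == ref["D50"]
            assert dose_at_volume(vol, mask, 98.0) == ref["D98"]
            assert volume_at_dose(vol, mask, 95.0, 70.0) == pytest.approx(ref["V95"])
            assert volume_at_dose(vol, mask, 100.0, 70.0) == pytest.approx(ref["V100"])
            assert np.mean(doses) == pytest.approx(ref["Dmean"])
            assert np.max(doses) == ref["Dmax"]


class TestMetricReport:
    def _structures(self, rng):
        grid = _vol(rng.random((4, 4, 4)) * 70)
        st = StructureSet(grid)
        ptv = np.zeros((4, 4, 4), bool)
        ptv[1:3, 1:3, 1:3] = True
        oar = ~ptv
        st.add("PTV7000", ptv)
        st.add("Parotid_L", oar)
        return grid, st

    def test_identical_doses_zero_diff(self, rng):
        gt, st = self._structures(rng)
        rep = metric_report(gt, gt, st, prescription=70.0)
        assert (rep.table["abs_diff"] == 0.0).all()
        assert rep.max_abs_diff() == 0.0

    def test_dx_ordering_invariant(self, rng):
        gt, st = self._structures(rng)
        pred = gt.copy_with(gt.data * (1 + 0.05 * rng.standard_normal((4, 4, 4))))
        rep = metric_report(gt, pred, st, prescription=70.0)
        ptv = rep.table[rep.table.structure == "PTV7000"].set_index("metric")
        for col in ("reference", "prediction"):
            assert ptv.loc["D98", col] <= ptv.loc["D50", col] <= ptv.loc["D2", col]
            assert ptv.loc["D2", col] <= ptv.loc["Dmax", col]
            assert ptv.loc["Dmean", col] <= ptv.loc["Dmax", col]

    def test_toy_structure_hand_computed(self):
        data = np.zeros((2, 2, 2))
        data.flat[:] = [10, 20, 30, 40, 50, 60, 70, 80]
        gt = _vol(data)
        pred = _vol(data + 1.0)
        st = StructureSet(gt)
        st.add("PTV7000", np.ones((2, 2, 2), bool))
        rep = metric_report(gt, pred, st, prescription=70.0)
        t = rep.table.set_index("metric")
        assert t.loc["Dmean", "reference"] == 45.0
        assert t.loc["Dmax", "reference"] == 80.0
        assert t.loc["D50", "reference"] == 50.0   # 4/8 receive >= 50
        assert t.loc["D98", "reference"] == 10.0
        assert t.loc["D2", "reference"] == 80.0
        assert t.loc["V95", "reference"] == pytest.approx(100.0 * 2 / 8)  # >= 66.5
        assert t.loc["V100", "reference"] == pytest.approx(100.0 * 2 / 8)  # >= 70
        assert np.allclose(t["abs_diff"][["Dmean", "Dmax", "D50", "D98", "D2"]], 1.0)
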