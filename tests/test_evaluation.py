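"""Image metrics, ROI analysis, DVH extraction and paired statistics
against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from cyclesct import evaluation as E
from cyclesct.core import PhaseVolume


def oracle_ssim(x, y, c1=400.0, c2=3600.0):
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(), y.std()
    return ((2 * mx * my + c1) * (2 * sx * sy + c2)) / \
        ((mx ** 2 + my ** 2 + c1) * (sx ** 2 + sy ** 2 + c2))


class TestSSIM:
    def test_identity_is_one(self, rng):
        x = rng.uniform(-1000, 1000, (32, 32))
        assert E.ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_equal_constants_is_one(self):
        x = np.full((16, 16), 123.0)
        assert E.ssim(x, x.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_formula_oracle(self, rng):
        for _ in range(10):
            x = rng.uniform(-1000, 2000, (32, 32))
            y = rng.uniform(-1000, 2000, (32, 32))
            assert E.ssim(x, y) == pytest.approx(oracle_ssim(x, y), rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            E.ssim(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPSNR:
    def test_identical_images_infinite(self, rng):
        x = rng.uniform(size=(8, 8))
        assert np.isinf(E.psnr(x, x))

    def test_zero_db_case(self):
        x = np.full((8, 8), 4095.0)
        y = x - 4095.0
        assert E.psnr(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_log_oracle(self, rng):
        for _ in range(10):
            x = rng.uniform(-500, 3000, (16, 16))
            y = rng.uniform(-500, 3000, (16, 16))
            expected = 10 * np.log10(np.max(np.abs(x)) ** 2) \
                - 10 * np.log10(np.mean((x - y) ** 2))
            assert E.psnr(x, y) == pytest.approx(expected, rel=1e-10)

    def test_fixed_peak_option(self, rng):
        x = rng.uniform(0, 100, (8, 8))
        y = x + 10
        expected = 10 * np.log10(4095.0 ** 2 / 100.0)
        assert E.psnr(x, y, peak=4095.0) == pytest.approx(expected, rel=1e-10)


class TestMEMAE:
    def test_constant_shift(self, rng):
        y = rng.uniform(size=(8, 8))
        assert E.me(y + 10, y) == pytest.approx(10.0)
        assert E.mae(y + 10, y) == pytest.approx(10.0)

    def test_alternating_errors(self):
        y = np.zeros((4, 4))
        x = np.indices((4, 4)).sum(axis=0) % 2 * 10.0 - 5.0
        assert E.me(x, y) == pytest.approx(0.0)
        assert E.mae(x, y) == pytest.approx(5.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.uniform(-100, 100, (12, 12))
        y = rng.uniform(-100, 100, (12, 12))
        me_loop = sum(x[i, j] - y[i, j] for i in range(12) for j in range(12)) / 144
        mae_loop = sum(abs(x[i, j] - y[i, j]) for i in range(12) for j in range(12)) / 144
        assert E.me(x, y) == pytest.approx(me_loop, abs=1e-12)
        assert E.mae(x, y) == pytest.approx(mae_loop, abs=1e-12)


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        x = rng.uniform(-1000, 3000, (32, 32))
        assert E.mutual_information(x, x) == pytest.approx(E.entropy_of(x),
                                                           abs=1e-12)

    def test_inverted_checkerboard_two_bins(self):
        board = (np.indices((16, 16)).sum(axis=0) % 2).astype(float)
        x = np.where(board > 0, 3095.0, -1000.0)
        y = np.where(board > 0, -1000.0, 3095.0)
        assert E.mutual_information(x, y, bins=2) == pytest.approx(np.log(2),
                                                                   abs=1e-12)

    def test_symmetry(self, rng):
        x = rng.uniform(-1000, 3000, (16, 16))
        y = rng.uniform(-1000, 3000, (16, 16))
        assert E.mutual_information(x, y) == pytest.approx(
            E.mutual_information(y, x), abs=1e-12)

    def test_non_negative(self, rng):
        for _ in range(5):
            x = rng.uniform(-1000, 3000, (16, 16))
            y = rng.uniform(-1000, 3000, (16, 16))
            assert E.mutual_information(x, y) >= -1e-12

    def test_too_few_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            E.mutual_information(np.zeros((4, 4)), np.zeros((4, 4)), bins=1)


class TestROI:
    def test_constant_roi(self):
        img = np.full((64, 64), 100.0)
        roi = E.ROISpec(tissue="bone", center=(32, 32))
        assert roi.size == 15
        assert E.roi_mean_ct(img, roi) == 100.0

    def test_gradient_roi_matches_loop_sum(self):
        img = np.arange(64 * 64, dtype=float).reshape(64, 64)
        roi = E.ROISpec(tissue="lung", center=(32, 32))
        assert roi.size == 35
        rs, cs = roi.slices(img.shape)
        loop = sum(img[r, c] for r in range(rs.start, rs.stop)
                   for c in range(cs.start, cs.stop)) / 1225
        assert E.roi_mean_ct(img, roi) == pytest.approx(loop, rel=1e-12)

    def test_self_difference_table_is_zero(self, default_ct):
        rois = [E.ROISpec("soft", (64, 64), size=9),
                E.ROISpec("lung", (58, 90), size=9)]
        table = E.roi_difference_table([default_ct], [default_ct], rois)
        assert np.allclose(table["difference"], 0.0)
        assert set(table["tissue"]) == {"soft", "lung"}

    def test_roi_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            E.roi_mean_ct(np.zeros((32, 32)), E.ROISpec("lung", (2, 2)))


class TestDVH:
    def test_uniform_dose_closed_form(self):
        dose = np.full((10, 10), 5000.0)  # 50 Gy in cGy
        mask = np.ones((10, 10), bool)
        grid = E.DoseGrid(dose=dose, spacing=(2.0, 2.0),
                          structure_masks={"PTV": mask})
        out = E.dvh_metrics(grid, "PTV", ["D98%", "D2%", "V20Gy", "V5Gy"])
        assert out["D98%"] == pytest.approx(5000.0)
        assert out["D2%"] == pytest.approx(5000.0)
        assert out["V20Gy"] == 100.0
        assert out["V5Gy"] == 100.0

    def test_linear_ramp_closed_form(self):
        n = 2000
        dose = np.linspace(0, 10000, n)  # 0..100 Gy uniformly covering the mask
        grid = E.DoseGrid(dose=dose, spacing=(1.0,),
                          structure_masks={"lung": np.ones(n, bool)})
        out = E.dvh_metrics(grid, "lung", ["V20Gy", "V5Gy", "D2%", "D98%", "V0Gy"])
        assert out["V20Gy"] == pytest.approx(80.0, abs=0.2)
        assert out["V5Gy"] == pytest.approx(95.0, abs=0.2)
        assert out["D2%"] == pytest.approx(9800.0, abs=20.0)
        assert out["D98%"] == pytest.approx(200.0, abs=20.0)
        assert out["V0Gy"] == 100.0

    def test_monotonicity(self, rng):
        dose = rng.uniform(0, 7000, 500)
        grid = E.DoseGrid(dose=dose, spacing=(1.0,),
                          structure_masks={"m": np.ones(500, bool)})
        vs = [E.dvh_metrics(grid, "m", [f"V{y}Gy"])[f"V{y}Gy"]
              for y in (0, 10, 20, 40, 60)]
        assert all(a >= b for a, b in zip(vs, vs[1:]))
        ds = [E.dvh_metrics(grid, "m", [f"D{x}%"])[f"D{x}%"]
              for x in (2, 25, 50, 75, 98)]
        assert all(a >= b for a, b in zip(ds, ds[1:]))

    def test_empty_mask_rejected(self):
        grid = E.DoseGrid(dose=np.ones(5), spacing=(1.0,),
                          structure_masks={"m": np.zeros(5, bool)})
        with pytest.raises(ValueError):
            E.dvh_metrics(grid, "m", ["D2%"])


class TestRPD:
    def test_equal_values_zero(self):
        assert E.rpd(60.0, 60.0) == 0.0

    def test_worked_example(self):
        assert E.rpd(60.0, 40.0) == pytest.approx(40.0)

    def test_symmetry(self, rng):
        for _ in range(5):
            a, f = rng.uniform(1, 100, 2)
            assert E.rpd(a, f) == pytest.approx(E.rpd(f, a), rel=1e-12)

    def test_degenerate_sum_flagged_as_nan(self):
        assert np.isnan(E.rpd(5.0, -5.0))


class TestPairedTest:
    def test_identical_samples_degenerate_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = E.paired_test(a, a.copy())
        assert not res.significant and res.degenerate and res.p == 1.0

    def test_constant_offset_zero_variance_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        res = E.paired_test(a + 5.0, a)
        assert res.significant and res.degenerate and res.p == 0.0

    def test_matches_formula_and_cdf_oracle(self):
        a = np.array([30.02, 29.99, 30.11, 29.97, 30.01])
        b = np.array([29.89, 29.93, 29.72, 29.98, 30.02])
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df=len(d) - 1)
        res = E.paired_test(a, b)
        assert res.t == pytest.approx(t_oracle, abs=1e-8)
        assert res.p == pytest.approx(p_oracle, abs=1e-8)

    def test_threshold_boundary_strict(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + np.array([0.5, 0.4, 0.6, 0.5, 0.45])
        p = E.paired_test(a, b, threshold=1.0).p
        assert E.paired_test(a, b, threshold=p + 1e-9).significant
        assert not E.paired_test(a, b, threshold=p - 1e-9).significant
        assert not E.paired_test(a, b, threshold=p).significant  # strict <


class TestEvaluatePairwise:
    @staticmethod
    def phases(rng, n=3, offset=0.0):
        ref = [PhaseVolume(voxels=rng.uniform(0, 1500, (32, 32)), phase=p,
                           spacing=(2.0, 2.0)) for p in range(n)]
        ev = [PhaseVolume(voxels=r.voxels + offset, phase=r.phase,
                          spacing=(2.0, 2.0), modality="CBCT") for r in ref]
        return ev, ref

    def test_reference_vs_itself(self, rng):
        _, ref = self.phases(rng)
        rep = E.evaluate_pairwise(ref, ref)
        assert rep.ssim == pytest.approx(1.0, abs=1e-12)
        assert rep.me == 0.0 and rep.mae == 0.0
        assert rep.psnr_infinite
        assert rep.mi == pytest.approx(
            np.mean([E.entropy_of(r.voxels) for r in ref]), abs=1e-12)

    def test_injected_offset_recovered(self, rng):
        ev, ref = self.phases(rng, offset=-100.0)
        rep = E.evaluate_pairwise(ev, ref)
        assert rep.me == pytest.approx(-100.0, abs=1.0)

    def test_pooled_equals_mean_of_phases(self, rng):
        ev, ref = self.phases(rng, offset=25.0)
        rep = E.evaluate_pairwise(ev, ref)
        assert rep.mae == pytest.approx(rep.per_phase["mae"].mean(), rel=1e-12)
        assert rep.ssim == pytest.approx(rep.per_phase["ssim"].mean(), rel=1e-12)

    def test_blending_toward_reference_improves_metrics(self, rng, default_ct):
        """Convex blends toward the reference decrease MAE, increase SSIM."""
        from cyclesct import phantom as P
        degraded = P.simulate_cbct_phase(P.PhantomSpec(), 0, seed=1).voxels
        ref = default_ct.voxels
        maes, ssims = [], []
        for alpha in (0.0, 0.5, 1.0):
            blend = (1 - alpha) * degraded + alpha * ref
            maes.append(E.mae(blend, ref))
            ssims.append(E.ssim(blend, ref))
        assert maes[0] > maes[1] > maes[2]
        assert ssims[0] < ssims[1] < ssims[2]

    def test_geometry_mismatch_rejected(self, rng):
        ev, ref = self.phases(rng)
        bad = [PhaseVolume(voxels=np.zeros((16, 16)), phase=0, spacing=(2.0, 2.0))]
        with pytest.raises(ValueError):
            E.evaluate_pairwise(bad, ref[:1])
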