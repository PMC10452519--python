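"""Statistical battery: hand-worked oracles, enumeration oracles, and
multiplicity-correction properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats as sps

import tmstarget as tt
from tmstarget.stats import holm_adjust, interpolate_volume, median_roi_dose


class TestMedianDose:
    def test_uniform_field(self, default_head):
        mask = tt.build_dlpfc_mask(default_head)
        vol = np.full(default_head.gm_grid.data.shape, 42.0)
        assert median_roi_dose(vol, mask) == pytest.approx(42.0)

    def test_equals_sort_based_oracle(self, default_head):
        mask = tt.build_dlpfc_mask(default_head)
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 200, default_head.gm_grid.data.shape)
        vals = np.sort(vol[mask.data])
        n = len(vals)
        expected = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
        assert median_roi_dose(vol, mask) == pytest.approx(expected)

    def test_robust_to_single_spike(self, default_head):
        mask = tt.build_dlpfc_mask(default_head)
        vol = np.full(default_head.gm_grid.data.shape, 10.0)
        med0 = median_roi_dose(vol, mask)
        idx = tuple(np.argwhere(mask.data)[0])
        vol[idx] = 1e6
        assert median_roi_dose(vol, mask) == pytest.approx(med0)
        assert vol[mask.data].mean() > 10 * med0  # the mean is not robust

    def test_interpolation_path(self, default_head):
        mask = tt.build_dlpfc_mask(default_head)
        grid = default_head.gm_grid
        # linear-in-y field interpolates exactly under trilinear interpolation
        centers = grid.voxel_centers(member_only=False).reshape(*grid.data.shape, 3)
        vol = 2.0 * centers[..., 1] + 5.0
        shifted = grid.affine.copy()
        got = median_roi_dose(vol, mask, affine=shifted + 0.0)
        expected = np.median(2.0 * mask.voxel_centers[:, 1] + 5.0)
        assert got == pytest.approx(expected)
        vals = interpolate_volume(vol, grid.affine, mask.voxel_centers)
        assert np.allclose(vals, 2.0 * mask.voxel_centers[:, 1] + 5.0)


class TestFriedman:
    def test_identical_columns_zero(self):
        m = np.tile(np.arange(5, dtype=float)[:, None], (1, 4))
        chi2, p = tt.friedman_test(m)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_worked_three_by_three(self):
        # ranks per row: [1,2,3],[1,3,2],[1,2,3] -> rank sums [3,7,8]
        # chi2 = 12/(n k (k+1)) * sum Rj^2 - 3 n (k+1) = 12/36*122 - 36
        m = np.array([[1.0, 2.0, 3.0], [10.0, 30.0, 20.0], [2.0, 4.0, 9.0]])
        chi2, _ = tt.friedman_test(m)
        assert chi2 == pytest.approx(12 / 36 * (9 + 49 + 64) - 36)

    def test_perfectly_concordant_rows_reach_maximum(self):
        # every subject orders the four methods identically: chi2 = n(k-1)
        rng = np.random.default_rng(0)
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = base[None, :] * rng.uniform(0.5, 2.0, (9, 1))
        chi2, p = tt.friedman_test(m)
        assert chi2 == pytest.approx(9 * 3)
        assert chi2 > 24.7  # any real-data value is bounded by this maximum
        assert p < 0.001

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            tt.friedman_test(m)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_invariant_under_monotone_row_transforms(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(6, 4))
        chi2a, _ = tt.friedman_test(m)
        chi2b, _ = tt.friedman_test(np.exp(m))  # strictly monotone
        assert chi2a == pytest.approx(chi2b)


class TestWilcoxonHolm:
    def test_exact_small_sample_enumeration(self):
        # n=6, all differences positive: two-sided p = 2/2^6
        a = np.array([5.0, 6, 7, 8, 9, 10])
        b = a - np.array([1.1, 0.9, 1.3, 0.7, 1.2, 1.4])
        df = tt.pairwise_wilcoxon_holm(np.column_stack([a, b]), labels=["a", "b"])
        assert df["p_raw"][0] == pytest.approx(2 / 64)

    def test_identical_columns_give_p_one(self):
        a = np.arange(6, dtype=float)
        with pytest.warns(UserWarning):
            df = tt.pairwise_wilcoxon_holm(np.column_stack([a, a]))
        assert df["p_raw"][0] == 1.0

    def test_holm_hand_worked(self):
        adj = holm_adjust(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    def test_holm_dominates_raw_and_is_monotone(self, pvals):
        p = np.array(pvals)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj <= 1.0).all()

    def test_all_pairs_reported(self):
        rng = np.random.default_rng(0)
        df = tt.pairwise_wilcoxon_holm(rng.normal(size=(8, 4)), labels=list("wxyz"))
        assert len(df) == 6
        assert (df["p_holm"] >= df["p_raw"]).all()


class TestBartlett:
    def test_equal_sample_variances_give_zero(self):
        a = np.array([1.0, 2, 3, 4])
        cols = [a, a + 10, a - 3]
        k2, p = tt.bartlett_test(cols)
        assert k2 == pytest.approx(0.0, abs=1e-12)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(1)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(0, 2, 10)
        k2, _ = tt.bartlett_test([g1, g2])
        # direct evaluation of the pooled-log-variance formula
        n = 10
        s1, s2 = np.var(g1, ddof=1), np.var(g2, ddof=1)
        sp2 = ((n - 1) * s1 + (n - 1) * s2) / (2 * n - 2)
        num = (2 * n - 2) * np.log(sp2) - (n - 1) * (np.log(s1) + np.log(s2))
        den = 1 + (2 / (n - 1) - 1 / (2 * n - 2)) / (3 * 1)
        assert k2 == pytest.approx(num / den)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        cols = [rng.normal(0, s, 12) for s in (1.0, 2.0, 0.5)]
        k2a, _ = tt.bartlett_test(cols)
        k2b, _ = tt.bartlett_test([3.7 * c for c in cols])
        assert k2a == pytest.approx(k2b)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            tt.bartlett_test([np.ones(5), np.arange(5, dtype=float)])


class TestPearsonAndT:
    def test_covariance_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, _ = tt.pearson_dose_response(x, y)
        oracle = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(oracle)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tt.pearson_dose_response(np.ones(5), np.arange(5, dtype=float))

    def test_motor_threshold_summary_check(self):
        """Group mean 141.3 +/- 14.7 (n=9) vs the 135 V/m adult reference."""
        t, p = tt.t_summary(141.3, 14.7, 9, 135.0)
        assert t == pytest.approx(1.2857, abs=1e-3)  # printed as 1.30
        assert p == pytest.approx(0.2345, abs=1e-3)  # printed as 0.23

    def test_mean_equals_reference(self):
        t, p = tt.t_summary(100.0, 5.0, 10, 100.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_p_matches_quadrature_of_t_density(self):
        t, p = tt.t_summary(141.3, 14.7, 9, 135.0)
        tail, _ = integrate.quad(lambda x: sps.t.pdf(x, 8), t, np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-6)


class TestBattery:
    def test_report_structure(self):
        rng = np.random.default_rng(4)
        import pandas as pd

        table = pd.DataFrame(
            rng.uniform(40, 150, (9, 4)), columns=tt.METHODS
        )
        rep = tt.run_stats_battery(
            table,
            dose_response=(rng.uniform(80, 120, 7), rng.uniform(-30, 0, 7)),
            motor_summary=(141.3, 14.7, 9, 135.0),
        )
        d = rep.to_dict()
        assert set(d) >= {
            "friedman_chi2", "friedman_p", "pairwise_wilcoxon_holm",
            "bartlett_k2", "bartlett_p", "pearson_r_magnitude", "t_motor",
        }
        assert len(d["pairwise_wilcoxon_holm"]) == 6
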