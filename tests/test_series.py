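"""Series assembly, Mann-Whitney U and the theta-d correlation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from vesiclebud import geometry as geo
from vesiclebud import series as ser
from vesiclebud import synthetic as syn
from vesiclebud.contours import FitResult
from vesiclebud.errors import EmptySeriesError, InsufficientDataError


def two_circle_fit(r1, r2, d, cx=0.0, cy=0.0):
    return FitResult(
        shape=geo.TwoCircleShape(
            sec1=geo.Circle2D(cx, cy, r1), sec2=geo.Circle2D(cx + d, cy, r2)
        ),
        circle=None,
        rms_residual=0.0,
        n_repeats=1,
    )


def single_circle_fit(r):
    return FitResult(
        shape=None,
        circle=geo.Circle2D(0.0, 0.0, r),
        rms_residual=0.0,
        n_repeats=1,
        pre_budding=True,
    )


class TestBuildSeries:
    def test_constant_shape_all_ones(self):
        fits = [two_circle_fit(3.0, 2.0, 3.5) for _ in range(10)]
        s = ser.build_series(fits, np.arange(10.0))
        assert np.allclose(s.S_rel, 1.0)
        assert np.allclose(s.V_rel, 1.0)
        assert np.allclose(s.r1_rel, 1.0)
        assert s.S_rel[0] == 1.0 and s.V_rel[0] == 1.0 and s.r1_rel[0] == 1.0

    def test_all_dropped(self):
        fits = [two_circle_fit(3.0, 2.0, 3.5) for _ in range(5)]
        with pytest.raises(EmptySeriesError):
            ser.build_series(fits, np.arange(5.0), keep=np.zeros(5, bool))

    def test_one_kept_insufficient(self):
        fits = [two_circle_fit(3.0, 2.0, 3.5)]
        with pytest.raises(InsufficientDataError):
            ser.build_series(fits, np.array([0.0]))

    def test_mixed_pre_budding(self):
        fits = [single_circle_fit(3.0), two_circle_fit(3.0, 1.0, 2.5)]
        s = ser.build_series(fits, np.array([0.0, 1.0]))
        assert not s.has_neck[0] and s.has_neck[1]
        assert math.isnan(s.theta[0]) and math.isnan(s.d[0])
        assert s.S_rel[0] == 1.0
        assert s.S[0] == pytest.approx(4 * math.pi * 9)

    def test_calibration_scales_lengths_not_ratios(self):
        fits = [two_circle_fit(30.0, 20.0, 35.0) for _ in range(3)]
        a = ser.build_series(fits, np.arange(3.0))
        b = ser.build_series(fits, np.arange(3.0), um_per_px=0.1)
        assert np.allclose(a.S_rel, b.S_rel)
        assert b.d[0] == pytest.approx(3.5)
        assert b.S[0] == pytest.approx(a.S[0] * 0.01)

    def test_label_continuity_follows_centers(self):
        # the bud (starting smaller, at x = d) outgrows the mother; labels
        # must stick with the centers, not with size ranking
        fits = []
        for r1, r2 in [(30, 20), (28, 25), (26, 29), (24, 32)]:
            fits.append(two_circle_fit(float(r1), float(r2), 40.0))
        # decompose always reports larger radius as sec1; emulate that here
        swapped = []
        for f in fits:
            s = f.shape
            if s.sec2.r > s.sec1.r:
                s = geo.TwoCircleShape(sec1=s.sec2, sec2=s.sec1)
            swapped.append(
                FitResult(shape=s, circle=None, rms_residual=0.0, n_repeats=1)
            )
        s = ser.build_series(swapped, np.arange(4.0))
        r1_abs = s.r1_rel * 30.0
        assert np.allclose(r1_abs, [30, 28, 26, 24])
        assert np.all(np.diff(r1_abs) < 0)


class TestMannWhitney:
    def test_worked_example(self):
        res = ser.mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(1 / 3)

    def test_identical_samples(self):
        res = ser.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.U == pytest.approx(res.n1 * res.n2 / 2)
        assert res.p_two_sided == 1.0

    def test_exact_matches_scipy_tie_free(self):
        rng = np.random.default_rng(5)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (2, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            mine = ser.mann_whitney_u(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)
            assert mine.U == pytest.approx(ref.statistic)

    def test_exact_vs_enumeration_with_ties(self):
        # independent oracle: direct count over all labelings of the pooled
        # data using the pair-count definition of U
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0]
        res = ser.mann_whitney_u(x, y, mode="exact")
        pooled = np.array(x + y)
        n1 = len(x)

        def u_of(sample_x, sample_y):
            u = 0.0
            for xi in sample_x:
                for yj in sample_y:
                    u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
            return u

        u_obs = u_of(x, y)
        mu = n1 * (len(pooled) - n1) / 2
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n1):
            mask = np.zeros(len(pooled), bool)
            mask[list(combo)] = True
            u = u_of(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
        assert res.U == pytest.approx(u_obs)
        assert res.p_two_sided == pytest.approx(count / total)

    @staticmethod
    def _normal_approx_p(x, y):
        n1, n2 = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        var = n1 * n2 * (n1 + n2 + 1) / 12
        z = max(abs(u - mu) - 0.5, 0) / math.sqrt(var)
        return min(2 * sps.norm.sf(z), 1.0)

    def test_normal_approx_close_to_exact(self):
        # Exhaustive worst-case gaps (tie-free p depends only on n1, n2, U):
        # 0.087 at n1=n2=2, 0.0375 at n1=n2=3, 0.0305 at n1=n2=4, then below
        # 0.03 from 5 upward.  In production the exact path is always taken
        # for n1+n2 <= 12, so the approximation is never used at these sizes.
        rng = np.random.default_rng(11)
        small, large = [], []
        for n1 in range(3, 7):
            for n2 in range(3, 7):
                for _ in range(10):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    p_exact = ser.mann_whitney_u(x, y, mode="exact").p_two_sided
                    gap = abs(p_exact - self._normal_approx_p(x, y))
                    (large if min(n1, n2) >= 5 else small).append(gap)
        assert max(large) <= 0.03
        assert max(small) <= 0.04

    def test_large_samples_use_normal(self):
        rng = np.random.default_rng(2)
        res = ser.mann_whitney_u(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "normal_approx"
        assert 0 < res.p_two_sided <= 1

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            ser.mann_whitney_u([], [1, 2])
        with pytest.raises(InsufficientDataError):
            ser.mann_whitney_u([1], [1, 2])


class TestCompareFirstFinal:
    def test_growth_trajectory_verdicts(self, default_trajectory):
        s = syn.measured_series_from_truth(default_trajectory, rel_sigma=0.01, seed=0)
        assert ser.compare_first_final(s, "S_rel").verdict == "distinguishable"
        assert ser.compare_first_final(s, "V_rel").verdict == "indistinguishable"

    def test_flat_noiseless(self):
        fits = [two_circle_fit(3.0, 2.0, 3.5) for _ in range(30)]
        s = ser.build_series(fits, np.arange(30.0))
        res = ser.compare_first_final(s, "S_rel")
        assert res.U == pytest.approx(res.n1 * res.n2 / 2)
        assert res.verdict == "indistinguishable"

    def test_short_series(self):
        fits = [two_circle_fit(3.0, 2.0, 3.5) for _ in range(8)]
        s = ser.build_series(fits, np.arange(8.0))
        with pytest.raises(InsufficientDataError):
            ser.compare_first_final(s, "S_rel", window_frac=0.15)

    def test_bad_metric(self):
        fits = [two_circle_fit(3.0, 2.0, 3.5) for _ in range(30)]
        s = ser.build_series(fits, np.arange(30.0))
        with pytest.raises(ValueError):
            ser.compare_first_final(s, "theta")


class TestThetaDCorrelation:
    def test_perfect_anticorrelation(self):
        fits = []
        for i in range(10):
            # d increasing strictly; theta decreases with d for fixed radii
            fits.append(two_circle_fit(3.0, 2.0, 1.5 + 0.3 * i))
        s = ser.build_series(fits, np.arange(10.0))
        assert ser.theta_d_correlation(s) == pytest.approx(-1.0)

    def test_simulated_default(self, default_trajectory):
        s = syn.measured_series_from_truth(default_trajectory, rel_sigma=0.01, seed=1)
        assert ser.theta_d_correlation(s) < -0.9

    def test_shuffled_pairs_mean_zero(self, default_trajectory):
        s = syn.measured_series_from_truth(default_trajectory, rel_sigma=0.01, seed=2)
        m = s.has_neck
        th, dd = s.theta[m], s.d[m]
        rng = np.random.default_rng(0)
        vals = [
            sps.spearmanr(rng.permutation(th), dd).statistic for _ in range(300)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_constant_series_nan(self):
        fits = [two_circle_fit(3.0, 2.0, 3.5) for _ in range(10)]
        s = ser.build_series(fits, np.arange(10.0))
        assert math.isnan(ser.theta_d_correlation(s))

    def test_too_few_neck_frames(self):
        fits = [single_circle_fit(3.0) for _ in range(10)]
        s = ser.build_series(fits, np.arange(10.0))
        with pytest.raises(InsufficientDataError):
            ser.theta_d_correlation(s)
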