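"""Change-point detection, bound states, residence times, stoichiometry
and distribution comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from smtrack.segmentation import (BoundSegment, IntensityTrace,
                                  compare_distributions,
                                  detect_change_points,
                                  normalize_stoichiometry,
                                  residence_time_stats,
                                  segment_bound_states)


def exhaustive_ls_segmentation(y, n_changes, min_seg=3):
    """Oracle: exhaustive least-squares segmentation with a known number
    of change points (1 or 2)."""
    n = len(y)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(a, b):
        s, ss = c1[b] - c1[a], c2[b] - c2[a]
        return ss - s * s / (b - a)

    best = (np.inf, ())
    if n_changes == 1:
        for k in range(min_seg, n - min_seg + 1):
            v = sse(0, k) + sse(k, n)
            if v < best[0]:
                best = (v, (k,))
    elif n_changes == 2:
        for k1 in range(min_seg, n - 2 * min_seg + 1):
            for k2 in range(k1 + min_seg, n - min_seg + 1):
                v = sse(0, k1) + sse(k1, k2) + sse(k2, n)
                if v < best[0]:
                    best = (v, (k1, k2))
    else:
        raise ValueError(n_changes)
    return best[1]


class TestChangePoints:
    def test_noiseless_step_exact(self):
        y = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        assert detect_change_points(y, alpha=0.01) == [50]

    def test_null_trace_rarely_splits(self):
        """Type-I error of the gate under the null (Monte Carlo)."""
        splits = 0
        for seed in range(300):
            r = np.random.default_rng(seed)
            y = 1.0 + r.normal(0, 0.2, size=60)
            if detect_change_points(y, alpha=0.01):
                splits += 1
        assert splits / 300 <= 0.01

    def test_matches_exhaustive_ls_oracle(self):
        """Recursive search agrees with exhaustive least squares within
        +-1 frame on >=90% of random 1-2 step traces at SNR 5."""
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(200):
            n = int(rng.integers(30, 61))
            k = int(rng.integers(1, 3))
            cps = np.sort(rng.choice(np.arange(8, n - 8), size=k,
                                     replace=False))
            if k == 2 and cps[1] - cps[0] < 8:
                cps = np.array([cps[0]])
                k = 1
            levels = rng.permutation([0.0, 1.0, 2.0])[:k + 1]
            y = np.empty(n)
            edges = [0, *cps, n]
            for lv, (a, b) in zip(levels, zip(edges[:-1], edges[1:])):
                y[a:b] = lv
            y += rng.normal(0, 0.2, size=n)
            found = detect_change_points(y, alpha=0.01, min_seg_frames=3)
            oracle = exhaustive_ls_segmentation(y, k)
            for cp in oracle:
                total += 1
                if any(abs(cp - f) <= 1 for f in found):
                    hits += 1
        assert total >= 200
        assert hits / total >= 0.90

    def test_too_short_trace_single_segment(self):
        assert detect_change_points(np.array([1.0, 2.0]), 0.01, 2) == []

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([np.zeros(30), np.ones(30)])
        y += rng.normal(0, 0.1, 60)
        assert detect_change_points(y, 0.01) == \
            detect_change_points(y + 123.4, 0.01)


class TestBoundStates:
    def make_trace(self, values, dt=2.0):
        return IntensityTrace(0, np.asarray(values, float), dt)

    def test_six_second_segment_rejected(self):
        # 3 frames above threshold at 2-s frames = 6 s < 8 s
        y = [0] * 10 + [1.0] * 3 + [0] * 10
        tr = self.make_trace(y)
        segs = segment_bound_states(tr, [10, 13], 0.5, min_bound_s=8.0)
        assert segs == []

    def test_eight_second_segment_accepted(self):
        y = [0] * 10 + [1.0] * 4 + [0] * 10
        tr = self.make_trace(y)
        segs = segment_bound_states(tr, [10, 14], 0.5, min_bound_s=8.0)
        assert len(segs) == 1
        assert segs[0].duration_s == pytest.approx(8.0)
        assert not segs[0].censored

    def test_all_below_threshold_empty(self):
        tr = self.make_trace([0.1] * 30)
        assert segment_bound_states(tr, [], 0.5) == []

    def test_boundary_segments_censored(self):
        y = [1.0] * 10 + [0.0] * 10
        tr = self.make_trace(y)
        segs = segment_bound_states(tr, [10], 0.5, min_bound_s=8.0)
        assert len(segs) == 1
        assert segs[0].censored_start and not segs[0].censored_end


class TestResidence:
    def seg(self, dur, censored=False):
        return BoundSegment(t_start=0.0, t_end=dur, mean_level=1.0,
                            censored_end=censored)

    def test_arithmetic_mean(self):
        stats = residence_time_stats([self.seg(2.0), self.seg(4.0),
                                      self.seg(6.0)])
        assert stats.mean_s == pytest.approx(4.0)
        assert stats.n == 3

    def test_all_censored_flagged(self):
        stats = residence_time_stats([self.seg(10.0, censored=True)])
        assert stats.undefined
        assert np.isnan(stats.mean_s)

    def test_geometric_mle_inverts_discretization(self):
        """Frame counts of a point-sampled exponential dwell are geometric;
        the MLE recovers the continuous mean."""
        rng = np.random.default_rng(5)
        tau, dt = 3.6, 2.0
        segs = []
        for _ in range(200_000):
            d = rng.exponential(tau)
            phase = rng.uniform(0, dt)
            n = int(np.floor((d - phase) / dt)) + 1 if d > phase else 0
            if n >= 1:
                segs.append(self.seg(n * dt))
        stats = residence_time_stats(segs, frame_interval_s=dt,
                                     policy="geometric")
        assert stats.mean_s == pytest.approx(tau, rel=0.02)


class TestStoichiometry:
    def test_identity(self):
        out = normalize_stoichiometry([7.0], 7.0)
        assert out[0] == pytest.approx(1.0)

    def test_invalid_calibration(self):
        with pytest.raises(ValueError):
            normalize_stoichiometry([1.0], 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hst.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        samples = np.array([1.0, 2.5, 7.0])
        a = normalize_stoichiometry(samples, 2.0)
        b = normalize_stoichiometry(samples * c, 2.0 * c)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_multi_binder_mode(self):
        """3-binder spots normalize to ~3 against the 1x calibration."""
        rng = np.random.default_rng(3)
        ones = 100.0 + rng.normal(0, 5.0, size=500)
        threes = 300.0 + rng.normal(0, 9.0, size=500)
        norm = normalize_stoichiometry(threes, float(np.mean(ones)))
        assert np.mean(norm) == pytest.approx(3.0, abs=0.2)


class TestCompareDistributions:
    def test_identical_samples(self):
        d, p = compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_ks_statistic_brute_force(self):
        """D equals the hand-enumerated sup-difference of the ECDFs."""
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]
        d, _ = compare_distributions(a, b, test="ks")
        grid = np.unique(a + b)
        ecdf_a = [np.mean(np.asarray(a) <= x) for x in grid]
        ecdf_b = [np.mean(np.asarray(b) <= x) for x in grid]
        assert d == pytest.approx(max(abs(x - y)
                                      for x, y in zip(ecdf_a, ecdf_b)))
        assert d == pytest.approx(0.25)

    def test_null_p_uniform(self):
        """p-values under the null are ~uniform (KS-against-uniform)."""
        from scipy import stats as sps
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(500):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            _, p = compare_distributions(a, b, test="t")
            ps.append(p)
        d = sps.kstest(ps, "uniform").statistic
        assert d < 0.06

    def test_pooled_t(self):
        from scipy import stats as sps
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=40), rng.normal(0.5, 1, size=35)
        t, p = compare_distributions(a, b, test="t")
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
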