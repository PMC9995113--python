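"""DCE rank-sum scoring tests against hand-computed rank tables and
permutation oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from glymphokit.dce import (
    DCESeries,
    accumulation_duration,
    arrival_time,
    compare_groups,
    dce_auc,
    dce_metrics,
    friedman_ranksum_scores,
    peak_intensity,
    preprocess_dce,
    time_to_peak,
)
from glymphokit.synthetic import DCEParams, gen_dce_dataset


def _toy_series(values, time=None):
    values = np.asarray(values, float)
    t = np.arange(1, values.shape[1] + 1) if time is None else np.asarray(time)
    return DCESeries(values, t, baseline_indices=(0, 1, 2), infusion_start_min=3.0)


class TestPreprocess:
    def test_identical_frames_give_zero(self, rng):
        ref = rng.uniform(1, 2, (6, 6, 3))
        series = np.repeat(ref[..., None], 5, axis=-1)
        out = preprocess_dce(series, baseline_index=0)
        assert out.shape[-1] == 4  # reference frame dropped
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_impulse_kernel_is_separable_product(self):
        w = np.array([0.2, 1.0, 0.2]) / 1.4
        expected = np.einsum("i,j,k->ijk", w, w, w)
        rng = np.random.default_rng(0)
        ref = rng.uniform(1, 2, (7, 7, 7))
        series = np.stack([ref, ref.copy()], axis=-1)
        series[3, 3, 3, 1] += 1.0
        out = preprocess_dce(series, baseline_index=0)[..., 0]
        np.testing.assert_allclose(out[2:5, 2:5, 2:5], expected / ref.std(), atol=1e-12)

    def test_matches_direct_separable_convolution(self, rng):
        series = rng.uniform(0, 1, (6, 6, 6, 3))
        out = preprocess_dce(series, baseline_index=0)
        ref = series[..., 0]
        w = np.array([0.2, 1.0, 0.2]) / 1.4
        from scipy.ndimage import convolve1d

        expected = (series[..., 2] - ref) / ref.std()
        for ax in range(3):
            expected = convolve1d(expected, w, axis=ax, mode="reflect")
        np.testing.assert_allclose(out[..., 1], expected, rtol=1e-12)

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError):
            preprocess_dce(np.ones((4, 4, 4, 3)), 0)


class TestFriedmanScores:
    def test_constant_series_all_zero(self):
        series = _toy_series(np.ones((4, 12)))
        curve = friedman_ranksum_scores(series)
        np.testing.assert_allclose(curve.score, 0.0)
        assert not curve.significant.any()

    def test_hand_computed_rank_table(self):
        """3 subjects x 4 times, strictly increasing within every subject:
        ranks are 1..4, so score(t) = 1 - rank(t) against reference t=0."""
        values = np.array([[1, 2, 3, 4], [10, 20, 30, 40], [0.1, 0.2, 0.3, 0.4]])
        t = np.arange(1.0, 5.0)
        series = DCESeries(values, t, baseline_indices=(0,), infusion_start_min=1.0)
        curve = friedman_ranksum_scores(series, baseline_ref=0)
        np.testing.assert_allclose(curve.score, [0, -1, -2, -3])

    def test_subject_permutation_invariance(self, rng):
        values = rng.uniform(0, 1, (5, 15))
        s1 = friedman_ranksum_scores(_toy_series(values)).score
        s2 = friedman_ranksum_scores(_toy_series(values[::-1])).score
        np.testing.assert_allclose(s1, s2)

    def test_two_subjects_warns_no_significance(self):
        with pytest.warns(UserWarning):
            curve = friedman_ranksum_scores(_toy_series(np.random.default_rng(0).uniform(0, 1, (2, 12))))
        assert not curve.significant.any()


@pytest.fixture(scope="module")
def noiseless_cohort():
    p = DCEParams(arrival=5, time_to_peak=40, peak=100, duration=60)
    series, truth = gen_dce_dataset(0, 6, 90, {"r": p}, noise_sd=0)
    return series["r"], p


class TestKineticMetrics:
    def test_flat_curve_undefined(self):
        series = _toy_series(np.ones((4, 12)))
        curve = friedman_ranksum_scores(series)
        assert arrival_time(curve) is None
        assert time_to_peak(curve) is None
        assert accumulation_duration(curve) == 0.0

    def test_arrival_matches_generator_truth(self, noiseless_cohort):
        series, p = noiseless_cohort
        curve = friedman_ranksum_scores(series)
        assert arrival_time(curve, series.baseline_indices) == p.arrival

    def test_ttp_and_peak_match_truth(self, noiseless_cohort):
        series, p = noiseless_cohort
        curve = friedman_ranksum_scores(series)
        assert time_to_peak(curve, series.infusion_start_min) == p.time_to_peak
        assert peak_intensity(series.mean_curve, curve) == pytest.approx(p.peak, rel=1e-9)

    def test_monotone_transform_invariance(self, noiseless_cohort):
        """Rank-derived metrics are invariant under strictly monotone maps."""
        series, p = noiseless_cohort
        doubled = DCESeries(series.values * 2.0, series.time_min,
                            series.baseline_indices, series.infusion_start_min)
        warped = DCESeries(np.asinh(series.values), series.time_min,
                           series.baseline_indices, series.infusion_start_min)
        base = dce_metrics(series)
        for other in (doubled, warped):
            m = dce_metrics(other)
            assert m.arrival_time == base.arrival_time
            assert m.time_to_peak == base.time_to_peak
            assert m.duration == base.duration

    def test_monotone_rising_curve_peaks_last(self):
        values = np.tile(np.linspace(0, 1, 12), (4, 1))
        series = _toy_series(values)
        curve = friedman_ranksum_scores(series)
        assert time_to_peak(curve, 3.0) == series.time_min[-1] - 3.0

    def test_duration_matches_independent_dunn_oracle(self, noiseless_cohort):
        """Oracle: rank the curves independently with scipy, apply the Dunn
        z threshold, and read the significant window directly."""
        series, _ = noiseless_cohort
        n, k = series.values.shape
        ranks = np.vstack([sps.rankdata(row) for row in series.values])
        mean_ranks = ranks.mean(axis=0)
        ref = series.baseline_indices[0]
        z = np.abs(mean_ranks[ref] - mean_ranks) / np.sqrt(k * (k + 1) / (6 * n))
        z_crit = sps.norm.ppf(1 - 0.05 / (2 * (k - 1)))
        sig = z > z_crit
        sig[ref] = False
        idx = np.nonzero(sig)[0]
        expected = series.time_min[idx[-1]] - series.time_min[idx[0]] if idx.size >= 2 else 0.0
        curve = friedman_ranksum_scores(series)
        assert accumulation_duration(curve) == expected

    def test_duration_ignores_nonsignificant_tail(self, noiseless_cohort):
        series, _ = noiseless_cohort
        curve = friedman_ranksum_scores(series)
        d0 = accumulation_duration(curve)
        # appending non-significant flags beyond the window changes nothing
        curve.significant[-1] = False
        assert accumulation_duration(curve) == d0


class TestAUC:
    def test_examples_and_linearity(self, rng):
        assert dce_auc(np.zeros(20)) == 0.0
        assert dce_auc(np.full(87, 2.0)) == pytest.approx(174.0)
        x, y = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        assert dce_auc(2 * x + 3 * y) == pytest.approx(2 * dce_auc(x) + 3 * dce_auc(y))

    def test_matches_direct_sum(self, rng):
        curve = rng.uniform(-1, 5, 88)
        assert dce_auc(curve) == pytest.approx(float(curve.sum()))


class TestGroupComparison:
    def test_identical_groups_nothing_significant(self, rng):
        values = rng.uniform(0, 1, (4, 20))
        a = _toy_series(values)
        b = _toy_series(values.copy())
        res = compare_groups(a, b)
        assert not res["significant"].any()

    def test_label_swap_flips_differences(self, rng):
        a = _toy_series(rng.uniform(0, 1, (4, 15)))
        b = _toy_series(rng.uniform(0.5, 1.5, (4, 15)))
        r1 = compare_groups(a, b)
        r2 = compare_groups(b, a)
        np.testing.assert_allclose(r1["difference"], -r2["difference"])
        np.testing.assert_allclose(r1["p_corrected"], r2["p_corrected"])

    def test_detects_peak_difference_like_permutation_oracle(self):
        """Groups with 2x differing peaks at 10% noise: the significant block
        around the peak agrees with a permutation test at matched alpha."""
        p_hi = DCEParams(arrival=3, time_to_peak=10, peak=100, duration=15)
        p_lo = DCEParams(arrival=3, time_to_peak=10, peak=50, duration=15)
        n_sub = 8
        sa, _ = gen_dce_dataset(1, n_sub, 20, {"r": p_hi}, noise_sd=10.0)
        sb, _ = gen_dce_dataset(2, n_sub, 20, {"r": p_lo}, noise_sd=10.0)
        res = compare_groups(sa["r"], sb["r"])
        k = sa["r"].time_min.size
        alpha_pt = 0.05 / k
        rng = np.random.default_rng(0)
        pooled = np.vstack([sa["r"].values, sb["r"].values])
        peak_idx = int(np.argmax(sa["r"].mean_curve))
        obs = sa["r"].values[:, peak_idx].mean() - sb["r"].values[:, peak_idx].mean()
        count = 0
        n_shuffle = 10_000
        for _ in range(n_shuffle):
            perm = rng.permutation(2 * n_sub)
            d = pooled[perm[:n_sub], peak_idx].mean() - pooled[perm[n_sub:], peak_idx].mean()
            if abs(d) >= abs(obs):
                count += 1
        p_perm = (count + 1) / (n_shuffle + 1)
        assert res["significant"][peak_idx]
        assert p_perm < alpha_pt  # oracle agrees the peak separates the groups

    def test_single_subject_group_rejected(self, rng):
        a = _toy_series(rng.uniform(0, 1, (4, 12)))
        with pytest.raises(ValueError):
            DCESeries(rng.uniform(0, 1, (1, 12)), np.arange(1, 13))
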