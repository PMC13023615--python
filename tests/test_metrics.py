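import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specrestore.dataset import WavenumberAxis
from specrestore.filters import SNIPParams
from specrestore.metrics import (
    OracleMethod,
    PeakSet,
    ProcessedInputBaseline,
    detect_peaks,
    difficulty_scores,
    global_metrics,
    global_metrics_rows,
    loso_evaluate,
    match_peaks,
    reduction_percent,
    sam_degrees,
    second_derivative_view,
    stability_metric,
)
from specrestore.synthetic import SyntheticConfig, make_paired_dataset


class TestGlobalMetrics:
    def test_identity(self, rng):
        x = rng.normal(size=32)
        m = global_metrics(x, x)
        assert m.rmse == 0 and m.mae == 0
        assert m.sam_deg == pytest.approx(0.0, abs=1e-6)
        assert m.pcc == pytest.approx(1.0)

    def test_sam_45_degrees(self):
        m = sam_degrees(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        assert m[0] == pytest.approx(45.0)

    def test_closed_form_rmse_mae(self):
        pred = np.array([4.0, 6.0])  # diffs (3, 4)
        target = np.array([1.0, 2.0])
        m = global_metrics(pred, target)
        assert m.rmse == pytest.approx(np.sqrt(12.5))
        assert m.mae == pytest.approx(3.5)

    def test_sam_scale_invariance(self, rng):
        a, b = np.abs(rng.normal(size=(2, 16))) + 0.1
        assert sam_degrees(3.0 * a, b)[0] == pytest.approx(sam_degrees(a, b)[0])
        assert sam_degrees(a, 7.0 * b)[0] == pytest.approx(sam_degrees(a, b)[0])

    def test_pcc_affine_invariance(self, rng):
        a, b = rng.normal(size=(2, 16))
        base = global_metrics(a, b).pcc
        assert global_metrics(2.0 * a + 3.0, b).pcc == pytest.approx(base)

    def test_zero_norm_sam_error(self):
        with pytest.raises(ValueError, match="zero-norm"):
            sam_degrees(np.zeros(4), np.ones(4))

    def test_constant_pcc_error(self):
        with pytest.raises(ValueError, match="constant"):
            global_metrics(np.ones(4), np.arange(4.0))

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_rmse_ge_mae(self, seed):
        r = np.random.default_rng(seed)
        pred, target = r.normal(size=(2, 32))
        m = global_metrics(pred, target)
        assert m.rmse >= m.mae - 1e-12


class TestReduction:
    def test_examples(self):
        assert reduction_percent(0.2, 0.1) == pytest.approx(50.0)
        assert reduction_percent(0.2, 0.2) == pytest.approx(0.0)
        assert reduction_percent(1.0, 0.487) == pytest.approx(51.3)

    def test_nonpositive_baseline_error(self):
        with pytest.raises(ValueError, match="positive"):
            reduction_percent(0.0, 0.1)


def brute_force_prominence(x, i):
    """Topographic prominence: drop to the higher of the two bases, where
    each base is the minimum between the peak and the nearest higher ground
    (or the signal edge)."""
    left = x[: i + 1]
    higher = np.nonzero(left > x[i])[0]
    left_base = left[higher[-1]:].min() if higher.size else left.min()
    right = x[i:]
    higher = np.nonzero(right > x[i])[0]
    right_base = right[: higher[0] + 1].min() if higher.size else right.min()
    return x[i] - max(left_base, right_base)


class TestDetectPeaks:
    def _axis(self, L):
        return WavenumberAxis(np.linspace(1000.0, 1000.0 + L - 1, L))

    def test_single_triangle(self):
        x = np.zeros(33)
        x[10:17] = [0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25]
        peaks = detect_peaks(x, self._axis(33))
        assert peaks.n_peaks == 1
        assert peaks.indices[0] == 13
        assert peaks.prominences[0] == pytest.approx(1.0)

    def test_cap_at_20(self):
        x = np.zeros(125)
        x[2:122:4] = 0.5  # 30 equal isolated peaks
        peaks = detect_peaks(x, self._axis(125))
        assert peaks.n_peaks == 20

    def test_prominence_threshold(self):
        x = np.zeros(33)
        x[10] = 0.01  # below 0.02
        x[20] = 0.5
        peaks = detect_peaks(x, self._axis(33))
        assert peaks.n_peaks == 1
        assert peaks.indices[0] == 20

    def test_prominence_matches_brute_force(self):
        rng = np.random.default_rng(33)
        axis = self._axis(64)
        for _ in range(20):
            x = rng.random(64)
            peaks = detect_peaks(x, axis, prominence=0.0 + 1e-9, max_peaks=64)
            for idx, prom in zip(peaks.indices, peaks.prominences):
                assert prom == pytest.approx(brute_force_prominence(x, idx))


def brute_force_match(t_idx, p_idx, tol=4):
    """Max-cardinality, then min-total-index-distance assignment."""
    best = (0, np.inf)
    nt, npred = len(t_idx), len(p_idx)
    k_max = min(nt, npred)
    for k in range(k_max, -1, -1):
        found = False
        for t_sub in itertools.combinations(range(nt), k):
            for p_perm in itertools.permutations(range(npred), k):
                dists = [abs(t_idx[a] - p_idx[b]) for a, b in zip(t_sub, p_perm)]
                if all(d <= tol for d in dists):
                    found = True
                    total = sum(dists)
                    if total < best[1] or best[0] < k:
                        best = (k, total)
        if found:
            return best
    return best


class TestMatchPeaks:
    def _sets(self, indices, axis):
        indices = np.asarray(indices, dtype=int)
        return PeakSet(
            indices=indices,
            wavenumbers=axis.values[indices],
            heights=np.ones(indices.size),
            prominences=np.ones(indices.size),
        )

    def test_identical_sets(self):
        axis = WavenumberAxis(np.linspace(1000.0, 1500.0, 501))
        peaks = self._sets([100, 200, 300], axis)
        result = match_peaks(peaks, peaks)
        assert result.n_matched == 3
        np.testing.assert_array_equal(result.e_pos, 0.0)
        np.testing.assert_array_equal(result.e_amp, 0.0)

    def test_tolerance_excludes_far_peaks(self):
        axis = WavenumberAxis(np.linspace(1000.0, 1999.0, 1000))
        target = self._sets([100, 300], axis)
        pred = self._sets([102, 402], axis)
        result = match_peaks(target, pred)
        assert result.n_matched == 1
        assert result.target_indices[0] == 100
        assert result.pred_indices[0] == 102
        # position error uses actual wavenumbers: 2 steps of ~1.0 cm^-1
        local_interval = axis.values[102] - axis.values[101]
        assert result.e_pos[0] == pytest.approx(2 * local_interval)
        assert result.n_unmatched_target == 1
        assert result.n_unmatched_pred == 1

    def test_chain_case_beats_greedy(self):
        # greedy nearest-first would match only (1, 1); the optimal
        # assignment pairs (0,1) and (1,5) for two matches
        axis = WavenumberAxis(np.linspace(1000.0, 1099.0, 100))
        target = self._sets([0, 1], axis)
        pred = self._sets([1, 5], axis)
        result = match_peaks(target, pred)
        assert result.n_matched == 2

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        axis = WavenumberAxis(np.linspace(1000.0, 1063.0, 64))
        for _ in range(60):
            nt = int(rng.integers(0, 9))
            npred = int(rng.integers(0, 9))
            t_idx = np.sort(rng.choice(64, size=nt, replace=False))
            p_idx = np.sort(rng.choice(64, size=npred, replace=False))
            result = match_peaks(self._sets(t_idx, axis), self._sets(p_idx, axis))
            k, total = brute_force_match(list(t_idx), list(p_idx))
            assert result.n_matched == k
            observed_total = np.abs(
                result.target_indices.astype(int) - result.pred_indices.astype(int)
            ).sum()
            if k:
                assert observed_total == total

    def test_empty_sets(self):
        axis = WavenumberAxis(np.linspace(1000.0, 1063.0, 64))
        empty = self._sets([], axis)
        result = match_peaks(empty, self._sets([5], axis))
        assert result.n_matched == 0
        assert result.n_unmatched_pred == 1


class TestDifficultyScores:
    def test_mean_is_zero(self, rng):
        lq = rng.normal(size=(10, 64))
        rmse = rng.random(10)
        sam = rng.random(10)
        scores = difficulty_scores(lq, rmse, sam)
        assert scores.total.mean() == pytest.approx(0.0, abs=1e-10)

    def test_noisy_spectrum_ranks_highest(self, rng):
        lq = 0.05 * rng.normal(size=(12, 64))
        lq[7] += 0.5 * rng.normal(size=64)  # 10x noise
        rmse = np.full(12, 0.1)
        rmse[7] = 0.5
        sam = np.full(12, 2.0)
        sam[7] = 8.0
        scores = difficulty_scores(lq, rmse, sam)
        assert int(np.argmax(scores.total)) == 7

    def test_identical_spectra_all_zero_with_warning(self, rng):
        lq = np.tile(rng.normal(size=64), (4, 1))
        with pytest.warns(UserWarning, match="zero spread"):
            scores = difficulty_scores(lq, np.ones(4), np.ones(4))
        np.testing.assert_allclose(scores.total, 0.0)

    def test_needs_two_spectra(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            difficulty_scores(rng.normal(size=(1, 64)), np.ones(1), np.ones(1))


class TestStabilityMetric:
    def _axis(self):
        return WavenumberAxis(np.arange(2400.0, 2700.0, 2.0))

    def test_exact_line_gives_zero(self):
        axis = self._axis()
        spectrum = 0.3 + 0.001 * axis.values
        assert stability_metric(spectrum, axis) == pytest.approx(0.0, abs=1e-12)

    def test_line_plus_noise_estimates_sigma(self):
        axis = self._axis()
        rng = np.random.default_rng(12)
        sigma = 0.02
        estimates = [
            stability_metric(
                0.1 + 0.0005 * axis.values + rng.normal(0, sigma, axis.n_points),
                axis,
            )
            for _ in range(200)
        ]
        n_window = axis.indices_in(2500.0, 2600.0).size
        est_sd = sigma / np.sqrt(2 * n_window)  # sd of an sd estimate
        assert np.mean(estimates) == pytest.approx(sigma, abs=3 * est_sd)

    def test_scan_ratio_approximately_2_8(self):
        from specrestore.synthetic import simulate_noise_ratios

        metrics = simulate_noise_ratios(n_spectra=300, seed=8, scan_counts=(1, 8))
        assert metrics[1] / metrics[8] == pytest.approx(2.8, rel=0.05)

    def test_window_too_small(self):
        axis = WavenumberAxis(np.arange(1000.0, 1100.0, 2.0))
        with pytest.raises(ValueError, match="at least 3"):
            stability_metric(np.zeros(axis.n_points), axis, window=(2500.0, 2600.0))


class TestSecondDerivative:
    def test_constant_is_zero(self):
        out = second_derivative_view(np.full(64, 3.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_quadratic_gives_constant(self):
        nu = np.arange(0, 200, 2.0)
        out = second_derivative_view(0.25 * nu ** 2, sampling_interval=2.0)
        np.testing.assert_allclose(out[8:-8], 0.5, rtol=1e-9)

    def test_gaussian_negative_lobe_at_center(self):
        nu = np.linspace(-50, 50, 101)
        out = second_derivative_view(np.exp(-0.5 * (nu / 10) ** 2), 1.0)
        assert out[50] < 0


@pytest.fixture(scope="module")
def loso_data():
    cfg = SyntheticConfig(n_points=96, seed=31)
    return make_paired_dataset(4, 12, cfg, drift_fov=2)


class TestLosoEvaluate:
    def test_four_folds(self, loso_data):
        snip = SNIPParams(max_half_window=6)
        summary = loso_evaluate([ProcessedInputBaseline(snip)], loso_data)
        medians = summary.fov_medians["input"]["rmse"]
        assert sorted(medians) == [0, 1, 2, 3]

    def test_oracle_scores_100_percent(self, loso_data):
        snip = SNIPParams(max_half_window=6)
        summary = loso_evaluate(
            [ProcessedInputBaseline(snip), OracleMethod()], loso_data
        )
        for metric in ("rmse", "mae", "sam_deg"):
            assert summary.reduction["oracle"][metric] == pytest.approx(100.0)
        assert summary.mean["oracle"]["pcc"] == pytest.approx(1.0)

    def test_identity_scores_zero_percent(self, loso_data):
        snip = SNIPParams(max_half_window=6)
        summary = loso_evaluate([ProcessedInputBaseline(snip)], loso_data)
        for metric in ("rmse", "mae", "sam_deg"):
            assert summary.reduction["input"][metric] == pytest.approx(0.0)

    def test_single_fov_rejected(self, loso_data):
        mask = loso_data.lq.sample_labels == 0
        single_fov = loso_data.select(mask)
        with pytest.raises(ValueError):
            loso_evaluate([OracleMethod()], single_fov)

    def test_no_held_out_leakage(self, loso_data):
        """Poisoning the held-out FOV during fit must not change anything:
        all fit-time statistics come from training rows only."""
        snip = SNIPParams(max_half_window=6)

        class FitSpy(ProcessedInputBaseline):
            name = "spy"
            seen = []

            def fit(self, train, train_arrays):
                FitSpy.seen.append((
                    set(np.unique(train.lq.sample_labels)),
                    train_arrays.stage1_bounds,
                    train_arrays.stage2_bounds,
                ))

        summary_full = loso_evaluate([FitSpy(snip)], loso_data, folds=[2])
        fovs_seen, bounds1, bounds2 = FitSpy.seen[-1]
        assert 2 not in fovs_seen
        # recompute bounds from the training rows alone: identical
        from specrestore.models import prepare_stage_arrays

        train, _ = loso_data.split_fov(2)
        arrays = prepare_stage_arrays(train)
        assert arrays.stage1_bounds == bounds1
        assert arrays.stage2_bounds == bounds2

    def test_peak_bias_summary(self, loso_data):
        snip = SNIPParams(max_half_window=6)
        summary = loso_evaluate(
            [ProcessedInputBaseline(snip), OracleMethod()], loso_data,
            peak_metrics=True,
        )
        oracle = summary.peak_bias["oracle"]
        assert oracle["n_matched"] > 0
        assert oracle["median"] == pytest.approx(0.0, abs=1e-12)
        assert oracle["iqr"] == pytest.approx(0.0, abs=1e-12)
        assert oracle["e_pos_median"] == pytest.approx(0.0, abs=1e-12)
        assert summary.peak_bias["input"]["n_matched"] > 0

    def test_tidy_records(self, loso_data):
        snip = SNIPParams(max_half_window=6)
        summary = loso_evaluate([ProcessedInputBaseline(snip)], loso_data)
        records = summary.to_records()
        assert len(records) == 4 * 4  # 4 metrics x 4 folds
        assert {r["metric"] for r in records} == set(summary.METRICS)
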