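"""Sliding-window multinomial logistic decoding."""

import numpy as np
import pytest
from scipy.special import softmax
from scipy.stats import spearmanr

from vartune import decoding
from vartune.decoding import (
    WindowFit,
    fit_decoder,
    fit_timecourse,
    decode_timecourse,
    group_comparison,
    marginalize_joint,
    population_tuning_curve,
    score_sorted_decoding,
    windowed_counts,
)


class TestWindowedCounts:
    def test_61_windows(self, dataset_small):
        mat = windowed_counts(dataset_small, "theta", b_theta=0.5)
        assert len(mat.window_starts) == 61
        assert mat.window_starts[0] == -200.0 and mat.window_starts[-1] == 400.0

    def test_task_class_counts(self, dataset_small):
        assert windowed_counts(dataset_small, "theta", b_theta=0.5).n_classes == 12
        assert windowed_counts(dataset_small, "btheta").n_classes == 8
        assert windowed_counts(dataset_small, "joint").n_classes == 96

    def test_joint_trials_cover_grid(self, dataset_small):
        mat = windowed_counts(dataset_small, "joint")
        assert mat.counts.shape[1] == 96 * 2 * 15
        assert len(np.unique(mat.labels)) == 96

    def test_unknown_task(self, dataset_small):
        with pytest.raises(ValueError):
            windowed_counts(dataset_small, "speed")

    def test_counts_match_direct_histogram(self, dataset_small):
        """Cumulative-bin window counts equal a direct per-trial count."""
        mat = windowed_counts(dataset_small, "btheta")
        nid = int(dataset_small.neuron_ids[0])
        sid = int(dataset_small.stimuli["stim_id"].iloc[0])
        times = dataset_small.spikes[(nid, sid)][0]
        w = 30  # window start 100 ms
        start = mat.window_starts[w]
        direct = np.count_nonzero((times >= start) & (times < start + 100.0))
        assert mat.counts[w, 0, 0] == direct


class TestFitDecoder:
    def test_zero_coefficients_give_uniform_softmax(self):
        beta = np.zeros((5, 3))
        x = np.array([3.0, 1.0, 4.0])
        p = softmax(beta @ x)
        np.testing.assert_allclose(p, 0.2)

    def test_linearly_separable_perfect_accuracy(self, rng):
        x = np.concatenate([rng.poisson(1.0, (60, 4)),
                            rng.poisson(25.0, (60, 4))])
        y = np.repeat([0, 1], 60)
        fit = fit_decoder(x, y, seed=0)
        assert fit.balanced_accuracy == 1.0

    def test_probabilities_sum_to_one(self, rng):
        x = rng.poisson(3.0, (120, 6))
        y = rng.integers(0, 4, 120)
        fit = fit_decoder(x, y, seed=0)
        np.testing.assert_allclose(fit.proba.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_raises(self, rng):
        x = rng.poisson(3.0, (40, 3))
        with pytest.raises(ValueError):
            fit_decoder(x, np.zeros(40, dtype=int), seed=0)


class TestPopulationTuningCurve:
    def _fit(self, proba, y):
        return WindowFit(window_start=0.0, balanced_accuracy=np.nan,
                         coef=None, classes=np.arange(proba.shape[1]),
                         proba=proba, y_test=y)

    def test_perfect_decoder_delta(self):
        k = 12
        y = np.arange(k)
        proba = np.eye(k)
        offsets, curve, sharpness = population_tuning_curve(self._fit(proba, y), k)
        assert curve[offsets == 0] == pytest.approx(1.0)
        assert curve.sum() == pytest.approx(1.0)
        assert sharpness == pytest.approx(0.0, abs=1e-12)

    def test_chance_decoder_flat(self):
        k = 12
        y = np.arange(k)
        proba = np.full((k, k), 1.0 / k)
        _, curve, sharpness = population_tuning_curve(self._fit(proba, y), k)
        np.testing.assert_allclose(curve, 1.0 / k)
        assert sharpness == pytest.approx(1.0)


class TestMarginalization:
    def test_uniform_joint_gives_uniform_marginal(self, rng):
        y = rng.integers(0, 96, 200)
        proba = np.full((200, 96), 1.0 / 96)
        fit = WindowFit(0.0, np.nan, None, np.arange(96), proba, y)
        acc = marginalize_joint(fit)
        # argmax of a uniform distribution is class 0: balanced accuracy is
        # the recall of theta class 0 only
        assert acc == pytest.approx(1.0 / 12, abs=0.02)

    def test_deterministic_joint_marginal_no_worse(self, rng):
        y = rng.integers(0, 96, 300)
        proba = np.zeros((300, 96))
        correct = rng.random(300) < 0.5
        noise = rng.integers(0, 96, 300)
        chosen = np.where(correct, y, noise)
        proba[np.arange(300), chosen] = 1.0
        fit = WindowFit(0.0, np.nan, None, np.arange(96), proba, y)
        joint_acc = np.mean(chosen == y)
        assert marginalize_joint(fit) >= joint_acc - 0.05


class TestTimecourseFit:
    def test_recovers_generated_sigmoid(self):
        t = np.arange(0.0, 301.0, 10.0)
        y = 0.6 / (1 + np.exp(-0.05 * (t - 120.0))) + 0.1
        max_acc, min_acc, k, tau, flagged = fit_timecourse(t, y)
        assert not flagged
        assert max_acc == pytest.approx(0.6, rel=0.02)
        assert k == pytest.approx(0.05, rel=0.02)
        assert tau == pytest.approx(120.0, rel=0.02)

    def test_step_curve_tau_near_150(self):
        t = np.arange(0.0, 301.0, 10.0)
        y = np.where(t < 150.0, 0.1, 0.7)
        *_, tau, flagged = fit_timecourse(t, y)
        assert not flagged
        assert 140.0 <= tau <= 160.0

    def test_constant_curve_flagged(self):
        t = np.arange(0.0, 301.0, 10.0)
        assert fit_timecourse(t, np.full_like(t, 0.3))[-1]


class TestWindowsIndependent:
    def test_permuting_windows_permutes_outputs(self, dataset_small):
        mat = windowed_counts(dataset_small, "theta", b_theta=0.5)
        fwd = decode_timecourse(mat, seed=0, windows=[20, 30, 40])
        rev = decode_timecourse(mat, seed=0, windows=[40, 30, 20])
        np.testing.assert_allclose(fwd.accuracy, rev.accuracy[::-1])


class TestGroupComparison:
    def test_identical_groups_not_significant(self, dataset_small):
        ids = list(dataset_small.neuron_ids)
        out = group_comparison(dataset_small, {"a": ids, "b": ids},
                               b_theta=0.5, n=8, reps=3, seed=0,
                               windows=range(28, 36))
        assert not out["significant"].any()

    def test_reproducible_masks(self, dataset60):
        ids = list(dataset60.neuron_ids)
        groups = {"a": ids[:30], "b": ids[30:]}
        kw = dict(b_theta=0.5, n=20, reps=3, seed=5, windows=range(30, 34))
        a = group_comparison(dataset60, groups, **kw)
        b = group_comparison(dataset60, groups, **kw)
        np.testing.assert_array_equal(a["significant"], b["significant"])
        np.testing.assert_allclose(a["p_values"], b["p_values"])

    def test_rate_contrast_detected(self, dataset60):
        """Degrading half the population creates significant windows."""
        import copy

        ds = dataset60
        ids = list(ds.neuron_ids)
        weak_ids = set(ids[30:])
        rng = np.random.default_rng(0)
        degraded = copy.copy(ds)
        degraded.spikes = {
            k: ([t[t < 0.0] for t in trials] if k[0] in weak_ids else trials)
            for k, trials in ds.spikes.items()}
        degraded._binned = {}
        out = group_comparison(
            degraded, {"strong": ids[:30], "weak": ids[30:]}, b_theta=0.5,
            n=25, reps=10, seed=0, windows=range(30, 34), p_threshold=0.05)
        assert out["significant"].any()
        assert (out["accuracy"]["strong"].mean()
                > out["accuracy"]["weak"].mean())

    def test_small_group_raises(self, dataset_small):
        with pytest.raises(ValueError):
            group_comparison(dataset_small, {"a": [0], "b": [1, 2]},
                             b_theta=0.5)


class TestScoreSorted:
    def test_group_construction_deterministic(self, dataset60):
        scores = np.linspace(0, 1, dataset60.n_neurons)
        a = score_sorted_decoding(dataset60, scores, task="theta",
                                  group_size=20, n_groups=4, seed=0,
                                  windows=[32])
        b = score_sorted_decoding(dataset60, scores, task="theta",
                                  group_size=20, n_groups=4, seed=0,
                                  windows=[32])
        for ga, gb in zip(a["group_members"], b["group_members"]):
            np.testing.assert_array_equal(ga, gb)
        assert len(a["group_members"]) == 4

    def test_shuffled_scores_flat_slope(self, dataset60, rng):
        """Scores unrelated to tuning: no rank correlation with accuracy."""
        scores = rng.permutation(np.linspace(0, 1, dataset60.n_neurons))
        out = score_sorted_decoding(dataset60, scores, task="theta",
                                    group_size=20, n_groups=4, seed=0,
                                    windows=[32])
        assert out["spearman_p"] > 0.05 or abs(out["spearman_r"]) < 0.9
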