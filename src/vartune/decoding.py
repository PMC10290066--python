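"""Sliding-window multinomial logistic population decoding.

Spike counts in 100 ms windows slid from -200 to 400 ms in 10 ms steps (61
windows) feed, independently per window, an L2-penalized multinomial
logistic regression (C = 1, stratified 15% held-out split).  Performance is
balanced accuracy (mean per-class recall); chance is 1/K.

Tasks: orientation ``theta`` (K = 12, one independent decoder per variance
level), variance ``btheta`` (K = 8), or the joint code (K = 96).  The mean
held-out class likelihood re-centered on the true class forms a *population
tuning curve*; a joint decoder can be marginalized over variance into an
orientation-only decoder.  Accuracy time courses over [0, 300] ms are
summarized with a sigmoid max_acc / (1 + exp(-k (t - tau))) + min_acc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress, spearmanr, wilcoxon
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split

from vartune.synthetic import SpikeDataset
from vartune.tuning import circular_variance

__all__ = [
    "SpikeCountMatrix",
    "WindowFit",
    "DecoderRun",
    "windowed_counts",
    "fit_decoder",
    "decode_timecourse",
    "population_tuning_curve",
    "marginalize_joint",
    "fit_timecourse",
    "group_comparison",
    "score_sorted_decoding",
]

WINDOW_RANGE_MS = (-200.0, 400.0)
WINDOW_STEP_MS = 10.0
WINDOW_WIDTH_MS = 100.0
N_BTHETA = 8


@dataclass
class SpikeCountMatrix:
    task: str  # "theta" | "btheta" | "joint"
    window_starts: np.ndarray  # (n_windows,)
    counts: np.ndarray  # (n_windows, n_trials, n_neurons)
    labels: np.ndarray  # (n_trials,) integer class per trial
    n_classes: int
    neuron_ids: np.ndarray
    b_theta: float | None = None  # set for per-variance theta decoders


@dataclass
class WindowFit:
    window_start: float
    balanced_accuracy: float
    coef: np.ndarray  # (n_classes, n_neurons)
    classes: np.ndarray
    proba: np.ndarray = field(repr=False, default=None)  # held-out (n_test, K)
    y_test: np.ndarray = field(repr=False, default=None)


@dataclass
class DecoderRun:
    task: str
    window_starts: np.ndarray
    accuracy: np.ndarray  # balanced accuracy per window
    fits: list  # WindowFit per window
    n_classes: int
    b_theta: float | None = None

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


def windowed_counts(dataset: SpikeDataset, task: str,
                    b_theta: float | None = None,
                    neuron_ids=None,
                    window_range=WINDOW_RANGE_MS,
                    step_ms: float = WINDOW_STEP_MS,
                    width_ms: float = WINDOW_WIDTH_MS) -> SpikeCountMatrix:
    """Build the sliding-window count tensor and class labels for a task.

    For ``task="theta"`` pass ``b_theta`` to restrict trials to one variance
    level (the per-variance orientation decoders); labels index the sorted
    unique values.  Joint labels are ``theta_idx * n_btheta + btheta_idx``.
    """
    if task not in ("theta", "btheta", "joint"):
        raise ValueError(f"unknown task {task!r}")
    stim = dataset.stimuli
    thetas = np.sort(stim["theta_deg"].unique())
    bthetas = np.sort(stim["b_theta_deg"].unique())
    sel = np.ones(len(stim), dtype=bool)
    if task == "theta" and b_theta is not None:
        sel = stim["b_theta_deg"].to_numpy() == b_theta
    stim_sel = stim[sel]

    t0_data = dataset.window_ms[0]
    bins = dataset.binned_counts(step_ms)  # (n_neurons, n_stim, n_trials, n_bins)
    if neuron_ids is not None:
        all_ids = dataset.neuron_ids
        idx = [int(np.where(all_ids == n)[0][0]) for n in neuron_ids]
        bins = bins[idx]
        nids = np.asarray(neuron_ids)
    else:
        nids = dataset.neuron_ids
    bins = bins[:, sel.to_numpy() if hasattr(sel, "to_numpy") else sel]

    starts = np.arange(window_range[0], window_range[1] + step_ms / 2, step_ms)
    nwin_bins = int(round(width_ms / step_ms))
    csum = np.concatenate([np.zeros(bins.shape[:-1] + (1,), dtype=np.int32),
                           np.cumsum(bins, axis=-1, dtype=np.int32)], axis=-1)
    counts = np.empty((len(starts), bins.shape[1] * bins.shape[2],
                       bins.shape[0]), dtype=np.int32)
    n_bins = bins.shape[-1]
    for w, s in enumerate(starts):
        b0 = min(int(round((s - t0_data) / step_ms)), n_bins)
        b1 = min(b0 + nwin_bins, n_bins)  # windows past the recording edge truncate
        win = csum[..., b1] - csum[..., b0]  # (neurons, stim, trials)
        counts[w] = win.reshape(win.shape[0], -1).T

    th_idx = np.searchsorted(thetas, stim_sel["theta_deg"].to_numpy())
    b_idx = np.searchsorted(bthetas, stim_sel["b_theta_deg"].to_numpy())
    if task == "theta":
        per_stim = th_idx
        n_classes = len(thetas)
    elif task == "btheta":
        per_stim = b_idx
        n_classes = len(bthetas)
    else:
        per_stim = th_idx * len(bthetas) + b_idx
        n_classes = len(thetas) * len(bthetas)
    labels = np.repeat(per_stim, dataset.n_trials)
    return SpikeCountMatrix(task=task, window_starts=starts, counts=counts,
                            labels=labels, n_classes=n_classes,
                            neuron_ids=nids, b_theta=b_theta)


def fit_decoder(counts: np.ndarray, labels: np.ndarray, penalty: str = "l2",
                C: float = 1.0, test_frac: float = 0.15, seed: int = 0,
                max_iter: int = 500) -> WindowFit:
    """Fit one window: multinomial logistic regression, held-out accuracy.

    The train/test split is stratified by class; a class absent from either
    split raises (propagated from sklearn's stratifier).
    """
    X_tr, X_te, y_tr, y_te = train_test_split(
        counts, labels, test_size=test_frac, stratify=labels,
        random_state=seed)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("need at least 2 classes present in training split")
    clf = LogisticRegression(penalty=penalty, C=C, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs convergence chatter
        clf.fit(X_tr, y_tr)
    proba = clf.predict_proba(X_te)
    acc = balanced_accuracy_score(y_te, clf.classes_[np.argmax(proba, axis=1)])
    return WindowFit(window_start=np.nan, balanced_accuracy=float(acc),
                     coef=clf.coef_, classes=clf.classes_, proba=proba,
                     y_test=y_te)


def decode_timecourse(matrix: SpikeCountMatrix, seed: int = 0,
                      windows=None, **fit_kwargs) -> DecoderRun:
    """Fit every window independently (optionally a subset of window indices)."""
    idx = range(len(matrix.window_starts)) if windows is None else windows
    fits = []
    for w in idx:
        fit = fit_decoder(matrix.counts[w], matrix.labels, seed=seed,
                          **fit_kwargs)
        fit.window_start = float(matrix.window_starts[w])
        fits.append(fit)
    return DecoderRun(task=matrix.task,
                      window_starts=np.array([f.window_start for f in fits]),
                      accuracy=np.array([f.balanced_accuracy for f in fits]),
                      fits=fits, n_classes=matrix.n_classes,
                      b_theta=matrix.b_theta)


def population_tuning_curve(fit: WindowFit, n_classes: int,
                            circular: bool = True):
    """Mean held-out likelihood per class offset from the true class.

    Returns ``(offsets, curve, sharpness)`` where offsets run over
    ``-K/2 .. K/2`` classes (circular re-centering) and sharpness is the
    circular variance of the curve read as an orientation profile.
    """
    proba_full = np.zeros((len(fit.y_test), n_classes))
    proba_full[:, fit.classes] = fit.proba
    rolled = np.stack([np.roll(p, -int(y)) for p, y in
                       zip(proba_full, fit.y_test)])
    curve = rolled.mean(axis=0)
    shift = n_classes // 2
    curve = np.roll(curve, shift)
    offsets = np.arange(n_classes) - shift
    sharpness = np.nan
    if circular:
        th = offsets * (180.0 / n_classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sharpness = circular_variance(curve, th)
    return offsets, curve, sharpness


def marginalize_joint(fit: WindowFit, n_theta: int = 12,
                      n_btheta: int = N_BTHETA) -> float:
    """Balanced theta accuracy of a joint fit after summing over variance.

    Joint labels are ``theta_idx * n_btheta + btheta_idx``; class
    probabilities are summed over the variance axis and the argmax compared
    with the true orientation.
    """
    proba_full = np.zeros((len(fit.y_test), n_theta * n_btheta))
    proba_full[:, fit.classes] = fit.proba
    p_theta = proba_full.reshape(-1, n_theta, n_btheta).sum(axis=2)
    y_theta = np.asarray(fit.y_test) // n_btheta
    return float(balanced_accuracy_score(y_theta, np.argmax(p_theta, axis=1)))


def _sigmoid(t, max_acc, min_acc, k, tau):
    return max_acc / (1.0 + np.exp(-k * (t - tau))) + min_acc


def fit_timecourse(t_ms, accuracy):
    """Sigmoid fit of an accuracy time course over [0, 300] ms.

    Returns ``(max_acc, min_acc, k, tau, flagged)``; a flat or non-converging
    curve is flagged (steepness unidentifiable).
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(accuracy, dtype=float)
    sel = (t >= 0) & (t <= 300)
    t, y = t[sel], y[sel]
    span = y.max() - y.min()
    if span < 1e-6:
        return np.nan, float(y.mean()), np.nan, np.nan, True
    t_mid = t[int(np.argmin(np.abs(y - (y.min() + span / 2))))]
    try:
        popt, _ = curve_fit(
            _sigmoid, t, y, p0=[span, y.min(), 0.05, t_mid],
            bounds=([0.0, -1.0, 1e-4, 0.0], [1.5, 1.0, 1.0, 300.0]),
            maxfev=20000)
    except RuntimeError:
        return np.nan, np.nan, np.nan, np.nan, True
    max_acc, min_acc, k, tau = popt
    return (float(max_acc), float(min_acc), float(k), float(tau), False)


def group_comparison(dataset: SpikeDataset, groups: dict,
                     task: str = "theta", b_theta: float | None = None,
                     n: int = 100, reps: int = 5, seed: int = 0,
                     p_threshold: float = 0.01, windows=None,
                     min_consecutive: int = 2, **fit_kwargs) -> dict:
    """Resampled decoding per neuron group plus a significance mask.

    ``groups`` maps two group names to neuron-id lists.  Each group is
    decoded ``reps`` times on ``n`` neurons drawn with replacement; per
    window, a Wilcoxon signed-rank across the paired resamples marks
    significance, reported only for at least ``min_consecutive`` consecutive
    windows.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for name, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 neurons")
    rng = np.random.default_rng(seed)
    acc = {}
    starts = None
    for name, ids in groups.items():
        ids = np.asarray(ids)
        rows = []
        for r in range(reps):
            pick = rng.choice(ids, size=n, replace=True)
            mat = windowed_counts(dataset, task, b_theta=b_theta,
                                  neuron_ids=pick)
            run = decode_timecourse(mat, seed=seed + r, windows=windows,
                                    **fit_kwargs)
            rows.append(run.accuracy)
            starts = run.window_starts
        acc[name] = np.asarray(rows)  # (reps, n_windows)

    (g1, a1), (g2, a2) = acc.items()
    pvals = np.ones(a1.shape[1])
    for w in range(a1.shape[1]):
        d = a1[:, w] - a2[:, w]
        if np.count_nonzero(d):
            pvals[w] = wilcoxon(a1[:, w], a2[:, w]).pvalue
    below = pvals < p_threshold
    mask = np.zeros_like(below)
    run_start = None
    for w in range(len(below) + 1):
        if w < len(below) and below[w]:
            if run_start is None:
                run_start = w
        else:
            if run_start is not None and w - run_start >= min_consecutive:
                mask[run_start:w] = True
            run_start = None
    return {"window_starts": starts, "accuracy": acc, "p_values": pvals,
            "significant": mask}


def score_sorted_decoding(dataset: SpikeDataset, scores, task: str = "joint",
                          group_size: int = 100, n_groups: int = 7,
                          seed: int = 0, windows=None, **fit_kwargs) -> dict:
    """Decoding accuracy along overlapping groups sorted by vulnerability.

    Neurons are ranked by descending score; ``n_groups`` windows of
    ``group_size`` neurons slide along the ranking (stride chosen so the
    last group ends at the last neuron; with fewer neurons than
    ``group_size`` requires, fewer/smaller groups are used with a warning).
    Returns per-group mean score and maximum balanced accuracy plus a linear
    regression and Spearman rank correlation of accuracy on mean score.
    """
    scores = np.asarray(scores, dtype=float)
    nids = dataset.neuron_ids
    order = nids[np.argsort(-scores)]
    n_neurons = len(order)
    if group_size >= n_neurons:
        warnings.warn("population smaller than group_size; using one group")
        starts = np.array([0])
        group_size = n_neurons
    else:
        starts = np.unique(np.round(np.linspace(
            0, n_neurons - group_size, n_groups)).astype(int))
        if len(starts) < n_groups:
            warnings.warn(f"only {len(starts)} distinct groups possible")
    sorted_scores = np.sort(scores)[::-1]
    mean_scores, max_acc, members = [], [], []
    for s in starts:
        ids = order[s:s + group_size]
        members.append(ids)
        mean_scores.append(sorted_scores[s:s + group_size].mean())
        mat = windowed_counts(dataset, task, neuron_ids=ids)
        run = decode_timecourse(mat, seed=seed, windows=windows, **fit_kwargs)
        max_acc.append(float(run.accuracy.max()))
    mean_scores = np.asarray(mean_scores)
    max_acc = np.asarray(max_acc)
    reg = linregress(mean_scores, max_acc)
    rho = spearmanr(mean_scores, max_acc)
    return {"group_members": members, "mean_score": mean_scores,
            "max_accuracy": max_acc, "slope": float(reg.slope),
            "slope_p": float(reg.pvalue), "spearman_r": float(rho.statistic),
            "spearman_p": float(rho.pvalue)}
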