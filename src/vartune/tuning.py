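"""Single-neuron analysis: tuning curves, fits, variance tuning, dynamics.

Conventions
-----------
- Orientations in degrees on [0, 180); all circular statistics double the
  angle internally (orientation is pi-periodic).
- Rates are baseline subtracted (baseline = mean rate in [-200, 0) ms);
  negative baseline-subtracted rates are clipped at 0 before circular
  variance only, since the resultant needs non-negative weights.
- The analysis window is the 300 ms window (slid in 10 ms steps over
  [0, 450] ms) maximizing across-condition variance of the trial-mean spike
  count.

The variance-tuning function (VTF) maps stimulus orientation variance
``b_theta`` to circular variance and is summarized by a Naka-Rushton fit
``f(b) = f0 + fmax * b^n / (b^n + b50^n)`` with ``log n`` reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import wilcoxon

from vartune import stimuli
from vartune.synthetic import SpikeDataset, vtf_value

__all__ = [
    "TuningCurve",
    "VonMisesFit",
    "NKRFit",
    "NeuronSummary",
    "best_window",
    "circular_variance",
    "fit_von_mises",
    "direction_selectivity",
    "fit_vtf",
    "tuning_significance",
    "b_theta_max",
    "early_late_ratio",
    "delay_to_peak",
    "hwhh",
    "summarize_neuron",
    "summarize_population",
    "NKR_BOUNDS",
]

WINDOW_SPAN_MS = 300.0
BIN_MS = 10.0
R2_EXCLUSION = 0.75

#: Naka-Rushton fitting bounds: (f0, fmax, log n, b_theta50).
NKR_BOUNDS = (np.array([0.0, 0.0, 0.1, 0.1]),
              np.array([1.0, 1.0, 10.0, 44.0]))


@dataclass
class TuningCurve:
    b_theta: float
    theta_values: np.ndarray  # deg
    mean_rate: np.ndarray  # baseline-subtracted Hz
    sem: np.ndarray
    window: tuple  # (start_ms, span_ms)
    trial_rates: np.ndarray = field(default=None, repr=False)  # (n_theta, n_trials)


@dataclass
class VonMisesFit:
    r0: float
    r_max: float
    theta_pref: float  # deg in [0, 180)
    kappa: float
    r_squared: float
    excluded: bool = False

    def predict(self, thetas_deg):
        d = np.deg2rad(np.asarray(thetas_deg) - self.theta_pref)
        return self.r0 + (self.r_max - self.r0) * np.exp(
            self.kappa * (np.cos(2.0 * d) - 1.0))


@dataclass
class NKRFit:
    f0: float
    f_max: float
    log_n: float
    b_theta50: float
    flagged: bool = False

    @property
    def n(self) -> float:
        return float(np.exp(self.log_n))

    def predict(self, b_theta_deg):
        return vtf_value(b_theta_deg, self.f0, self.f_max, self.log_n,
                         self.b_theta50)


@dataclass
class NeuronSummary:
    neuron_id: int
    theta_pref: float
    kappa: float
    r_squared: float
    excluded: bool
    ds_index: float
    baseline_hz: float
    window_start_ms: float
    b_thetas: np.ndarray
    cv: np.ndarray  # circular variance per b_theta
    curves: list = field(repr=False, default=None)
    vm_fits: list = field(repr=False, default=None)
    nkr: NKRFit = None
    p_tuned: np.ndarray = None  # Wilcoxon p per b_theta
    b_theta_max: float = np.nan
    early_late_low: float = np.nan
    early_late_high: float = np.nan
    delay_low: float = np.nan
    delay_high: float = np.nan
    pref_shift_deg: float = np.nan
    layer_depth: float = np.nan

    def as_row(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "theta_pref": self.theta_pref,
            "kappa": self.kappa,
            "r_squared": self.r_squared,
            "excluded": self.excluded,
            "ds_index": self.ds_index,
            "baseline_hz": self.baseline_hz,
            "log_n": self.nkr.log_n if self.nkr else np.nan,
            "b_theta50": self.nkr.b_theta50 if self.nkr else np.nan,
            "f0": self.nkr.f0 if self.nkr else np.nan,
            "f_max": self.nkr.f_max if self.nkr else np.nan,
            "b_theta_max": self.b_theta_max,
            "cv_low": self.cv[0],
            "cv_high": self.cv[-1],
            "early_late_low": self.early_late_low,
            "early_late_high": self.early_late_high,
            "delay_low": self.delay_low,
            "delay_high": self.delay_high,
            "pref_shift_deg": self.pref_shift_deg,
            "layer_depth": self.layer_depth,
        }


# ---------------------------------------------------------------------------
# Elementary statistics


def best_window(counts_by_time: np.ndarray, bin_ms: float = BIN_MS,
                span_ms: float = WINDOW_SPAN_MS) -> float:
    """Start (ms) of the span maximizing across-condition count variance.

    ``counts_by_time`` holds per-condition trial-mean spike counts binned over
    [0, 450] ms, shape (n_conditions, n_bins).  Windows slide in one-bin
    steps; ties break toward the earliest window.
    """
    counts = np.atleast_2d(np.asarray(counts_by_time, dtype=float))
    n_bins_win = int(round(span_ms / bin_ms))
    n_starts = counts.shape[1] - n_bins_win + 1
    if n_starts < 1:
        raise ValueError("window span exceeds the available range")
    if not counts.any():
        warnings.warn("all-zero spike counts; defaulting to window [0, 300] ms")
        return 0.0
    csum = np.concatenate(
        [np.zeros((counts.shape[0], 1)), np.cumsum(counts, axis=1)], axis=1)
    win = csum[:, n_bins_win:] - csum[:, :-n_bins_win]  # (n_cond, n_starts)
    var = win.var(axis=0)
    return float(np.argmax(var) * bin_ms)


def circular_variance(rates, thetas_deg) -> float:
    """1 - |sum R(theta) exp(2i theta)| / sum R(theta); 0 sharp, 1 untuned.

    Negative rates are clipped at 0.  All-zero input is undefined and
    reported as 1 with a warning.
    """
    r = np.clip(np.asarray(rates, dtype=float), 0.0, None)
    if not np.any(r > 0):
        warnings.warn("circular variance undefined for all-zero rates; "
                      "reporting 1")
        return 1.0
    th = np.deg2rad(np.asarray(thetas_deg, dtype=float))
    return float(1.0 - np.abs(np.sum(r * np.exp(2j * th))) / np.sum(r))


def direction_selectivity(r_pref: float, r_null: float) -> float:
    """(R_pref - R_null) / R_pref; NaN (flagged) if R_pref <= 0."""
    if r_pref <= 0:
        warnings.warn("direction selectivity undefined for r_pref <= 0")
        return np.nan
    return (r_pref - r_null) / r_pref


def hwhh(kappa: float) -> float:
    """Half-width at half-height (degrees) of a von Mises tuning curve."""
    if kappa < -np.log(0.5):
        raise ValueError(
            f"kappa={kappa:g} below domain bound -log(0.5) ~= 0.6931")
    return float(np.rad2deg(
        0.5 * np.arccos((np.log(0.5) + kappa) / kappa)))


# ---------------------------------------------------------------------------
# Fits


def _vm_model(thetas_deg, r0, rmax, theta_pref, kappa):
    d = np.deg2rad(thetas_deg - theta_pref)
    return r0 + (rmax - r0) * np.exp(kappa * (np.cos(2.0 * d) - 1.0))


def fit_von_mises(curve: TuningCurve) -> VonMisesFit:
    """Least-squares von Mises fit; R^2 < 0.75 flags the neuron excluded."""
    th = np.asarray(curve.theta_values, dtype=float)
    y = np.asarray(curve.mean_rate, dtype=float)
    tp0 = th[int(np.argmax(y))]

    def resid(p):
        return _vm_model(th, *p) - y

    def jac(p):
        r0, rmax, tp, kappa = p
        d = np.deg2rad(th - tp)
        e = np.exp(kappa * (np.cos(2.0 * d) - 1.0))
        return np.stack([
            1.0 - e,
            e,
            (rmax - r0) * e * kappa * 2.0 * np.sin(2.0 * d) * np.pi / 180.0,
            (rmax - r0) * e * (np.cos(2.0 * d) - 1.0),
        ], axis=1)

    best = None
    for k0 in (0.5, 3.0):
        try:
            sol = least_squares(
                resid, jac=jac, x0=[max(y.min(), 0.0), y.max(), tp0, k0],
                bounds=([-np.inf, -np.inf, tp0 - 90.0, 0.0],
                        [np.inf, np.inf, tp0 + 90.0, 500.0]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return VonMisesFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                           excluded=True)
    r0, rmax, tp, kappa = best.x
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    excluded = not (r2 >= R2_EXCLUSION)
    return VonMisesFit(float(r0), float(rmax), float(tp % 180.0),
                       float(kappa), float(r2) if np.isfinite(r2) else np.nan,
                       excluded=excluded)


def _nkr_model(b, p):
    f0, fmax, log_n, b50 = p
    n = np.exp(log_n)
    return f0 + fmax * expit(n * (np.log(np.maximum(b, 1e-300)) - np.log(b50)))


def fit_vtf(b_thetas, cv_values) -> NKRFit:
    """Bounded Naka-Rushton fit of circular variance vs b_theta.

    Multi-start over the transition point and steepness (the sum is computed
    in log space, so arbitrarily steep fits are numerically stable).  A flat
    VTF pins ``log n`` at a bound and is flagged.
    """
    b = np.asarray(b_thetas, dtype=float)
    y = np.asarray(cv_values, dtype=float)
    ok = np.isfinite(b) & np.isfinite(y)
    b, y = b[ok], y[ok]
    if len(b) < 4:
        raise ValueError("need at least 4 (b_theta, CV) points")
    lo, hi = NKR_BOUNDS

    def resid(p):
        return _nkr_model(b, p) - y

    logb = np.log(np.maximum(b, 1e-300))

    def jac(p):
        _f0, fmax, log_n, b50 = p
        n = np.exp(log_n)
        u = n * (logb - np.log(b50))
        s = expit(u)
        sp = s * (1.0 - s)
        return np.stack([
            np.ones_like(b),
            s,
            fmax * sp * u,
            -fmax * sp * n / b50,
        ], axis=1)

    f0_init = float(np.clip(y.min(), 0.0, 1.0))
    fmax_init = float(np.clip(y.max() - y.min(), 1e-3, 1.0))
    order = np.argsort(b)
    bs, ys = b[order], y[order]
    # candidate transition points: quantiles of the b grid plus the steepest
    # rise (pins near-step VTFs without scanning every point)
    cand = list(np.quantile(bs, np.linspace(0.05, 0.95, 5)))
    if len(bs) > 1:
        j = int(np.argmax(np.diff(ys)))
        cand += [bs[j], bs[min(j + 1, len(bs) - 1)],
                 0.5 * (bs[j] + bs[min(j + 1, len(bs) - 1)])]
    b50_candidates = np.unique(np.clip(cand, lo[3] + 1e-6, hi[3] - 1e-6))
    best = None
    for b50_0 in b50_candidates:
        for ln0 in (0.5, 2.0, 4.0, 7.0):
            x0 = np.clip([f0_init, fmax_init, ln0, b50_0],
                         lo + 1e-9, hi - 1e-9)
            sol = least_squares(resid, jac=jac, x0=x0, bounds=(lo, hi),
                                x_scale=[1.0, 1.0, 2.0, 10.0])
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
    f0, fmax, log_n, b50 = best.x
    flagged = bool(fmax < 1e-3
                   or log_n > hi[2] - 1e-6 or log_n < lo[2] + 1e-6)
    return NKRFit(float(f0), float(fmax), float(log_n), float(b50),
                  flagged=flagged)


# ---------------------------------------------------------------------------
# Significance and dynamics


def tuning_significance(trial_rates_pref, trial_rates_ortho,
                        min_pairs: int = 6) -> float:
    """Two-sided Wilcoxon signed-rank p (zero differences discarded).

    Returns NaN (condition counted as not tuned) with fewer than
    ``min_pairs`` informative pairs.
    """
    pref = np.asarray(trial_rates_pref, dtype=float)
    ortho = np.asarray(trial_rates_ortho, dtype=float)
    diffs = pref - ortho
    if np.count_nonzero(diffs) < min_pairs:
        return np.nan
    return float(wilcoxon(pref, ortho, zero_method="wilcox",
                          correction=True).pvalue)


def b_theta_max(b_thetas, p_values, alpha: float = 0.05) -> float:
    """Largest b_theta with p < alpha; NaN if never significant."""
    b = np.asarray(b_thetas, dtype=float)
    p = np.asarray(p_values, dtype=float)
    sig = b[np.isfinite(p) & (p < alpha)]
    return float(sig.max()) if len(sig) else np.nan


def early_late_ratio(spike_times, early_ms: float = 100.0,
                     late_ms: float = 200.0, t_end: float = 450.0,
                     eps: float = 1.0) -> float:
    """log((late + eps)/(early + eps)): early = [0, 100) ms, late = (200, 450]."""
    t = np.asarray(spike_times, dtype=float)
    early = np.count_nonzero((t >= 0) & (t < early_ms))
    late = np.count_nonzero((t > late_ms) & (t <= t_end))
    return float(np.log((late + eps) / (early + eps)))


def delay_to_peak(rates_by_window, window_centers_ms) -> float:
    """Center (ms) of the 100 ms window maximizing tuning-curve amplitude.

    ``rates_by_window``: per-window baseline-subtracted tuning curves, shape
    (n_windows, n_theta); amplitude is the max over orientations.
    """
    amp = np.max(np.asarray(rates_by_window, dtype=float), axis=1)
    return float(np.asarray(window_centers_ms)[int(np.argmax(amp))])


# ---------------------------------------------------------------------------
# Per-neuron pipeline


def _rates_tensor(dataset: SpikeDataset, i_neuron: int, start_ms: float,
                  span_ms: float) -> np.ndarray:
    """Trial firing rates (Hz) in [start, start+span) per stimulus, shape (n_stim, n_trials)."""
    t0 = dataset.window_ms[0]
    counts = dataset.binned_counts(BIN_MS)[i_neuron]
    b0 = int(round((start_ms - t0) / BIN_MS))
    b1 = int(round((start_ms + span_ms - t0) / BIN_MS))
    return counts[:, :, b0:b1].sum(axis=-1) / (span_ms / 1000.0)


def summarize_neuron(dataset: SpikeDataset, neuron_id: int,
                     ds_gate: float = 0.5, alpha: float = 0.05,
                     layer_depth: float = np.nan) -> NeuronSummary:
    """Full single-neuron analysis chain for one neuron.

    Tuning curves are averaged across the two drift directions unless the
    direction-selectivity index exceeds ``ds_gate``, in which case only the
    preferred direction enters.
    """
    nids = dataset.neuron_ids
    i = int(np.where(nids == neuron_id)[0][0])
    stim = dataset.stimuli
    t0, _ = dataset.window_ms
    thetas = np.sort(stim["theta_deg"].unique())
    b_thetas = np.sort(stim["b_theta_deg"].unique())
    drifts = np.sort(stim["drift"].unique())

    counts = dataset.binned_counts(BIN_MS)[i]  # (n_stim, n_trials, n_bins)
    base_bins = slice(0, int(round((0.0 - t0) / BIN_MS)))
    baseline = counts[:, :, base_bins].sum(axis=-1).mean() / (-t0 / 1000.0)

    evoked_bins = slice(int(round((0.0 - t0) / BIN_MS)), None)
    per_cond_mean = counts[:, :, evoked_bins].mean(axis=1)  # (n_stim, n_bins)
    win_start = best_window(per_cond_mean)

    rates = _rates_tensor(dataset, i, win_start, WINDOW_SPAN_MS) - baseline

    # index helpers -----------------------------------------------------
    stim_idx = {}
    sid_order = stim["stim_id"].to_numpy()
    pos = {s: j for j, s in enumerate(sid_order)}
    for row in stim.itertuples(index=False):
        stim_idx[(row.theta_deg, row.b_theta_deg, row.drift)] = pos[row.stim_id]

    def theta_trials(th, b, drift_sel):
        """Trial rates at (theta, b) pooled over the selected drifts."""
        return np.concatenate(
            [rates[stim_idx[(th, b, d)]] for d in drift_sel])

    # direction selectivity at lowest variance --------------------------
    b_low, b_high = b_thetas[0], b_thetas[-1]
    mean_by_td = {(th, d): rates[stim_idx[(th, b_low, d)]].mean()
                  for th in thetas for d in drifts}
    (th_best, d_best) = max(mean_by_td, key=mean_by_td.get)
    r_pref = mean_by_td[(th_best, d_best)]
    r_null = mean_by_td[(th_best, -d_best)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = direction_selectivity(r_pref, max(r_null, 0.0))
    drift_sel = [d_best] if (np.isfinite(ds) and ds > ds_gate) else list(drifts)

    # per-b_theta tuning curves, CV, fits --------------------------------
    curves, vm_fits, cvs = [], [], []
    for b in b_thetas:
        tr = np.stack([theta_trials(th, b, drift_sel) for th in thetas])
        curve = TuningCurve(
            b_theta=float(b), theta_values=thetas,
            mean_rate=tr.mean(axis=1),
            sem=tr.std(axis=1, ddof=1) / np.sqrt(tr.shape[1]),
            window=(win_start, WINDOW_SPAN_MS), trial_rates=tr)
        curves.append(curve)
        vm_fits.append(fit_von_mises(curve))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cvs.append(circular_variance(curve.mean_rate, thetas))
    cvs = np.asarray(cvs)
    fit_low = vm_fits[0]
    theta_pref = fit_low.theta_pref

    nkr = fit_vtf(b_thetas, cvs)

    # tuning significance per b_theta ------------------------------------
    def nearest_theta(target):
        d = np.abs((thetas - target + 90.0) % 180.0 - 90.0)
        return thetas[int(np.argmin(d))]

    th_pref_grid = nearest_theta(theta_pref if np.isfinite(theta_pref)
                                 else th_best)
    th_ortho_grid = nearest_theta(th_pref_grid + 90.0)
    p_tuned = np.array([
        tuning_significance(theta_trials(th_pref_grid, b, list(drifts)),
                            theta_trials(th_ortho_grid, b, list(drifts)))
        for b in b_thetas])
    bmax = b_theta_max(b_thetas, p_tuned, alpha)

    # preferred-orientation shift ----------------------------------------
    pref_shift = np.nan
    if np.isfinite(bmax):
        fit_at_max = vm_fits[int(np.where(b_thetas == bmax)[0][0])]
        if np.isfinite(fit_at_max.theta_pref) and np.isfinite(theta_pref):
            d = abs(fit_at_max.theta_pref - theta_pref) % 180.0
            pref_shift = min(d, 180.0 - d)

    # dynamics ------------------------------------------------------------
    def pooled_pref_spikes(b):
        sids = [stim_idx[(th_pref_grid, b, d)] for d in drifts]
        sid_vals = [sid_order[j] for j in sids]
        out = []
        for sid in sid_vals:
            out.extend(dataset.trial_spikes(neuron_id, int(sid)))
        return np.concatenate(out) if out else np.array([])

    # trial-mean rates for every 100 ms window start at once
    delay_starts = np.arange(0.0, 350.0 + 1, BIN_MS)
    csum = np.concatenate(
        [np.zeros(counts.shape[:2] + (1,)), np.cumsum(counts, axis=-1)],
        axis=-1)
    s_idx = np.round((delay_starts - t0) / BIN_MS).astype(int)
    nwin = int(round(100.0 / BIN_MS))
    win_rates = (csum[:, :, s_idx + nwin] - csum[:, :, s_idx]).mean(axis=1) \
        / 0.1  # (n_stim, n_starts), Hz

    def delay(b):
        curves_w = np.stack([
            np.mean([win_rates[stim_idx[(th, b, d)]] for d in drifts], axis=0)
            for th in thetas], axis=1) - baseline  # (n_starts, n_theta)
        return delay_to_peak(curves_w, delay_starts + 50.0)

    total_low = pooled_pref_spikes(b_low)
    total_high = pooled_pref_spikes(b_high)
    if len(total_low) + len(total_high) == 0:
        el_low = el_high = d_low = d_high = np.nan
        warnings.warn(f"neuron {neuron_id}: no spikes at preferred "
                      "orientation; dynamics undefined")
    else:
        el_low = early_late_ratio(total_low)
        el_high = early_late_ratio(total_high)
        d_low = delay(b_low)
        d_high = delay(b_high)

    return NeuronSummary(
        neuron_id=int(neuron_id), theta_pref=float(theta_pref),
        kappa=fit_low.kappa, r_squared=fit_low.r_squared,
        excluded=fit_low.excluded, ds_index=float(ds) if np.isfinite(ds) else np.nan,
        baseline_hz=float(baseline), window_start_ms=float(win_start),
        b_thetas=b_thetas, cv=cvs, curves=curves, vm_fits=vm_fits, nkr=nkr,
        p_tuned=p_tuned, b_theta_max=float(bmax),
        early_late_low=el_low, early_late_high=el_high,
        delay_low=d_low, delay_high=d_high,
        pref_shift_deg=pref_shift, layer_depth=layer_depth)


def summarize_population(dataset: SpikeDataset,
                         **kwargs) -> tuple[list[NeuronSummary], pd.DataFrame]:
    """Run :func:`summarize_neuron` for every neuron; returns list + table."""
    depths = {}
    if dataset.truth is not None:
        depths = {n.neuron_id: n.layer_depth for n in dataset.truth}
    summaries = [
        summarize_neuron(dataset, int(nid),
                         layer_depth=depths.get(int(nid), np.nan), **kwargs)
        for nid in dataset.neuron_ids]
    return summaries, pd.DataFrame([s.as_row() for s in summaries])
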