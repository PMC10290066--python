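"""Ground-truth model neurons and inhomogeneous-Poisson spike trains.

The generator emulates the statistical structure the downstream analyses
assume, without rendering any pixels: spikes are drawn from condition-level
rate functions

    r(t) = base + A(b_theta) * vm(theta; theta_pref, kappa_eff(b_theta)) * k(t)

where ``vm`` is a peak-normalized von Mises over orientation, ``k(t)`` a
difference-of-exponentials temporal kernel whose mean over the 300 ms
stimulation window is 1, and ``kappa_eff`` is solved per condition so that
the circular variance of the 300 ms mean-rate tuning curve equals the
neuron's Naka-Rushton variance-tuning function (VTF) at that ``b_theta``.

Two archetypes are drawn:

- *vulnerable*: steep nonlinear VTF (high n, low b_theta50), early-transient
  temporal kernel, mostly granular/infragranular depths;
- *resilient*: shallow near-linear VTF (low n, high b_theta50), late-ramping
  kernel, mostly supragranular depths.

Trial-to-trial variability is Poisson (optionally negative binomial via a
dispersion factor); spikes are sampled by thinning a homogeneous Poisson
process at the per-condition rate bound.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from vartune import stimuli

__all__ = [
    "GroundTruthNeuron",
    "SpikeDataset",
    "ArchetypeParams",
    "DEFAULT_ARCHETYPES",
    "sample_population",
    "rate_function",
    "simulate_trials",
    "vtf_value",
    "noiseless_tuning_curve",
]

#: Recording window around stimulus onset, ms.
RECORD_WINDOW_MS = (-200.0, 450.0)
STIM_DURATION_MS = 300.0


def vtf_value(b_theta_deg, f0, fmax, log_n, b_theta50):
    """Naka-Rushton VTF f0 + fmax * b^n / (b^n + b50^n), log-space stable."""
    b = np.asarray(b_theta_deg, dtype=float)
    n = np.exp(log_n)
    out = np.where(
        b > 0,
        f0 + fmax * expit(n * (np.log(np.maximum(b, 1e-300)) - np.log(b_theta50))),
        f0,
    )
    return out if out.ndim else float(out)


@dataclass
class ArchetypeParams:
    """Parameter distributions (means/SDs or uniform bounds) for one archetype."""

    log_n: tuple[float, float] = (4.5, 0.8)
    log_n_clip: tuple[float, float] = (3.0, 6.5)
    b_theta50: tuple[float, float] = (13.0, 3.0)
    b_theta50_clip: tuple[float, float] = (7.0, 20.0)
    f0_range: tuple[float, float] = (0.25, 0.55)
    cv_high_range: tuple[float, float] = (0.88, 0.98)
    temporal_profile: str = "transient"
    latency_range: tuple[float, float] = (20.0, 40.0)
    tau_rise_ms: float = 10.0
    tau_decay_ms: float = 60.0
    p_supragranular: float = 0.35


#: Defaults reproduce the direction of every archetype contrast: resilient
#: neurons are more linear (lower log n), transition later (higher b_theta50),
#: are better tuned at low variance (lower f0), ramp up late and sit mostly
#: above 800 um.
DEFAULT_ARCHETYPES = {
    "vulnerable": ArchetypeParams(),
    "resilient": ArchetypeParams(
        log_n=(2.0, 0.5), log_n_clip=(1.0, 3.0),
        b_theta50=(29.0, 4.0), b_theta50_clip=(22.0, 42.0),
        f0_range=(0.12, 0.40), cv_high_range=(0.85, 0.95),
        temporal_profile="ramping", latency_range=(30.0, 60.0),
        tau_rise_ms=120.0, tau_decay_ms=500.0,
        p_supragranular=0.8,
    ),
}


@dataclass
class GroundTruthNeuron:
    neuron_id: int
    archetype: str  # "vulnerable" | "resilient"
    theta_pref: float  # deg in [0, 180)
    r_max: float  # peak evoked rate at lowest variance, Hz
    r_base: float  # baseline rate, Hz
    f0: float
    fmax: float
    log_n: float
    b_theta50: float  # deg
    temporal_profile: str  # "transient" | "ramping"
    latency_ms: float
    tau_rise_ms: float
    tau_decay_ms: float
    layer_depth: float  # um below pia
    ds_index: float  # direction selectivity in [0, 1]
    pref_drift: int = 1
    kappa_tuning: float = field(default=np.nan)  # kappa_eff at lowest grid b_theta

    def vtf(self, b_theta_deg):
        return vtf_value(b_theta_deg, self.f0, self.fmax, self.log_n,
                         self.b_theta50)


def sample_population(n_neurons: int, resilient_fraction: float = 85 / 249,
                      seed: int = 0,
                      archetypes: dict | None = None) -> list[GroundTruthNeuron]:
    """Draw a reproducible population of ground-truth neurons.

    The archetype split is deterministic: ``round(fraction * n)`` resilient
    neurons, the rest vulnerable (ids are shuffled so archetypes interleave).
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if not 0 <= resilient_fraction <= 1:
        raise ValueError("resilient_fraction must be in [0, 1]")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)
    n_res = int(round(resilient_fraction * n_neurons))
    labels = np.array(["resilient"] * n_res
                      + ["vulnerable"] * (n_neurons - n_res))
    rng.shuffle(labels)

    neurons = []
    for nid, label in enumerate(labels):
        p = archetypes[label]
        f0 = rng.uniform(*p.f0_range)
        cv_high = rng.uniform(*p.cv_high_range)
        fmax = min(cv_high - f0, 1.0 - f0)
        neuron = GroundTruthNeuron(
            neuron_id=nid,
            archetype=str(label),
            theta_pref=rng.uniform(0.0, 180.0),
            r_max=float(np.clip(rng.lognormal(np.log(25.0), 0.4), 8.0, 70.0)),
            r_base=rng.uniform(2.0, 8.0),
            f0=f0,
            fmax=fmax,
            log_n=float(np.clip(rng.normal(*p.log_n), *p.log_n_clip)),
            b_theta50=float(np.clip(rng.normal(*p.b_theta50), *p.b_theta50_clip)),
            temporal_profile=p.temporal_profile,
            latency_ms=rng.uniform(*p.latency_range),
            tau_rise_ms=p.tau_rise_ms,
            tau_decay_ms=p.tau_decay_ms,
            layer_depth=(rng.uniform(150.0, 800.0)
                         if rng.random() < p.p_supragranular
                         else rng.uniform(800.0, 1600.0)),
            ds_index=float(rng.beta(2.0, 6.0)),
            pref_drift=int(rng.choice([-1, 1])),
        )
        neuron.kappa_tuning = _kappa_eff(neuron, float(np.min(stimuli.B_THETA_GRID_DEG)))
        neurons.append(neuron)
    return neurons


# ---------------------------------------------------------------------------
# Rate model


def _cv_of_kappa(kappa: float, theta_pref_deg: float,
                 thetas_deg=None) -> float:
    """Circular variance of a von Mises tuning curve sampled on the theta grid."""
    thetas = np.deg2rad(stimuli.THETA_GRID_DEG if thetas_deg is None
                        else np.asarray(thetas_deg))
    tp = np.deg2rad(theta_pref_deg)
    w = np.exp(kappa * (np.cos(2.0 * (thetas - tp)) - 1.0))
    return float(1.0 - np.abs(np.sum(w * np.exp(2j * thetas))) / np.sum(w))


def _kappa_eff(neuron: GroundTruthNeuron, b_theta_deg: float) -> float:
    """Concentration making the analytic tuning-curve CV match the VTF."""
    target = float(np.clip(neuron.vtf(b_theta_deg), 0.0, 1.0))
    lo, hi = 1e-8, 80.0
    cv_hi = _cv_of_kappa(hi, neuron.theta_pref)
    if target >= _cv_of_kappa(lo, neuron.theta_pref):
        return lo
    if target <= cv_hi:
        return hi
    return brentq(lambda k: _cv_of_kappa(k, neuron.theta_pref) - target,
                  lo, hi, xtol=1e-10)


def _amplitude(neuron: GroundTruthNeuron, b_theta_deg: float) -> float:
    """Evoked peak-rate amplitude; decreases 73% from b=0 to b=35 deg."""
    return neuron.r_max * (1.0 - 0.73 * b_theta_deg / 35.0)


def _kernel(t_ms, latency, tau_rise, tau_decay,
            t_off=STIM_DURATION_MS, tau_off=60.0):
    """Difference-of-exponentials kernel, mean 1 over [0, 300] ms.

    The drive decays with ``tau_off`` once the stimulus turns off at
    ``t_off`` (plus latency).
    """
    t = np.asarray(t_ms, dtype=float)
    s = t - latency
    k = np.where(s > 0, np.exp(-s / tau_decay) - np.exp(-s / tau_rise), 0.0)
    gate_t = t_off + latency
    k = np.where(t > gate_t, k * np.exp(-(t - gate_t) / tau_off), k)
    grid = np.arange(0.0, STIM_DURATION_MS, 1.0) + 0.5
    sg = grid - latency
    kg = np.where(sg > 0, np.exp(-sg / tau_decay) - np.exp(-sg / tau_rise), 0.0)
    norm = kg.mean()
    return k / norm if norm > 0 else k


def rate_function(neuron: GroundTruthNeuron, spec: stimuli.StimulusSpec,
                  t_ms, kappa_eff: float | None = None) -> np.ndarray:
    """Instantaneous firing rate (Hz) at times ``t_ms`` relative to onset.

    Baseline before onset; evoked response scaled down by ``1 - ds_index``
    for the non-preferred drift direction so that the direction-selectivity
    index of the rates equals ``ds_index``.
    """
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    if kappa_eff is None:
        kappa_eff = _kappa_eff(neuron, spec.b_theta)
    vm = np.exp(kappa_eff * (np.cos(2.0 * np.deg2rad(spec.theta - neuron.theta_pref)) - 1.0))
    amp = _amplitude(neuron, spec.b_theta)
    if spec.drift_direction != neuron.pref_drift:
        amp *= 1.0 - neuron.ds_index
    k = _kernel(t, neuron.latency_ms, neuron.tau_rise_ms, neuron.tau_decay_ms)
    rate = neuron.r_base + amp * vm * np.where(t >= 0, k, 0.0)
    return np.maximum(rate, 0.0)


def noiseless_tuning_curve(neuron: GroundTruthNeuron, b_theta_deg: float,
                           thetas_deg=None) -> np.ndarray:
    """Analytic baseline-subtracted 300 ms mean-rate tuning curve."""
    thetas = stimuli.THETA_GRID_DEG if thetas_deg is None else np.asarray(thetas_deg)
    kappa = _kappa_eff(neuron, b_theta_deg)
    vm = np.exp(kappa * (np.cos(2.0 * np.deg2rad(thetas - neuron.theta_pref)) - 1.0))
    return _amplitude(neuron, b_theta_deg) * vm


# ---------------------------------------------------------------------------
# Spike sampling


@dataclass
class SpikeDataset:
    """Per-neuron, per-trial spike-time lists with condition labels.

    ``spikes[(neuron_id, stim_id)]`` is a list of ``n_trials`` sorted arrays
    of spike times in ms relative to stimulus onset, all within
    ``window_ms``.
    """

    spikes: dict
    stimuli: pd.DataFrame  # stim_id, theta_deg, b_theta_deg, drift, sf_cpd
    n_trials: int
    window_ms: tuple = RECORD_WINDOW_MS
    truth: list[GroundTruthNeuron] | None = None
    _binned: dict = field(default_factory=dict, repr=False)

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.unique([k[0] for k in self.spikes])

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def trial_spikes(self, neuron_id: int, stim_id: int) -> list:
        return self.spikes[(neuron_id, stim_id)]

    def binned_counts(self, bin_ms: float = 10.0) -> np.ndarray:
        """Spike counts, shape (n_neurons, n_stim, n_trials, n_bins).

        Bins tile ``window_ms``; cached per bin width.
        """
        if bin_ms in self._binned:
            return self._binned[bin_ms]
        t0, t1 = self.window_ms
        n_bins = int(round((t1 - t0) / bin_ms))
        nids = self.neuron_ids
        sids = self.stimuli["stim_id"].to_numpy()
        out = np.zeros((len(nids), len(sids), self.n_trials, n_bins),
                       dtype=np.int16)
        sid_pos = {s: j for j, s in enumerate(sids)}
        nid_pos = {n: i for i, n in enumerate(nids)}
        edges = t0 + bin_ms * np.arange(n_bins + 1)
        for (nid, sid), trials in self.spikes.items():
            i, j = nid_pos[nid], sid_pos[sid]
            for tr, times in enumerate(trials):
                if len(times):
                    out[i, j, tr] = np.histogram(times, bins=edges)[0]
        self._binned[bin_ms] = out
        return out

    def events_frame(self) -> pd.DataFrame:
        """Tidy event list (neuron_id, stim_id, trial, t_ms)."""
        rows = {"neuron_id": [], "stim_id": [], "trial": [], "t_ms": []}
        for (nid, sid), trials in self.spikes.items():
            for tr, times in enumerate(trials):
                rows["neuron_id"].append(np.full(len(times), nid))
                rows["stim_id"].append(np.full(len(times), sid))
                rows["trial"].append(np.full(len(times), tr))
                rows["t_ms"].append(times)
        return pd.DataFrame({k: np.concatenate(v) if v else np.array([])
                             for k, v in rows.items()})

    # -- persistence --------------------------------------------------------

    def to_csv(self, prefix) -> None:
        """Write events + stimulus table + JSON metadata (+ truth if present)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.events_frame().to_csv(f"{prefix}_events.csv", index=False)
        self.stimuli.to_csv(f"{prefix}_stimuli.csv", index=False)
        meta = {"n_trials": self.n_trials, "window_ms": list(self.window_ms),
                "neuron_ids": [int(n) for n in self.neuron_ids]}
        Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))
        if self.truth is not None:
            pd.DataFrame([asdict(n) for n in self.truth]).to_csv(
                f"{prefix}_truth.csv", index=False)

    @classmethod
    def from_csv(cls, prefix) -> "SpikeDataset":
        prefix = Path(prefix)
        events = pd.read_csv(f"{prefix}_events.csv")
        stim = pd.read_csv(f"{prefix}_stimuli.csv")
        meta = json.loads(Path(f"{prefix}_meta.json").read_text())
        spikes = {}
        for nid in meta["neuron_ids"]:
            for sid in stim["stim_id"]:
                spikes[(int(nid), int(sid))] = [
                    np.array([]) for _ in range(meta["n_trials"])]
        if len(events):
            for (nid, sid, tr), grp in events.groupby(
                    ["neuron_id", "stim_id", "trial"]):
                spikes[(int(nid), int(sid))][int(tr)] = np.sort(
                    grp["t_ms"].to_numpy())
        truth = None
        tpath = Path(f"{prefix}_truth.csv")
        if tpath.exists():
            truth = [GroundTruthNeuron(**row)
                     for row in pd.read_csv(tpath).to_dict("records")]
        return cls(spikes=spikes, stimuli=stim, n_trials=meta["n_trials"],
                   window_ms=tuple(meta["window_ms"]), truth=truth)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["n_trials"] = self.n_trials
            h5.attrs["window_ms"] = self.window_ms
            h5.create_dataset("stimuli",
                              data=self.stimuli.to_records(index=False))
            g = h5.create_group("spikes")
            for (nid, sid), trials in self.spikes.items():
                for tr, times in enumerate(trials):
                    g.create_dataset(f"{nid}/{sid}/{tr}", data=times)

    @classmethod
    def from_hdf5(cls, path) -> "SpikeDataset":
        import h5py

        with h5py.File(path, "r") as h5:
            stim = pd.DataFrame(h5["stimuli"][()])
            n_trials = int(h5.attrs["n_trials"])
            window = tuple(h5.attrs["window_ms"])
            spikes = {}
            for nid in h5["spikes"]:
                for sid in h5[f"spikes/{nid}"]:
                    spikes[(int(nid), int(sid))] = [
                        h5[f"spikes/{nid}/{sid}/{tr}"][()]
                        for tr in sorted(h5[f"spikes/{nid}/{sid}"], key=int)]
        return cls(spikes=spikes, stimuli=stim, n_trials=n_trials,
                   window_ms=window)


def simulate_trials(population: list[GroundTruthNeuron],
                    stimulus_table: pd.DataFrame | None = None,
                    n_trials: int = 15, seed: int = 0,
                    dispersion: float = 1.0) -> SpikeDataset:
    """Sample spike trains for every (neuron, stimulus, trial) by thinning.

    Homogeneous Poisson candidates are drawn at the per-condition rate bound
    and accepted with probability ``r(t)/bound``, so counts in any window are
    Poisson with mean equal to the integrated rate.  ``dispersion > 1``
    switches to a negative-binomial trial count via a gamma-modulated rate
    (mean preserved, variance multiplied by ``dispersion``).
    """
    if stimulus_table is None:
        stimulus_table = stimuli.grid_table()
    t0, t1 = RECORD_WINDOW_MS
    span_s = (t1 - t0) / 1000.0
    ss = np.random.SeedSequence(seed)
    rngs = {n.neuron_id: np.random.default_rng(child)
            for n, child in zip(population, ss.spawn(len(population)))}
    tgrid = np.arange(t0, t1, 1.0) + 0.5

    spikes = {}
    for neuron in population:
        rng = rngs[neuron.neuron_id]
        kappa_cache = {}
        for row in stimulus_table.itertuples(index=False):
            b = float(row.b_theta_deg)
            if b not in kappa_cache:
                kappa_cache[b] = _kappa_eff(neuron, b)
            spec = stimuli.StimulusSpec(theta=float(row.theta_deg), b_theta=b,
                                        drift_direction=int(row.drift))
            profile = rate_function(neuron, spec, tgrid,
                                    kappa_eff=kappa_cache[b])
            bound = float(profile.max())
            if bound <= 0:
                spikes[(neuron.neuron_id, int(row.stim_id))] = [
                    np.array([]) for _ in range(n_trials)]
                continue
            if dispersion > 1.0:
                gain = rng.gamma(1.0 / (dispersion - 1.0),
                                 dispersion - 1.0, size=n_trials)
            else:
                gain = np.ones(n_trials)
            n_cand = rng.poisson(bound * span_s * gain)
            total = int(n_cand.sum())
            times = rng.uniform(t0, t1, total)
            accept = rng.uniform(0.0, bound * gain.repeat(n_cand)) \
                < profile[((times - t0).astype(int))] * gain.repeat(n_cand)
            trial_idx = np.repeat(np.arange(n_trials), n_cand)
            trials = [np.sort(times[(trial_idx == tr) & accept])
                      for tr in range(n_trials)]
            spikes[(neuron.neuron_id, int(row.stim_id))] = trials
    return SpikeDataset(spikes=spikes, stimuli=stimulus_table,
                        n_trials=n_trials, truth=list(population))
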