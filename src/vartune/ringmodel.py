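"""Recurrent ring network of orientation-tuned rate units.

``n_units`` passive units evenly tile orientation space; each obeys

    tau dV/dt + V = V_ff + V_exc - V_inh,      R(t) = alpha * max(V, 0)

with a feedforward von Mises drive of concentration ``kappa_ff`` (set from
the stimulus orientation variance ``b_theta``) and a recurrent drive given
by the ring convolution of the rates with a Mexican-hat kernel — the
difference of excitatory and inhibitory von Mises profiles of concentration
``kappa_exc`` / ``kappa_inh`` scaled by ``j_exc`` / ``j_inh``.  Recurrent
sums are spacing-weighted so results are insensitive to ``n_units``.

The default constants (tau = 10.8 ms, alpha = 10.6 Hz/mV, j_ff = 9.57,
j_exc = 1.71, j_inh = 2.0178) were fitted to cat V1 recordings in prior
work on this model family.  Strongly excitation-dominated kernels can push
the linear loop gain above one; such configurations diverge and are flagged
unstable rather than reported.

``model_vtf`` sweeps a grid of variances (20 levels by default, 32 stimulus
orientations each), reads out the steady tuning curve of the unit preferring
the center orientation, and summarizes the resulting circular-variance
curve with a Naka-Rushton fit.  ``scan`` maps those summaries over a
``kappa_exc`` x ``kappa_inh`` grid (200 x 200 = 40,000 cells at full
resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import i0e

from vartune.stimuli import btheta_from_kappa, kappa_from_btheta  # noqa: F401
from vartune import stimuli, tuning

__all__ = [
    "RingConfig",
    "RingResult",
    "von_mises_profile",
    "feedforward_input",
    "connectivity_kernel",
    "simulate",
    "model_vtf",
    "feedforward_mode",
    "scan",
]

RATE_BOUND_HZ = 1e8  # divergence flag threshold


@dataclass
class RingConfig:
    n_units: int = 256
    tau_m: float = 10.8  # ms
    alpha: float = 10.6  # Hz/mV
    j_ff: float = 9.57  # feedforward gain
    j_exc: float = 1.71  # recurrent excitatory gain
    j_inh: float = 2.0178  # recurrent inhibitory gain
    kappa_exc: float = 2.5
    kappa_inh: float = 2.0
    dt: float = 0.5  # ms
    t_max: float = 300.0  # ms
    steady_ms: float = 50.0  # averaging span for the steady state

    def __post_init__(self):
        for name in ("tau_m", "alpha", "j_ff", "kappa_exc", "kappa_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt > self.tau_m / 10.0:
            raise ValueError("dt must be <= tau_m / 10 for accurate stepping")

    @property
    def theta_prefs(self) -> np.ndarray:
        """Preferred orientations evenly tiling [-pi, pi), radians."""
        return -np.pi + 2.0 * np.pi * np.arange(self.n_units) / self.n_units

    @property
    def spacing(self) -> float:
        return 2.0 * np.pi / self.n_units


@dataclass
class RingResult:
    config: RingConfig
    theta: float  # stimulus orientation, radians
    kappa_ff: float
    v: np.ndarray  # final membrane potentials
    rates: np.ndarray = field(repr=False, default=None)  # (n_steps, n_units)
    t_ms: np.ndarray = field(repr=False, default=None)
    steady_rates: np.ndarray = None  # mean over the last steady_ms
    tau_half_ms: float = np.nan  # readout delay to half the steady rate
    unstable: bool = False


def von_mises_profile(delta_rad, kappa):
    """exp(kappa cos(2 delta)) / (2 pi I0(kappa)): unit mass over the circle.

    Computed via the exponentially scaled Bessel function so it stays finite
    for the very large concentrations that near-zero orientation variance
    maps to.
    """
    return np.exp(kappa * (np.cos(2.0 * np.asarray(delta_rad)) - 1.0)) \
        / (2.0 * np.pi * i0e(kappa))


def feedforward_input(theta: float, kappa_ff: float,
                      config: RingConfig) -> np.ndarray:
    """Feedforward drive j_ff * vm(theta_pref - theta; kappa_ff) per unit."""
    if kappa_ff < stimuli.KAPPA_MIN:
        raise ValueError(
            f"kappa_ff={kappa_ff:g} outside the b_theta mapping domain "
            f"(needs kappa >= {stimuli.KAPPA_MIN:.4f})")
    return config.j_ff * von_mises_profile(config.theta_prefs - theta,
                                           kappa_ff)


def connectivity_kernel(config: RingConfig) -> np.ndarray:
    """Circulant recurrent matrix (spacing-weighted Mexican hat).

    ``K[i, j]`` couples unit j's rate into unit i's potential; rows are the
    difference of normalized von Mises profiles times the ring spacing.
    """
    delta = config.theta_prefs[:, None] - config.theta_prefs[None, :]
    c_tot = (config.j_exc * von_mises_profile(delta, config.kappa_exc)
             - config.j_inh * von_mises_profile(delta, config.kappa_inh))
    return c_tot * config.spacing


def kernel_profile(config: RingConfig) -> np.ndarray:
    """C_tot as a function of orientation offset (one row of the kernel)."""
    delta = config.theta_prefs
    return (config.j_exc * von_mises_profile(delta, config.kappa_exc)
            - config.j_inh * von_mises_profile(delta, config.kappa_inh))


def ring_convolve(signal: np.ndarray, profile: np.ndarray,
                  spacing: float) -> np.ndarray:
    """Circular convolution over the ring, spacing-weighted (FFT-based).

    ``signal`` may be (n_units,) or (n_units, n_stim); the convolution runs
    along the unit axis.
    """
    sig_hat = np.fft.fft(signal, axis=0)
    prof_hat = np.fft.fft(profile)
    if signal.ndim == 2:
        prof_hat = prof_hat[:, None]
    return np.real(np.fft.ifft(sig_hat * prof_hat, axis=0)) * spacing


def simulate(config: RingConfig, theta: float = 0.0,
             b_theta_deg: float | None = None,
             kappa_ff: float | None = None,
             v_init: np.ndarray | None = None,
             record: bool = False,
             v_ff: np.ndarray | None = None) -> RingResult:
    """Integrate the ring to ``t_max`` (exponential Euler).

    The stimulus turns on at t = 0; either ``b_theta_deg`` (mapped to
    ``kappa_ff``) or ``kappa_ff`` directly selects the input spread.  A
    rate exceeding ``RATE_BOUND_HZ`` flags the configuration unstable.
    """
    if kappa_ff is None:
        if b_theta_deg is None:
            raise ValueError("provide b_theta_deg or kappa_ff")
        kappa_ff = kappa_from_btheta(np.deg2rad(b_theta_deg))
    if v_ff is None:
        v_ff = feedforward_input(theta, kappa_ff, config)
    kernel = connectivity_kernel(config)
    n_steps = int(round(config.t_max / config.dt))
    decay = np.exp(-config.dt / config.tau_m)
    v = np.zeros(config.n_units) if v_init is None else v_init.astype(float)
    rates_hist = np.empty((n_steps, config.n_units)) if record else None
    n_steady = max(1, int(round(config.steady_ms / config.dt)))
    steady_acc = np.zeros(config.n_units)
    readout = int(np.argmin(np.abs(
        (config.theta_prefs - theta + np.pi / 2) % np.pi - np.pi / 2)))
    readout_rates = np.empty(n_steps)
    unstable = False
    for step in range(n_steps):
        r = config.alpha * np.maximum(v, 0.0)
        target = v_ff + kernel @ r
        v = target + (v - target) * decay
        r = config.alpha * np.maximum(v, 0.0)
        if record:
            rates_hist[step] = r
        readout_rates[step] = r[readout]
        if step >= n_steps - n_steady:
            steady_acc += r
        if r.max() > RATE_BOUND_HZ:
            unstable = True
            if record:
                rates_hist = rates_hist[:step + 1]
            readout_rates = readout_rates[:step + 1]
            break
    steady = steady_acc / n_steady if not unstable else np.full(
        config.n_units, np.nan)
    tau_half = np.nan
    if not unstable and steady[readout] > 0:
        half = steady[readout] / 2.0
        above = np.nonzero(readout_rates >= half)[0]
        if len(above):
            tau_half = float((above[0] + 1) * config.dt)
    t_ms = (np.arange(len(readout_rates)) + 1) * config.dt
    return RingResult(config=config, theta=float(theta),
                      kappa_ff=float(kappa_ff), v=v,
                      rates=rates_hist, t_ms=t_ms if record else None,
                      steady_rates=steady, tau_half_ms=tau_half,
                      unstable=unstable)


def _steady_profiles(config: RingConfig, kappa_ffs,
                     rf_profile: np.ndarray | None = None):
    """Simulate one centered stimulus per variance level, all levels at once.

    The stimulus sits at orientation 0, on a unit's preference, so by ring
    translation symmetry the steady population profile over preferred
    orientations IS the steady tuning curve of the center readout unit over
    stimulus orientations.

    Returns (steady profiles (n_units, n_levels), center-unit rate time
    courses (n_steps, n_levels), unstable flag).
    """
    v_ff = np.stack([feedforward_input(0.0, k, config) for k in kappa_ffs],
                    axis=1)  # (n_units, n_levels)
    if rf_profile is not None:
        v_ff = ring_convolve(v_ff, rf_profile, config.spacing)
    kernel = connectivity_kernel(config)
    n_steps = int(round(config.t_max / config.dt))
    decay = np.exp(-config.dt / config.tau_m)
    v = np.zeros_like(v_ff)
    n_steady = max(1, int(round(config.steady_ms / config.dt)))
    steady_acc = np.zeros_like(v_ff)
    center = int(np.argmin(np.abs(
        (config.theta_prefs + np.pi / 2) % np.pi - np.pi / 2)))
    readout_rates = np.empty((n_steps, v_ff.shape[1]))
    for step in range(n_steps):
        r = config.alpha * np.maximum(v, 0.0)
        target = v_ff + kernel @ r
        v = target + (v - target) * decay
        r = config.alpha * np.maximum(v, 0.0)
        readout_rates[step] = r[center]
        if step >= n_steps - n_steady:
            steady_acc += r
        if r.max() > RATE_BOUND_HZ:
            return None, None, True
    return steady_acc / n_steady, readout_rates, False


def model_vtf(config: RingConfig, n_btheta: int = 20, n_theta: int = 32,
              b_theta_range=(0.5, 35.0), theta_span_deg: float = 75.0,
              rf_kappa: float | None = None) -> dict:
    """Variance-tuning function of the model readout unit.

    Simulates ``n_btheta`` variance levels, reads the steady tuning curve of
    the center unit at ``n_theta`` stimulus orientations tiling
    [-span, span] degrees (snapped to the unit grid), computes the circular
    variance per level, and fits a Naka-Rushton.  Returns a dict with the
    curves, CV values, the fit, ``tau_half_ms`` (delay to half the steady
    rate at the lowest variance) and an ``unstable`` flag.
    """
    bthetas = np.linspace(*b_theta_range, n_btheta)
    # snap stimulus orientations to unit preferences: near-zero variance maps
    # to a feedforward profile narrower than the ring spacing, so off-grid
    # orientations would drive no unit at all
    thetas_rad = np.deg2rad(np.linspace(-theta_span_deg, theta_span_deg,
                                        n_theta))
    thetas_rad = np.round(thetas_rad / config.spacing) * config.spacing
    # the grid must sample the curve's peak: at near-zero variance the curve
    # is close to a delta at 0 and a grid of tail samples would read as flat
    thetas_rad[int(np.argmin(np.abs(thetas_rad)))] = 0.0
    thetas_deg = np.rad2deg(thetas_rad)
    rf_profile = (von_mises_profile(config.theta_prefs, rf_kappa)
                  if rf_kappa is not None else None)
    kappa_ffs = [kappa_from_btheta(np.deg2rad(b)) for b in bthetas]
    steady, readout_rates, unstable = _steady_profiles(config, kappa_ffs,
                                                       rf_profile)
    if unstable:
        return {"b_thetas": bthetas, "thetas_deg": thetas_deg, "cv": None,
                "curves": None, "nkr": None, "tau_half_ms": np.nan,
                "unstable": True}
    # sample the population profile at the stimulus orientations
    d = np.abs((config.theta_prefs[None, :] - thetas_rad[:, None]
                + np.pi / 2) % np.pi - np.pi / 2)
    unit_idx = np.argmin(d, axis=1)
    curves = steady[unit_idx, :].T  # (n_levels, n_theta)
    cvs = np.asarray([tuning.circular_variance(c, thetas_deg)
                      for c in curves])
    tau_half = np.nan
    center_steady = readout_rates[-1, 0]
    peak0 = curves[0][int(np.argmin(np.abs(thetas_deg)))]
    if peak0 > 0:
        above = np.nonzero(readout_rates[:, 0] >= peak0 / 2.0)[0]
        if len(above):
            tau_half = float((above[0] + 1) * config.dt)
    del center_steady
    nkr = tuning.fit_vtf(bthetas, cvs)
    return {"b_thetas": bthetas, "thetas_deg": thetas_deg, "cv": cvs,
            "curves": curves, "nkr": nkr,
            "tau_half_ms": tau_half, "unstable": False}


def feedforward_mode(config: RingConfig, rf_kappa: float,
                     **vtf_kwargs) -> dict:
    """VTF with recurrence disabled and the input convolved with a
    von Mises receptive field of concentration ``rf_kappa``.

    The returned dict gains ``rf_hwhh_deg`` (half-width at half-height of
    the receptive field).
    """
    ff_config = replace(config, j_exc=0.0, j_inh=0.0)
    out = model_vtf(ff_config, rf_kappa=rf_kappa, **vtf_kwargs)
    out["rf_hwhh_deg"] = tuning.hwhh(rf_kappa) if rf_kappa >= -np.log(0.5) \
        else np.nan
    return out


def scan(kappa_range=(0.35, 7.0), steps: int = 200,
         config: RingConfig | None = None, **vtf_kwargs) -> dict:
    """Map VTF summaries over the kappa_exc x kappa_inh grid.

    Returns arrays of shape (steps, steps): ``log_n``, ``b_theta50``,
    ``f0`` and ``tau_half_ms`` (rows index kappa_exc, columns kappa_inh).
    Unstable cells are NaN.  Full resolution (200 x 200) is a long,
    cluster-scale run; pass small ``steps`` and reduced ``vtf_kwargs`` for
    desk-scale maps.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    config = config or RingConfig()
    kappas = np.linspace(*kappa_range, steps)
    shape = (steps, steps)
    maps = {k: np.full(shape, np.nan) for k in
            ("log_n", "b_theta50", "f0", "f_max", "tau_half_ms")}
    maps["flagged"] = np.zeros(shape, dtype=bool)
    for i, ke in enumerate(kappas):
        for j, ki in enumerate(kappas):
            cfg = replace(config, kappa_exc=float(ke), kappa_inh=float(ki))
            out = model_vtf(cfg, **vtf_kwargs)
            if out["unstable"] or out["nkr"] is None:
                continue
            maps["log_n"][i, j] = out["nkr"].log_n
            maps["b_theta50"][i, j] = out["nkr"].b_theta50
            maps["f0"][i, j] = out["nkr"].f0
            maps["f_max"][i, j] = out["nkr"].f_max
            maps["flagged"][i, j] = out["nkr"].flagged
            maps["tau_half_ms"][i, j] = out["tau_half_ms"]
    maps["kappas"] = kappas
    return maps
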