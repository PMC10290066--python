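"""Motion-Cloud stimulus synthesis and the experimental stimulus grid.

Motion Clouds are band-pass filtered white-noise textures whose Fourier
amplitude is shaped by an orientation envelope with mean orientation ``theta``
and orientation variance ``b_theta``, times a radial (spatial-frequency)
band-pass envelope.  The orientation envelope is

    O(theta_f) = exp( cos(2 (theta_f - theta)) / (4 * b_theta^2) )

with ``theta_f`` the angle of a frequency component in the Fourier plane and
``b_theta`` in radians.  The experiment tiles 12 mean orientations (0..180 in
15 deg steps) against 8 variance levels (~0..35 deg), each drifting in both
directions orthogonal to the mean orientation and repeated 15 times.

The module also converts between ``b_theta`` and the von Mises concentration
``kappa`` used by the feedforward drive of the ring model,

    b_theta = sqrt( 0.5 * arccos((log 0.5 + kappa)/kappa) / (2 log 2) ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "THETA_GRID_DEG",
    "B_THETA_GRID_DEG",
    "StimulusSpec",
    "CloudFrames",
    "orientation_envelope",
    "synthesize_cloud",
    "stimulus_grid",
    "grid_table",
    "trial_table",
    "btheta_from_kappa",
    "kappa_from_btheta",
    "KAPPA_MIN",
]

#: 12 mean orientations evenly tiling [0, 180) degrees.
THETA_GRID_DEG = np.arange(12) * 15.0

#: 8 orientation-variance levels, evenly spaced 0..35 deg with the lowest
#: level set to 0.5 deg (the envelope diverges at exactly 0).
B_THETA_GRID_DEG = np.where(np.linspace(0.0, 35.0, 8) == 0.0, 0.5,
                            np.linspace(0.0, 35.0, 8))

#: Smallest kappa for which the b_theta <-> kappa relation is defined
#: (the arccos argument reaches -1).
KAPPA_MIN = -np.log(0.5) / 2.0


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus condition.

    Angles in degrees; ``theta`` wraps modulo 180.  ``drift_direction`` is the
    sign of the drift orthogonal to the mean orientation.
    """

    theta: float
    b_theta: float
    drift_direction: int = 1
    drift_speed: float = 10.0  # deg/s
    spatial_freq: float = 0.9  # cycles/deg
    duration_ms: float = 300.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", float(self.theta) % 180.0)
        if not self.b_theta > 0:
            raise ValueError("b_theta must be strictly positive (the "
                             "orientation envelope divides by b_theta^2)")
        if self.drift_direction not in (-1, 1):
            raise ValueError("drift_direction must be +1 or -1")


@dataclass
class CloudFrames:
    """Rendered stimulus movie: luminance frames in [0, 1]."""

    frames: np.ndarray  # (n_frames, height, width)
    pixel_deg: float
    seed: int
    spec: StimulusSpec = field(repr=False, default=None)


def orientation_envelope(theta_deg, b_theta_deg, freq_angle_rad):
    """Orientation envelope over the Fourier plane.

    Parameters
    ----------
    theta_deg, b_theta_deg
        Mean orientation and orientation variance, degrees.
    freq_angle_rad
        Angle(s) of the frequency components, radians.

    The envelope is pi-periodic in both the frequency angle and ``theta`` and
    attains its maximum ``exp(1/(4 b^2))`` where the frequency angle equals
    the mean orientation.
    """
    if not np.all(np.asarray(b_theta_deg) > 0):
        raise ValueError("b_theta must be strictly positive")
    theta = np.deg2rad(theta_deg)
    b = np.deg2rad(b_theta_deg)
    return np.exp(np.cos(2.0 * (np.asarray(freq_angle_rad) - theta))
                  / (4.0 * b ** 2))


def _radial_envelope(f_radial, sf_cpd, bandwidth_octaves=1.0):
    """Log-Gaussian band-pass in spatial frequency (zero at DC)."""
    sigma = bandwidth_octaves / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    with np.errstate(divide="ignore"):
        logf = np.log2(np.where(f_radial > 0, f_radial, np.nan) / sf_cpd)
    env = np.exp(-logf ** 2 / (2.0 * sigma ** 2))
    return np.where(f_radial > 0, np.nan_to_num(env), 0.0)


def synthesize_cloud(spec: StimulusSpec, size_px: int = 128, seed: int = 0,
                     pixel_deg: float = 0.05, frame_rate: float = 60.0,
                     bandwidth_octaves: float = 1.0) -> CloudFrames:
    """Render a drifting Motion Cloud.

    White noise is shaped in the Fourier plane by the orientation envelope and
    a log-Gaussian radial band-pass centered on ``spec.spatial_freq``; drift
    is a per-frame Fourier phase advance along the mean frequency axis.
    Frames are jointly (per-stimulus) rescaled to [0, 1]; identical
    ``spec`` + ``seed`` give bit-identical output.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(size_px, d=pixel_deg)  # cycles/deg
    fy = np.fft.fftfreq(size_px, d=pixel_deg)
    FX, FY = np.meshgrid(fx, fy)
    f_rad = np.hypot(FX, FY)
    f_ang = np.arctan2(FY, FX)

    # peak-normalized orientation envelope (the raw exp(cos/(4 b^2)) form
    # overflows for narrow bandwidths; only the shape matters here)
    th, bb = np.deg2rad(spec.theta), np.deg2rad(spec.b_theta)
    orient = np.exp((np.cos(2.0 * (f_ang - th)) - 1.0) / (4.0 * bb ** 2))
    env = orient * _radial_envelope(f_rad, spec.spatial_freq,
                                    bandwidth_octaves)
    noise_hat = np.fft.fft2(rng.standard_normal((size_px, size_px)))
    base_hat = noise_hat * env

    n_frames = max(1, int(round(spec.duration_ms / 1000.0 * frame_rate)))
    # Drift orthogonal to the stimulus orientation = along the mean frequency
    # axis; displacement per frame in degrees.
    th = np.deg2rad(spec.theta)
    step = spec.drift_direction * spec.drift_speed / frame_rate
    dx, dy = step * np.cos(th), step * np.sin(th)
    shift = np.exp(-2j * np.pi * (FX * dx + FY * dy))

    frames = np.empty((n_frames, size_px, size_px))
    phase = np.ones_like(base_hat)
    for t in range(n_frames):
        frames[t] = np.real(np.fft.ifft2(base_hat * phase))
        phase = phase * shift
    lo, hi = frames.min(), frames.max()
    if hi > lo:
        frames = (frames - lo) / (hi - lo)
    frames = 0.5 + spec.contrast * (frames - 0.5)
    return CloudFrames(frames=frames, pixel_deg=pixel_deg, seed=seed,
                       spec=spec)


def stimulus_grid(drift_directions=(1, -1), **spec_kwargs) -> list[StimulusSpec]:
    """The experimental grid: 12 theta x 8 b_theta x drift directions.

    Returns one :class:`StimulusSpec` per (theta, b_theta, drift) triple;
    96 unique (theta, b_theta) pairs.
    """
    return [
        StimulusSpec(theta=th, b_theta=b, drift_direction=d, **spec_kwargs)
        for th in THETA_GRID_DEG
        for b in B_THETA_GRID_DEG
        for d in drift_directions
    ]


def grid_table(drift_directions=(1, -1)) -> pd.DataFrame:
    """Stimulus grid as a table (stim_id, theta_deg, b_theta_deg, drift, sf_cpd)."""
    specs = stimulus_grid(drift_directions)
    return pd.DataFrame(
        {
            "stim_id": np.arange(len(specs)),
            "theta_deg": [s.theta for s in specs],
            "b_theta_deg": [s.b_theta for s in specs],
            "drift": [s.drift_direction for s in specs],
            "sf_cpd": [s.spatial_freq for s in specs],
        }
    )


def trial_table(n_trials: int = 15) -> pd.DataFrame:
    """Full trial table: each grid stimulus repeated ``n_trials`` times."""
    grid = grid_table()
    reps = grid.loc[grid.index.repeat(n_trials)].reset_index(drop=True)
    reps["trial"] = np.tile(np.arange(n_trials), len(grid))
    return reps


def btheta_from_kappa(kappa: float) -> float:
    """Orientation variance (radians) from von Mises concentration.

    Defined for ``kappa >= -log(0.5)/2``; decreasing in kappa, with
    b_theta -> 0 as kappa -> infinity.
    """
    kappa = float(kappa)
    if kappa < KAPPA_MIN:
        raise ValueError(
            f"kappa={kappa:g} below domain bound -log(0.5)/2 ~= {KAPPA_MIN:.4f}")
    arg = (np.log(0.5) + kappa) / kappa
    return float(np.sqrt(0.5 * np.arccos(np.clip(arg, -1.0, 1.0))
                         / (2.0 * np.log(2.0))))


def kappa_from_btheta(b_theta_rad: float) -> float:
    """Inverse of :func:`btheta_from_kappa` by bracketed root finding."""
    b = float(b_theta_rad)
    b_max = btheta_from_kappa(KAPPA_MIN)
    if not 0 < b <= b_max:
        raise ValueError(f"b_theta must lie in (0, {b_max:.4f}] rad")
    lo, hi = KAPPA_MIN, 1.0
    while btheta_from_kappa(hi) > b:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - b bounded away from 0 above
            break
    return float(brentq(lambda k: btheta_from_kappa(k) - b, lo, hi,
                        xtol=1e-12, rtol=1e-14))


def _replace_spec(spec: StimulusSpec, **kw) -> StimulusSpec:
    return replace(spec, **kw)
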