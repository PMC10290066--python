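# Methods

This note documents the models, estimators and design choices behind
`vartune`, the defaults they use, and what the synthetic-data tests do and
do not establish about real recordings.

## Stimulus model

Motion Clouds are realized in the Fourier plane as white noise multiplied by
an orientation envelope and a radial spatial-frequency envelope, then
inverse-transformed. The orientation envelope is
`O(θ_f) = exp(cos(2(θ_f − θ)) / 4B_θ²)` with the variance parameter B_θ in
radians; it is π-periodic, peaks where the frequency angle equals the mean
orientation θ, and broadens as B_θ grows. Inside the synthesizer the
envelope is normalized to peak 1 (the raw form overflows for the narrowest
grid level); the public `orientation_envelope` keeps the literal expression.

Fixed design parameters: spatial frequency 0.9 cycles/deg with a
log-Gaussian band-pass of one octave (full width at half maximum; the
bandwidth is configurable since only the center frequency is constrained by
the experimental design), drift at 10 deg/s orthogonal to θ implemented as a
per-frame Fourier phase advance at 60 Hz, frames rescaled to [0, 1] jointly
per stimulus (full-contrast presentation). The experimental grid tiles 12
orientations (15° steps) × 8 variance levels evenly spaced 0–35°, with the
"≈0°" level set to 0.5° because the envelope diverges at exactly zero. With
two drift directions and 15 repeats the trial table has 2880 rows.

Two distinct variance↔concentration conventions exist and must not be
conflated: the stimulus envelope's small-angle rule B_θ ≈ 1/√κ, and the
ring model's mapping `B_θ = √(0.5·arccos((log½ + κ_ff)/κ_ff) / 2 log 2)`
used for the feedforward drive. The latter scales as κ^(−1/4) for large κ,
so the two disagree by tens of percent over the experimental range; the
package implements both where each belongs and the inverse of the model
mapping by bracketed root finding (round-trip error < 1e-8).

## Synthetic recordings

Spikes are generated from condition-level rate functions, not from rendered
pixels: every downstream analysis consumes only condition labels, so a
stimulus-to-spikes encoding model would add untestable structure without
widening coverage. The rate of a neuron for condition (θ, B_θ) is

    r(t) = base + A(B_θ) · vm(θ; θ_pref, κ_eff(B_θ)) · k(t)

with `vm` a peak-normalized von Mises and `k(t)` a difference-of-exponentials
kernel (mean 1 over the 300 ms stimulation window, exponential cutoff with
τ = 60 ms after stimulus offset). κ_eff is solved per condition by bracketed
root finding so that the circular variance of the analytic 300 ms tuning
curve equals the neuron's Naka–Rushton VTF at that B_θ (within 1e-3); this
makes the generator's ground truth exactly the quantity the analysis chain
estimates. The amplitude declines linearly to 27% of its low-variance value
at B_θ = 35°, matching the population-level amplitude loss the design
emulates. Direction selectivity scales the non-preferred drift's amplitude
by (1 − ds), so the rate-based selectivity index equals `ds` exactly.

Archetype-conditional parameter distributions are not constrained
numerically by the source material, so the defaults were chosen once as
field-realistic values that reproduce the *direction* of every archetype
contrast and were not revisited afterwards:

| parameter | vulnerable | resilient |
| --- | --- | --- |
| log n | N(4.5, 0.8) clipped [3, 6.5] | N(2.0, 0.5) clipped [1, 3] |
| B_θ50 (deg) | N(13, 3) clipped [7, 20] | N(29, 4) clipped [22, 42] |
| f0 | U(0.25, 0.55) | U(0.12, 0.40) |
| CV at 35° | U(0.88, 0.98) | U(0.85, 0.95) |
| temporal kernel | transient (τ_rise 10 ms, τ_decay 60 ms, latency 20–40 ms) | ramping (τ_rise 120 ms, τ_decay 500 ms, latency 30–60 ms) |
| supragranular probability | 0.35 | 0.8 |

Shared draws: peak rate log-normal around 25 Hz (clipped 8–70 Hz), baseline
U(2, 8) Hz, preferred orientation uniform, direction index Beta(2, 6). The
vulnerable log n center sits well below the steepest single-cell example in
the literature because a VTF that is an exact step is not identifiable from
8 variance levels — the transition point is only bracketed — and the
generator is meant to define a well-posed recovery problem at the
experimental design.

Trial noise is Poisson via thinning (homogeneous candidates at the
per-condition rate bound, accepted with probability r(t)/bound), with an
optional gamma-modulated negative-binomial mode. What passing tests show:
the estimators recover parameters of rate-modulated (possibly
overdispersed) Poisson spiking with stationary tuning. What they do not
show: robustness to cross-neuron noise correlations, slow gain drift,
non-Poisson bursting, or spike-sorting artifacts, none of which the
generator emulates.

## Single-neuron estimators

- **Analysis window**: 300 ms window slid in 10 ms steps over [0, 450] ms,
  maximizing the variance across conditions of the trial-mean spike count;
  ties break to the earliest window. All-zero input warns and falls back to
  [0, 300] ms.
- **Baseline**: mean rate in [−200, 0) ms, subtracted before all tuning
  metrics. Negative baseline-subtracted rates are clipped at zero *only*
  for circular variance (the resultant needs non-negative weights);
  clipping-vs-offsetting is an open choice and clipping is the conservative
  one (it cannot manufacture selectivity from noise at untuned conditions).
- **Tuning curves** average the two drift directions unless the direction
  index exceeds 0.5, in which case only the preferred direction enters.
- **Von Mises fits** use analytic-Jacobian bounded least squares with two
  concentration starts; R² < 0.75 at the lowest variance flags the neuron
  excluded, mirroring standard selectivity screens.
- **Naka–Rushton fits** run in log space (`f0 + fmax·σ(n(log B − log B50))`),
  which is exact and overflow-free at any steepness, with bounds f0, fmax ∈
  [0,1], B_θ50 ∈ [0.1, 44]°, log n ∈ [0.1, 10]. Multi-start covers quantiles
  of the B grid plus the steepest observed rise, so near-step VTFs converge
  to the bracketing interval of the transition. Degenerate flat fits pin
  fmax ≈ 0 and are flagged. `log n` is reported rather than n.
- **Tuning significance** is a two-sided Wilcoxon signed-rank (continuity
  corrected, zero differences discarded) between trial rates at the
  preferred and orthogonal grid orientations; fewer than 6 informative
  pairs yields "not tuned". B_θmax is the largest grid variance with
  p < 0.05.
- **Dynamics**: early/late log spike-count ratio log((late+1)/(early+1))
  with early = [0, 100) ms and late = (200, 450] ms (ε = 1 additive
  smoothing), and delay-to-peak as the center of the 100 ms window
  maximizing the baseline-subtracted tuning-curve amplitude.

## Clustering and the vulnerability score

Ten features per neuron (log n, B_θ50, f0, B_θmax, CV and early/late ratio
and delay at the lowest and highest variance) are median-imputed (error if
any column exceeds 20% missing), z-scored, reduced to two principal
components and split by K-means (k = 2, k-means++, 50 restarts, fixed
seed). The cluster with the larger mean B_θmax is labeled resilient — a
deterministic rule, since K-means label indices are arbitrary. The
within-cluster sum of squares is reported for k = 1…8.

The continuous score combines seven variables, each min-max normalized over
the population and oriented so that larger = more resilient (B_θ50, B_θmax,
early/late ratio and delay enter positively; log n, f0 and CV as their
complements), weighted by the mean absolute PC-1/PC-2 loading of the
corresponding feature (weights normalized to sum 1). The weighted
resilience sum is subtracted from one and affinely rescaled to [0, 1]
(0 = most resilient, 1 = most vulnerable). The published formulation of
this score is ambiguous about signs and normalization; this reading is the
one under which every term pushes in the direction of the documented group
contrasts, and both the weight source (which PCs, absolute vs signed) and
the variable set are configurable.

## Decoding

Spike counts in 100 ms windows slid from −200 to 400 ms in 10 ms steps (61
windows; windows crossing the recording edge truncate at 450 ms) feed an
L2-penalized multinomial logistic regression per window (C = 1, lbfgs,
stratified 15% held-out split, seeds logged). Orientation decoders are
trained separately per variance level; the joint task uses labels
θ-index × 8 + B_θ-index. Performance is balanced accuracy (mean per-class
recall; chance 1/K). Population tuning curves are the mean held-out class
likelihood re-centered on the true class (held-out rather than training
trials, the unbiased choice), with sharpness summarized by circular
variance. Marginalizing the joint decoder sums probabilities over the
variance axis. Accuracy time courses over [0, 300] ms are fitted with
`σ(t) = max_acc/(1 + e^{−k(t−τ)}) + min_acc`; the printed source form omits
the time variable and this is the standard sigmoid consistent with calling
τ a time constant. Flat curves leave k unidentifiable and are flagged.

Group comparisons resample (with replacement) equal-size groups, decode
each resample, and compare groups per window with a Wilcoxon signed-rank
across resamples, reporting significance only for ≥ 2 consecutive windows.
Note that 5 resamples — the documented default — cannot reach p < 0.01
(minimum two-sided p = 1/16 for 5 pairs); both the resample count and the
threshold are configurable and the tests use 10 resamples at p < 0.05.
Score-sorted decoding slides ~7 overlapping groups of 100 along the
descending vulnerability ranking (stride adapts to the population size;
with 249 neurons an exact 20-neuron overlap between 7 groups of 100 is
arithmetically impossible, so the stride is chosen to span the ranking) and
regresses maximal accuracy on group mean score.

## Ring model

N = 256 units (128 in tests and scans; spacing-weighted sums make the
results insensitive to N, checked at 128 vs 256) tile [−π, π) with
π-periodic (doubled-angle) von Mises interactions. Integration is
exponential Euler with dt = 0.5 ms (dt ≤ τ/10 enforced; halving dt moves
steady rates by < 0.1%), t_max = 300 ms, steady state = mean over the last
50 ms. The constants τ = 10.8 ms, α = 10.6 Hz/mV, J_ff = 9.57,
J_exc = 1.71, J_inh = 2.0178 follow the model family's published fit to
cortical recordings; their printed units are internally inconsistent, and
they are composed here exactly as the defining equations read, with the
recurrent drive `Σ C_tot(Δ)·R(t)·Δθ`.

Under this normalization the linearized loop gain of the first angular
harmonic, α(J_exc I₁/I₀(κ_exc) − J_inh I₁/I₀(κ_inh)), exceeds one when
excitation is much more concentrated than inhibition; those configurations
diverge, are flagged unstable, and appear as missing cells in scans. The
near-instability band just above the identity line is slow (delay to half
maximum of order 100 ms) and transitions early in variance — the
vulnerable-like regime — while balanced near-identity kernels are fast and
keep low circular variance to higher input variance. The scan tests assert
these contrasts as median rank comparisons between the two stable regions.

Model VTFs exploit ring translation symmetry: one centered stimulus per
variance level (all levels integrated in a single batched run), with the
steady population profile read as the tuning curve of the center unit at
32 (tests: 16) orientations tiling ±75°, snapped to unit preferences and
always including the peak orientation — at near-zero variance the
feedforward profile is narrower than the unit spacing, so an off-grid
sample set would see only tails. Circular variance on the ±75° span cannot
reach 1 even for a flat curve (the resultant of a partial span does not
cancel); untuned configurations are therefore compared to that flat-curve
bound. The feedforward mode zeroes both recurrent gains and convolves the
input with a normalized von Mises receptive field on the ring, reported by
its half-width at half-height `0.5·arccos((log½ + κ)/κ)`.

## Problem sizes

The default study scale for simulation-based checks is 60 synthetic neurons
on the full 2880-trial grid, 20 label shuffles per decoding chance control,
a 10 × 10 connectivity subgrid at 8 variance × 16 orientation resolution,
and dense 0.1°-grid Naka–Rushton self-consistency checks; these sizes are
the package's reproducibility baseline and scale up by argument.

## Known limitations

- The generator's archetype distributions are directional emulations, not
  fits to any recorded population; absolute medians of recovered parameters
  are not comparable to published population medians.
- Balanced accuracy on shuffled labels is slightly conservative (below
  1/K) in small held-out splits; chance controls test agreement within
  Monte-Carlo error, not exact equality.
- The ring model's unstable region is a consequence of the printed gain
  constants under spacing-weighted sums; alternative normalizations trade
  the unstable region against different VTF magnitudes, and only rank-order
  regional contrasts are asserted.
- Eq-style VTF exponents above log n ≈ 7 are unidentifiable at any
  practical variance sampling; fits report the bracketing transition
  faithfully but the exponent only up to "steep".
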