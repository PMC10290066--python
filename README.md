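# vartune

Tools for studying how the **orientation variance** of a visual stimulus
reshapes single-neuron tuning and population codes in primary visual cortex
(V1), and for explaining the observed response diversity with a recurrent
ring network.

Natural scenes rarely contain a single clean orientation: local image
patches hold a *distribution* of orientations with some mean θ and spread
B<sub>θ</sub>. V1 neurons respond very differently as that spread grows —
some lose their orientation tuning quickly (*vulnerable* cells), others keep
it (*resilient* cells) — and the two groups play different roles in the
population code. `vartune` implements the complete analysis chain for this
question:

1. **Stimuli** (`vartune.stimuli`): band-pass filtered white-noise textures
   ("Motion Clouds") whose Fourier orientation envelope
   `O(θ_f) = exp(cos(2(θ_f − θ)) / 4B_θ²)` controls mean orientation and
   variance; the experimental grid of 12 θ × 8 B<sub>θ</sub> × 2 drift
   directions × 15 trials.
2. **Synthetic recordings** (`vartune.synthetic`): ground-truth model neurons
   of both archetypes and inhomogeneous-Poisson spike trains for the full
   trial table, so every downstream stage is testable without any recording
   data.
3. **Single-neuron analysis** (`vartune.tuning`): tuning curves in the 300 ms
   window maximizing spike-count variance, von Mises fits
   `f(θ) = R₀ + (R_max − R₀) e^{κ(cos 2(θ−θ_pref) − 1)}`, circular variance
   `CV = 1 − |Σ_k R(θ_k) e^{2iθ_k} / Σ_k R(θ_k)|`, Naka–Rushton
   variance-tuning functions (VTFs)
   `f(B_θ) = f₀ + f_max B_θⁿ/(B_θⁿ + B_θ50ⁿ)`, Wilcoxon tuning significance
   (B<sub>θmax</sub>), direction selectivity, and response-dynamics features.
4. **Archetype clustering** (`vartune.clustering`): PCA + K-means on ten
   response features, plus a continuous vulnerability score in [0, 1]
   weighted by principal-component loadings.
5. **Population decoding** (`vartune.decoding`): sliding-window (100 ms,
   10 ms steps, −200…400 ms) multinomial logistic decoders
   `P(y=k|X) = e^{⟨β_k,X⟩} / Σ_k' e^{⟨β_k',X⟩}` for orientation (K=12, per
   variance level), variance (K=8) and the joint code (K=96); population
   tuning curves, marginalization over variance, sigmoid time-course fits,
   group comparisons and score-sorted decoding.
6. **Ring model** (`vartune.ringmodel`): rate units tiling orientation space
   with `τ dV/dt + V = V_ff + V_exc − V_inh`, `R = α·max(V,0)`, a von Mises
   feedforward drive whose concentration κ_ff is set from B<sub>θ</sub>, and
   a Mexican-hat recurrent kernel (difference of excitatory/inhibitory von
   Mises profiles, κ_exc vs κ_inh); feedforward-only mode with receptive-field
   convolution, VTF extraction, and the 2-D κ_exc × κ_inh connectivity scan
   (200 × 200 = 40,000 configurations at full resolution).

## Worked example

```python
import numpy as np
from vartune import synthetic, tuning, clustering
from sklearn.metrics import adjusted_rand_score

pop = synthetic.sample_population(60, seed=1)      # 2 archetypes
data = synthetic.simulate_trials(pop, seed=2)      # 2880 trials/neuron
summaries, table = tuning.summarize_population(data)

features = clustering.assemble_features(table)
model = clustering.cluster(features, seed=0)
scores = clustering.vulnerability_score(features, model=model)

truth = np.array([n.archetype for n in pop])
print("ARI vs ground truth:",
      round(adjusted_rand_score(truth, model.labels), 3))
print("median b_theta50:",
      table.groupby(model.labels)["b_theta50"].median().round(1).to_dict())
print("mean vulnerability score:",
      {a: round(float(scores[truth == a].mean()), 2)
       for a in ("resilient", "vulnerable")})
```

Output:

```
ARI vs ground truth: 1.0
median b_theta50: {'resilient': 31.0, 'vulnerable': 11.7}
mean vulnerability score: {'resilient': 0.19, 'vulnerable': 0.74}
```

The clustering recovers the two simulated archetypes exactly: the resilient
cluster keeps tuning to much higher input variance (its VTF changepoint
B<sub>θ50</sub> sits near 31° versus 12°), and the continuous score places
the groups at opposite ends of the resilience axis.

A command-line entry point runs the same stages end to end:

```bash
vartune --seed 1 --outdir run all          # simulate → tuning → cluster → decode
vartune ringscan --steps 10                # coarse connectivity scan
```

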