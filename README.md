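# motorexplore

Quantify **exploration during motor learning** from joint-angle recordings of
a cyclical skill (the motivating case is novice breaststroke swimmers
practicing over many sessions at two speed conditions).

Motor learning is a search through a space of coordination patterns.  Some
learners search blindly, some converge gradually toward a target pattern,
some anchor on intermediate patterns before moving on.  `motorexplore`
implements a pipeline that makes this search measurable:

1. **Kinematics** — low-pass filter elbow/knee angle series (8 Hz Fourier
   filter), partition each trial into movement cycles at successive maximal
   knee flexions (first and last cycle dropped), and express each cycle's
   arm–leg coordination as the continuous relative phase
   `crp(t) = wrap(φ_elbow − φ_knee)` on a 100-point grid (0° = in-phase,
   ±180° = anti-phase).
2. **Coordination profiling** — pool all cycles and cluster them with a
   Fisher-EM style discriminative Gaussian mixture; the number of patterns
   `K` is the first value of the plateau of the BIC curve (the "elbow").
3. **Drifting Markov models (DMM)** — each learner's chronological pattern
   sequence `x_0..x_n` is modelled by an order-1 chain whose transition
   matrix drifts along the sequence as a degree-`d` polynomial between
   `d+1` row-stochastic support matrices:
   `Π_{t/n} = Σ_i P_i · L_i(t/n)` with `L_i` the Lagrange basis on `{i/d}`.
4. **Quantity of exploration** — per pattern `k`, the average distance (in
   %) between the degree-1 (linear drift) and degree-3 (flexible drift)
   models of the same sequence:
   `Q_k = 100/(n+1) · Σ_t |p_t^{(3)}(k) − p_t^{(1)}(k)|`,
   where `p_t` are the models' simulated probabilities of appearance.  A
   large `Q_k` means the pattern was anchored for a while and later
   abandoned — exploration; `Q_k ≈ 0` means linear appearance/disappearance.
5. **Learning curves** — per-session mean stroke frequency fitted by
   `f(t) = a·exp(−b·t) + c` (nonlinear least squares); `b` is the learning
   rate.
6. **Statistics** — paired t, mean-centered Levene, fully within-subject
   two-way ANOVA with partial η² and Greenhouse–Geisser/Huynh–Feldt
   sphericity handling, Bonferroni post hocs, Pearson/Spearman, Cohen's d.

A seeded synthetic-cohort generator (`motorexplore.synthetic`) emulates the
study protocol — learners × 2 speed conditions × 16 sessions × 5 trials ×
3–17 cycles per trial — from known strategy presets (`blind`, `linear`,
`anchored_local`, `hybrid_nonlocal`), so every stage can be tested against
ground truth.

## Worked example

Published per-participant learning rates (bundled in
`motorexplore.datasets`) and their group statistics:

```python
import motorexplore as mx
from motorexplore.datasets import learning_rate_table, coordination_bic_curve

piv = learning_rate_table().pivot(index="participant", columns="speed",
                                  values="b")
low, high = piv["low"].to_numpy(), piv["high"].to_numpy()
print(mx.paired_t(low, high))
print(mx.levene_mean_centered([low, high]))
print(mx.sample_variance(low), mx.sample_variance(high))
print(mx.select_k(coordination_bic_curve()))
```

prints

```
paired t: stat = -1.3728, df = (6.0), p = 0.2189
Levene: stat = 6.0701, df = (1, 12), p = 0.02983
0.006437791568120001 0.030420833705952385
(11, False)
```

— the learning rates do not differ in mean between speed conditions
(t(6) = −1.373), but their variances do (F(1,12) = 6.070, p = 0.03): the
harder condition diversified how fast individuals learned.  The BIC plateau
rule applied to the published clustering BIC curve selects 11 coordination
patterns.

Quantifying exploration for a synthetic learner who anchors on
intermediate patterns:

```python
import numpy as np

supports = mx.make_strategy_supports("anchored_local", m=5, degree=3)
seq = mx.simulate_labels(supports, n=680, initial=1, seed=42)
d1 = mx.fit_dmm(seq, degree=1, m=5)
d3 = mx.fit_dmm(seq, degree=3, m=5)
Q = mx.exploration_quantity(d1, d3)      # per-pattern %, appearance mode
print(np.round(Q, 2))
```

prints

```
[ 8.2  11.36  0.79 12.63  8.03]
```

— the anchor patterns (2 and 4) carry the most exploration (11–13 %),
while pattern 3, which the drift passes through only linearly, carries
almost none.  The same learner modelled with a linear strategy yields a
maximum `Q` of about 1 %.

The full pipeline (synthetic input, or an angle CSV with columns
`learner,session,trial,speed,t_s,elbow_deg,knee_deg`):

```python
from motorexplore import PipelineConfig, run_pipeline

cfg = PipelineConfig(scenario=dict(n_learners=2, m=4,
                                   trials_per_session=2,
                                   cycles_per_session=[24] * 6),
                     k_min=2, k_max=8, seed=0, outdir="out")
report = run_pipeline(cfg)
print(report["k_star"])                  # selected number of patterns
```

A `motorexplore` command-line tool exposes the same stages
(`simulate`, `filter`, `segment`, `crp`, `cluster`, `dmm-fit`, `explore`,
`learncurve`, `stats`, `run`).

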