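# Methods

This note documents the models implemented in `motorexplore`, their
assumptions, the numerical choices behind them, and what the synthetic
data generator does and does not emulate.

## Kinematic processing

Input is a pair of joint-angle series (elbow, knee; degrees) per trial on a
uniform 100 Hz grid.  Processing per trial:

1. **Filtering.** A brick-wall Fourier low-pass at 8 Hz: transform, zero
   all bins above the cutoff, invert.  The filter is idempotent and exactly
   preserves the passband; its ringing on discontinuous signals is the
   usual price, acceptable for smooth movement data.
2. **Cycle segmentation.** Cycle boundaries are strictly interior local
   maxima of the knee angle (a sample strictly greater than both
   neighbours; plateau ties resolve to the earliest sample) separated by at
   least `min_period` (default 0.5 s, as cycles last on the order of
   1–2 s).  The first and last cycle of every trial are dropped —
   in a pool-swimming protocol they are contaminated by push-off and
   approach.  Each retained cycle is amplitude-normalized per cycle
   (min → 0, max → 1) and time-normalized to L = 100 points.  Per-cycle
   normalization was chosen over per-trial: it makes cycles comparable
   when overall amplitude drifts within a trial.
3. **Continuous relative phase.** Per-joint instantaneous phase comes from
   the Hilbert analytic signal of the mean-centered, max-abs-normalized
   series, computed on the *whole trial* and then sliced per cycle —
   computing it per cycle would put an edge artifact at every boundary.
   `crp = wrap(φ_elbow − φ_knee)` into (−180°, 180°], so 0° is in-phase
   and ±180° anti-phase; the sign convention (elbow minus knee) follows
   the field's reading of anti-phase as −180°.  Whether the original
   analyses used Hilbert phase or an angle/angular-velocity phase plane is
   not documented; the Hilbert convention is fixed here and stated.

## Coordination profiling (Fisher-EM)

Cycles are clustered in curve space.  Two preprocessing choices matter and
are deliberate:

* **Circular embedding.** CRP is an angle; a curve hovering near ±180°
  must not be torn apart by a Euclidean metric.  Each curve is embedded as
  `(cos crp, sin crp)` per grid point (200 coordinates).  On raw wrapped
  angles, clusters straddling the boundary are irrecoverable (adjusted
  Rand ≈ 0.4 on synthetic data vs 1.0 after embedding).
* **Span restriction.** Band-limited curves are numerically rank-deficient
  (an 8 Hz-filtered 1 s cycle has ≈ 20 degrees of freedom, not 100), and
  near-null principal directions make a Gaussian model with spherical
  complement noise degenerate (the noise estimate collapses toward zero
  and the likelihood diverges with the latent dimension).  By default the
  embedded curves are projected — without rescaling — onto the principal
  directions whose eigenvalue exceeds 1 % of the leading one.  The 1 %
  level is coarse by design: it removes the numerically empty directions
  of filtered movement data.  For data with genuine white noise (e.g.
  directly simulated template curves) the restriction is unnecessary;
  pass `span_tol=None`.

The cluster model is a discriminative Gaussian mixture of the Fisher-EM
family: an orthonormal latent subspace `U` (dimension `d = K − 1`, capped
at the ambient dimension minus one), full per-component covariance inside
the subspace, one shared spherical noise variance β outside, component
means constrained to the subspace.  The EM iteration alternates:

* **E-step**: Gaussian posteriors (log-domain, Cholesky-based).
* **F-step**: update `U`.  The subspace is built from the *exact span of
  the current class means*, completed up to `d` dimensions with the top
  generalized eigenvectors of `(S_B, S_W)` (the Fisher criterion).
  Containing the mean span exactly is essential: with the plain
  eigenvector solution, sampling tilt leaks a fraction of the (large)
  between-cluster variance into the spherical complement, inflating β and
  collapsing the likelihood — on iid Gaussian clusters this error moved
  the fitted log-likelihood ~10⁵ nats below the true model's.
* **M-step**: weights, latent means, latent covariances (ridge 1e-6
  relative), β from the mean squared orthogonal residual.

Initialization is seeded k-means; `n_init` restarts (default 10) with the
best log-likelihood retained.  Fisher-EM does not guarantee monotone
likelihood; the implementation records the likelihood path, stops at the
first decrease and keeps the best iterate, so the reported path is
non-decreasing.  Convergence: relative log-likelihood change below 1e-8 or
200 iterations.

**Model selection.** `BIC = 2·LL − npar·log n` (larger is better), with
`npar` counting weights (K−1), the Stiefel dimension of the subspace
(`dp − d(d+1)/2`), latent means (Kd), latent covariances (Kd(d+1)/2) and β
(1).  The number of patterns is the *first value of the plateau*: the
smallest K whose successor has a lower BIC.  If the BIC rises throughout
the scanned range, the largest K is returned with a warning flag.
K = 1 is fitted as a single component on the first principal direction.

**Canonical ordering.** The mixture's component order depends on the
random initialization.  Labels are therefore canonicalized: components are
renumbered 1..K by ascending circular mean of their profile's mean CRP
curve (profile means are pointwise circular means, again to respect the
wrap).  A plain Gaussian-mixture-on-PCA fallback (`method="gmm_pca"`) is
available behind the same interface.

## Drifting Markov models

A chronological pattern sequence `x_0..x_n` on the alphabet `{1..m}` (the
global cluster set, so models are comparable across learners even when
some patterns are never visited) is modelled by an order-1 chain whose
transition matrix at relative position `s = t/n` is the Lagrange
interpolation of `d+1` support matrices at the equispaced nodes `i/d`:

    Π_s = Σ_i P_i · L_i(s),   each P_i row-stochastic.

* **Degree 0** is the classical homogeneous chain; its fit is exactly the
  transition-count MLE (rows with no observations fall back to uniform).
* **Degree ≥ 1** is estimated by penalized maximum likelihood over the
  support matrices: rows are parameterized by softmax logits (which keeps
  them in the simplex), and L-BFGS maximizes
  `Σ_t log Π_{t/n}(x_{t−1}, x_t)` minus a quadratic penalty (weight 1e5)
  on any interpolated entry outside [0, 1] on the data grid — for degree
  ≥ 2 the Lagrange basis has negative lobes, so interpolated entries can
  exit the simplex between nodes.  Evaluation (`transition_at`,
  likelihoods, simulation) always clips to [0, 1] and renormalizes rows.
* **Initialization and nesting.** The optimizer starts from the Laplace-
  smoothed (α = 0.5) homogeneous estimate replicated across supports; for
  degree ≥ 2 a second start embeds the fitted degree-1 model (interpolated
  at the higher-degree nodes — exact, since low-degree polynomials are
  reproduced).  The best candidate by evaluated log-likelihood is kept,
  which guarantees the nested ordering LL(d=3) ≥ LL(d=1) up to numerics.
* Evaluated probabilities are floored at 1e-12 so unvisited patterns keep
  a finite likelihood; constructing a model with `floor=0` instead reports
  −∞ with a diagnostic list of the offending transitions.
* A row-wise weighted least-squares estimator (`method="ls"`) is provided
  as a cheap cross-check; maximum likelihood is the default because AIC
  and BIC are computed from the same objective
  (`npar = (d+1)·m·(m−1)`).

Identifiability caveat: support matrices are well determined only where
the chain actually occupies the corresponding rows near the corresponding
positions.  Strongly concentrated drift structures leave rarely-occupied
rows pinned near their initialization; parameter-recovery checks therefore
use well-occupied ground truths.

## Quantity of exploration

Two readings of "distance between the degree-1 and degree-3 models" are
implemented; both are in percent and symmetric in the two models.

* **appearance** (default): propagate each model's pattern-appearance
  probabilities `p_t = p_{t−1} Π_{t/n}` from the same initial distribution
  (default: the indicator of the first observed label) and average the
  absolute difference per pattern,
  `Q_k = 100/(n+1) Σ_t |p_t^{(3)}(k) − p_t^{(1)}(k)|`.  This follows the
  definition of the exploration quantity as the distance between the two
  simulated appearance-probability trajectories.
* **column**: root-mean-square difference of the transition probabilities
  *toward* pattern k (its matrix column), averaged along the sequence —
  the alternative reading of "probabilities of transiting towards" a
  pattern.

The exact normalization that produced published percentage values is not
documented; both candidates are exposed and the default is stated.
Summaries report the number of distinct visited patterns and the sample
standard deviation (n−1) of Q across all m patterns; never-visited
patterns keep their computed Q and are flagged rather than zeroed.

## Learning curves

Per-session mean stroke frequency is fitted by `f(t) = a·exp(−b·t) + c`
with `t` the 1-based session index (so `a + c` is the pre-practice level).
Nonlinear least squares (trust-region, bounds `b ∈ [0, 10]`,
`c ∈ [0, max f]`) with starting values from a log-linear regression of
`f − min(f) + ε`, plus four restarts with the initial rate jittered ±50 %
to escape the flat local minimum near `b = 0`.  Constant series return the
degenerate flat fit (`a = b = 0`) flagged as such.  `r² = 1 − SS_res/SS_tot`;
`RMSE = √(SS_res/n)` with the session count in the denominator (the
common definition; the alternative `n − p` is not used).

## Statistics

All tests return a uniform result object (statistic, dfs, two-sided p,
effect size, CI where applicable).

* Paired t, unbiased variances, Pearson/Spearman correlations, Cohen's d
  (paired: mean/SD of differences; unpaired: pooled SD).
* Levene's test with **mean**-centering by default (the original
  statistic); median-centering (Brown–Forsythe) behind a flag.
* The two-way fully within-subject ANOVA decomposes the subject × A × B
  cube with each effect tested against its own subject-interaction error;
  partial η² = SS_effect/(SS_effect + SS_error).  For effects with more
  than one numerator df, Greenhouse–Geisser and Huynh–Feldt epsilons are
  computed from the orthonormally contrasted per-subject covariance; the
  p value uses GG-corrected dfs when ε_GG < 0.75 and HF otherwise;
  two-level effects are exempt.  The decomposition is verified against a
  brute-force cell-mean oracle and against `pingouin` in the tests.
* Bonferroni post hocs are per-pair paired t tests on per-subject level
  means, p multiplied by the number of pairs (capped at 1), with
  per-pair t-based 95 % CIs (a pooled-error construction would be the
  alternative; per-pair is stated and used).
* Shapiro–Wilk screening is reported but never switches tests
  automatically.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested.

* **Protocol shape**: learners × 2 speed conditions × 16 sessions ×
  5 trials, 3–17 cycles per trial (session totals 15–85 cycles).  Reduced
  problem sizes used in the test suite (2 learners, 6 sessions, 2 trials
  per session, m = 4 patterns) are the package's own choice of a compact
  but structurally complete configuration.
* **Strategies** (the classical search-strategy taxonomy) are encoded as
  drifting-support presets: `blind` = uniform rows everywhere; `linear` =
  linear drift from a start-concentrated to a target-concentrated matrix
  (anchor mass 0.85); `anchored_local` = interior supports concentrated on
  successive adjacent anchors; `hybrid_nonlocal` = interior anchors jump
  half the alphabet (requires m ≥ 4).
* **Templates**: each pattern's CRP template starts and ends the cycle in
  anti-phase (−180°, the coordination at maximal knee flexion) and makes a
  smooth `sin²` excursion toward in-phase, with depths evenly spaced in
  30–90°; the deepest is the most expert-like shape (anti-phase → toward
  in-phase → anti-phase).  Sharing the boundary value keeps the
  synthesized elbow phase continuous across cycle boundaries (no bleed of
  one cycle's coordination into its neighbours through the filter and the
  analytic signal), and capping the depth keeps the elbow phase monotone
  so the Hilbert phase is well defined.  An earlier family of constant
  levels plus a −180°→0°→−180° sweep was abandoned: constant levels at the
  wrap boundary and discontinuous template jumps produced heavy
  context-dependent artifacts.
* **Trace synthesis**: knee = fixed-period cosine with maxima at cycle
  boundaries; elbow = the same cosine phase-shifted by the current cycle's
  template (interpolated within the cycle) plus i.i.d. Gaussian
  phase-offset jitter (default SD 5°, representing measurement/execution
  jitter — the 8 Hz chain smooths it to roughly 2° at cycle scale;
  pattern-scale variability comes from the label process, not the
  jitter).  Half a period of margin is added at both ends so every
  boundary is an interior knee maximum; the cohort generator additionally
  pads each trial with two sacrificial cycles so that the downstream
  edge-drop recovers exactly the true label sequence.
* **Performance**: per-session stroke frequency follows
  `a·exp(−b·t) + c` plus Gaussian noise (defaults: low speed
  a = 0.35 Hz, b = 0.20/session, c = 0.50 Hz; high speed a = 0.30,
  b = 0.28, c = 0.65; σ = 0.02 Hz — rates within the published range,
  asymptotes giving realistic breaststroke cycle durations of 1–2 s).
  The session's cycle period is the reciprocal of its frequency, so
  session means recovered downstream match the generated curve.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: inertial-sensor noise and sensor-fusion error;
biomechanically realistic multi-joint swimming kinematics; within-cycle
tempo variation (cycles are exactly periodic within a session);
continuous between-pattern morphing (patterns are discrete templates);
drop-out, missed cycles, or unequal trial validity.  Real CRP clusters
are certainly less Gaussian and less separated than the synthetic ones,
so recovery results here are a correctness check of the machinery, not a
claim about achievable accuracy on recorded data.

## Problem sizes and determinism

The test suite and the acceptance checks use: drift-recovery at
m = 5, d = 3, n = 10 000; homogeneous-chain exploration at n = 10 000;
strategy comparisons at n = 680 (a realistic per-learner cycle count);
learning-curve calibration over 200 noisy replicates; and an end-to-end
synthetic run with 4 true patterns scanning K = 2..8.  Every stochastic
step is seeded; pipelines rerun byte-identically for a fixed config and
seed.

## Known limitations

* The drifting-model estimator treats the sequence length as fixed and
  conditions on the first label; no stationarity or ergodicity is assumed,
  but confidence statements for the support matrices are not provided.
* BIC-based selection of the cluster count inherits the Gaussian
  assumption; strongly non-Gaussian within-cluster structure (e.g. heavy
  measurement artifacts) biases it upward.  The plateau rule mitigates
  but does not remove this.
* The exploration quantity depends on the initial distribution through
  the appearance simulation; the default (indicator of the first observed
  label) matches the per-learner analyses but other choices are possible
  and exposed.
* Sphericity corrections use the single-group Huynh–Feldt formula; with
  very few subjects the epsilon estimates are themselves noisy.
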