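# Methods

## The generative model

A subject's performance in a 2AFC contrast task is modelled through a
per-trial log10 contrast threshold `xi(t)` that is the sum of four latent
component processes:

- **general learning** `b − γ·log10(t)` over the global trial number `t`
  (cumulative across pre-training and all sessions, 1-based);
- **between-session forgetting**, a step `δ_s` added throughout session
  `s ≥ 2` (no step in session 1; steps do not accumulate across sessions —
  each `δ_s` offsets its own session relative to the general-learning
  curve);
- **within-session rapid relearning**, an elbow `max(−d_s, −τ·t′)` in the
  0-based within-session index `t′`: a linear recovery at rate `τ` per
  trial that saturates at `−d_s`;
- **within-session adaptation**, a ramp `φ·t′` that resets at each session
  start.

All components are in log10 threshold units. The parameter vector `θ`
stores the log10 of each component magnitude, which enforces positivity and
makes the Gaussian population assumptions of the hierarchical models
reasonable. The within-session index convention (`t′ = 0` at each
session's first trial, so relearning and adaptation contribute nothing
there) and the non-cumulative reading of the forgetting steps are modelling
choices; the alternatives (1-based `t′`, accumulating steps) only reindex
or reparameterise the same family.

Model orders: `K = 14` frees `δ_s` and `d_s` per session (sessions 2–6,
six-session designs only), `K = 6` shares one `δ` and one `d` across
sessions, `K = 2` keeps general learning alone. The `K = 14` and `K = 6`
families nest exactly (equal per-session values), and `K = 6` limits to
`K = 2` as the extra magnitudes go to zero; both nestings are property
tests.

Performance on a trial is linked to threshold through a Weibull
psychometric function with guessing rate `g = 0.5`, lapse rate
`λ = 0.04`, slope `β ∈ [1, 4]`, and a threshold criterion anchored at the
accuracy of an ideal observer at sensitivity d′ = 1.5,
`p_ref = Φ(1.5/√2) ≈ 0.856`:

```
p(correct | c) = g·λ + (1−λ)·( g + (1−g)·(1 − exp(−(c/ϑ)^β)) )
log10 ϑ        = ξ − (1/β)·log10( ln((1−g)/(1−p_ref)) )
```

so the curve passes through `p_ref` exactly at `c = 10^ξ`, with floor
`g = 0.5` and ceiling `g·λ + (1−λ) = 0.98`. The lapse factor multiplies
the whole lapse-free curve by `(1−λ)`; the alternative in which the outer
factor is `(1−g)` would cap accuracy at 52% and is incompatible with an
85%-accuracy staircase, so it is not used. The inner logarithm is natural,
the outer base-10. Per-trial probabilities are clipped to
`[1e−9, 1−1e−9]` before logs so the likelihood stays finite under extreme
proposals; `θ` itself is unbounded when used generatively — the Table of
prior bounds below constrains priors, not the model.

Trials are conditionally independent Bernoulli given `θ`, `β` and the
contrast sequence, so the dataset log likelihood is the sum of per-trial
terms; an independent scalar-math reimplementation serves as the oracle in
the test suite (agreement to 1e−10).

## Synthetic data

The generator emulates a six-group, sixty-subject staircase-controlled
training study: groups of (12, 12, 6, 6, 12, 12) subjects under
low (65%), low, mixed, mixed, high (85%), high accuracy staircases, with
the feedback flag alternating off/on across groups. Feedback is metadata
only: the generative model has no feedback term, so simulated groups differ
only through their true parameters — by default the first (low-accuracy,
no-feedback) group has a ~40% lower general-learning rate, mirroring the
kind of group difference such designs are used to detect. Each subject
runs 6 sessions × 320 trials, preceded by a pre-training block of 60–80
trials (drawn per subject) that belongs to session 1 and counts toward the
global trial number.

Parameters follow a three-level Gaussian hierarchy: subject means
`ρ_i ~ MVN(μ + group shift, Σ)` and test-level vectors
`θ_ij ~ MVN(ρ_i, ϕ)`. Default population means are chosen once so that
every component leaves a visible signature on the curve, as in the training
data the design emulates: γ ≈ 0.045, initial threshold `10^−0.2`,
forgetting steps ≈ 0.08 log10 units, relearning amplitude ≈ 0.1 recovered
within ~30 trials (τ ≈ 3·10⁻³/trial), adaptation ≈ 3·10⁻⁴/trial
(≈ 0.1 log10 units over a 320-trial session). Default dispersions are
between-subject SD 0.15 and within-subject SD 0.05 per log10 dimension.

The staircase is Kesten-style accelerated stochastic approximation on
log10 contrast `x`: `x ← x − (s/n)(r − p_target)` on the first two trials
and `x ← x − (s/(2+m))(r − p_target)` afterwards, with `m` the number of
response reversals, initial step `s = 0.3` log10 units, initial contrast
`10^−0.5`, and `x` clipped so contrast ≤ 1. Convergence of the realized
accuracy to the design target (±2 percentage points against a stationary
observer) is the tested contract; any rule with that Robbins–Monro property
would serve. Mixed-accuracy subjects run two staircases in strict
alternation, each updating only on its own trials. Staircase state carries
across sessions by default (configurable reset). Pre-training uses the
same staircase as training.

What the generator does *not* emulate: feedback effects on learning
dynamics, response times, attention lapses beyond the constant lapse rate,
session-to-session variability in the psychometric slope, and any
non-staircase adaptive procedure for pre-training. Passing tests therefore
show the inference machinery is correct and well calibrated *for data of
this structure*, not that the functional form is right for any particular
real dataset.

## Inference procedures

- **BIP** fits each subject/test independently: independent uniform priors
  `U(θ_k,min, θ_k,max)` per dimension and `β` fixed at 2 (a single
  subject's staircase data, concentrated near one or two accuracy levels,
  identifies `β` poorly). Bounds default to: γ and −b in `[10⁻³,
  10⁻⁰·⁵]`, φ in `[10⁻⁶, 10⁻³]`, δ in `[10⁻³, 10⁻¹]`, τ in `[10⁻⁴,
  10⁻²]`, d in `[10⁻³, 10⁻⁰·⁶]` (log10 bounds −3…−0.5, −6…−3, −3…−1,
  −4…−2, −3…−0.6).
- **HBMv** is a three-level hierarchy with per-dimension variances:
  `ρ_ik ~ N(μ_k, σ_k)`, `θ_ijk ~ N(ρ_ik, ε_k)`, priors `μ_k ~ U(bounds)`,
  `1/σ_k² ~ Gamma(15, 1)`, `1/ε_k² ~ Gamma(20, 1)` (shape, rate), and a
  single `β ~ U(1, 4)` shared by all subjects.
- **HBMc** replaces the diagonal dispersions with full covariances:
  `ρ_i ~ MVN(μ, Σ)`, `θ_ij ~ MVN(ρ_i, ϕ)`, with Wishart priors on the
  precisions `Ω = Σ⁻¹` and `Λ = ϕ⁻¹` with `v = K+1` degrees of freedom and
  scale `S⁻¹/v`, so the prior mean of the precision equals the inverse of
  the anchoring covariance `S`. `S` is taken from a previous HBMv run
  (between-subject covariance of subject-level posterior means, and the
  diagonal of the posterior-mean `ε²` for the within-subject scale — see
  `wishart_scales_from_hbmv`); with no HBMv run available the scales fall
  back to the identity.

The Gaussian levels are *not* truncated at the prior bounds: any real `θ`
is generatively valid; bounds constrain only `μ`'s uniform prior. The
test-level conditional is Gaussian with the `ε`/`ϕ` dispersion even when
each subject runs the experiment once (`J = 1`); the data then inform the
subject/test decomposition only through the hierarchy.

## The sampler

All three procedures run on a bespoke Metropolis-within-Gibbs sampler
(no general-purpose MCMC backend is a dependency):

- Conjugate Gibbs updates for everything Gaussian: `(μ, ρ)` are drawn as a
  block — `μ` from its ρ-collapsed conditional (subject means integrate to
  `N(μ, σ² + ε²/J)` per dimension, or `MVN(μ, Σ + ϕ/J)`; the box
  truncation on `μ` is handled by a componentwise truncated-normal Gibbs
  scan), then `ρ` conjugate given the fresh `μ`. Collapsing removes the
  μ–ρ random-walk bottleneck that otherwise dominates the autocorrelation
  time. Precisions update by conjugate Gamma/Wishart draws.
- The likelihood-coupled parameters (`θ` per subject/test, shared `β`) use
  componentwise random-walk Metropolis with proposal scales adapted toward
  44% acceptance during warm-up only, plus two extra moves per subject and
  sweep: a full-vector proposal along the adapted posterior covariance
  (handles the strong γ–b ridge of the log-scale parameterisation) and a
  single-coordinate independence proposal from the prior conditional,
  whose acceptance ratio reduces to the likelihood ratio (jumps between
  the "component present / component absent" modes that log-magnitude
  parameters create). All adaptation freezes before the first kept draw.
- With the likelihood disabled every update is an exact conditional draw,
  so the prior-mode sampler is a plain Gibbs sampler on the joint prior;
  the test suite verifies its marginals against direct forward sampling of
  the hierarchy (two-sample KS).

Chains are initialised with hyperparameters from their priors (dispersed
across chains) but `θ` from a data-driven least-squares line of log10
contrast on log10 trial — the staircase keeps contrast near threshold, so
the line's slope and intercept give serviceable starts for γ and b.
Initialisation affects only convergence speed, never the stationary
distribution; random Wishart starts with `v = K+1` degrees of freedom were
found to strand early sweeps at near-singular covariances and are avoided
(the precision matrices start at their prior means).

The reference schedule is 3 chains × 5,000 kept samples with thinning 10,
after 5,000 adaptation and 5,000 burn-in sweeps (500,000 burn-in for the
covariance model); tests and examples use reduced schedules (typically 2–3
chains, a few hundred kept draws, warm-up 500–2,500 sweeps) with problem
sizes stated in each test. Convergence is summarised per scalar parameter
by the ratio of pooled-across-chain variance to mean within-chain
variance, with threshold 1.05; non-convergence flags the returned
posterior rather than raising.

## Post-inference summaries

- **BPIC** `= D̄ + 2·p_D`, with `D̄` the posterior-mean deviance and
  `p_D = D̄ − D(θ̂)`. The plug-in `θ̂` is the highest-likelihood kept draw
  rather than the coordinate-wise posterior mean: on the log10 scale,
  weakly constrained magnitudes make the posterior banana-shaped, the mean
  falls off the likelihood ridge, and a mean plug-in can produce a
  *negative* penalty. The modal-draw plug-in keeps `p_D ≥ 0` and reduces
  to `p_D = 0` at a point-mass posterior. Model orderings, not absolute
  values, are the supported use.
- **Learning-curve posteriors** push every kept `θ` draw through the
  threshold curve; the summary is the pointwise mean and the half width of
  the central 68.2% interval (15.9th–84.1st percentiles), verified against
  order statistics to 1e−12.
- **Group posteriors** are built by resampling: each of 15,000 group
  samples is the across-subject mean of one per-subject posterior draw,
  drawn independently per subject and repetition.
- **MANOVA** (Pillai's trace, via statsmodels) runs on subject-level
  posterior-mean vectors with group labels — with G groups and K
  dimensions it needs at least `G + K` subjects, and raises a
  rank-deficiency error otherwise. **LDA** (scikit-learn, equal priors)
  scores pairwise group separability on 90/10 splits of the group
  posterior clouds, repeated 100 times; each group's samples are split
  independently. A singular within-class covariance falls back to a
  shrinkage-regularised solver.
- **Partial-data prediction** refits the covariance model after truncating
  one subject to 0, 1 or 2 sessions (other subjects keep full data; a
  subject with no data stays in the model and is driven purely by the
  hierarchy), then reads that subject's curve posterior over the full
  session structure. Reported: Pearson correlation between predicted and
  full-data mean curves, and the ratio of average HWCIs. Anchoring the
  Wishart scales on a variance-model run is essential here: with the
  identity cold start the heavy inverse-Wishart tail lets a no-data
  subject's decoded curve explode (average HWCIs of hundreds of log10
  units at small subject counts).

## Numerical and design notes

- Weibull evaluation works in log space (`(c/ϑ)^β = exp(β·ln10·(log10 c −
  log10 ϑ))`, capped at exp(700)) so extreme proposals cannot overflow.
- The staircase's contrast is clipped to (0, 1]; log10 contrast is floored
  at −10.
- Posterior storage is a labelled columnar CSV plus a JSON sidecar (model
  tag, subject/test pairs, convergence ratios, seed); trial tables are CSV
  with `%.17g` floats and round-trip parsing, so write→read is bit-exact.
- Group-sample pairing, the MANOVA statistic (Pillai), the LDA split
  construction (per-group independent splits) and the Pearson correlation
  metric for prediction are all places where several reasonable choices
  exist; the ones above are fixed and documented rather than configurable.

## Known limitations

- With a single staircase accuracy and a few hundred trials, `β`, and the
  (γ, b) pair are weakly identified; posteriors are honest about this
  (wide, curved), but summaries that plug in coordinate-wise means can be
  misleading — hence the modal-draw BPIC plug-in.
- At small numbers of subjects the Wishart posterior over `ϕ` is loose
  (its posterior mean carries a divisor of roughly the number of subjects
  when each runs one test), and the covariance model's curve intervals can
  exceed the variance model's, whose Gamma hyperpriors pin the dispersions
  regardless of sample size. The precision advantage of covariance pooling
  over per-dimension variances emerges only with of order 15+ subjects —
  more than the shipped reduced-scale ordering suite simulates, so that
  one comparison is expected to favour the variance model there. Both
  hierarchies beat the independent fits at all tested scales, and the
  goodness-of-fit (BPIC) ordering favours the covariance model as in the
  full-scale regime.
- The half-width summaries assume roughly unimodal curve posteriors;
  strongly bimodal component posteriors (component on/off) are summarised
  conservatively by wide intervals.
- Runtime: the samplers are pure NumPy; a full-scale run (60 subjects ×
  1,990 trials, reference schedule) is feasible but slow (hours). The
  shipped tests and examples use the reduced problem sizes stated inline.
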