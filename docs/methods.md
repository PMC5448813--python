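# Methods

## The belief-update model

Perceptual decisions about an ambiguous rotating Lissajous figure are
modelled on the discrete grid of stimulus "overlaps", the depth-symmetric
configurations at which transitions occur. The perceptual variable θ codes
rotation direction (0 clockwise, 1 counter-clockwise). Two Gaussian factors
form the joint prior at each overlap:

- **Stability prior** `N(μ_stability, 1/π_stability)` with mean equal to the
  previous perceptual decision. Immediately after a transition its precision
  is `π_init`; while the percept is stable the accumulated prediction error
  grows its variance (below).
- **Stereodisparity weight** `N(μ_stereo, 1/π_stereo)`. Ambiguous overlaps
  carry `μ_stereo = 0.5`; replay overlaps carry 0 or 1 according to the
  imposed disparity direction.

Their product gives `π_m = π_stability + π_stereo` and the precision-weighted
mean `μ_m`; when both precisions vanish, `μ_m = 0.5` by convention.

**Likelihood reduction.** The bimodal likelihood is modelled as two narrow,
equal-variance modes at θ = 0 and θ = 1. In the narrow-mode limit the
posterior weight of the counter-clockwise mode depends only on the joint
prior's density ratio at the modes, giving the closed form
`P(θ > 0.5) = logistic(π_m (μ_m − ½))`. The unit tests verify this closed
form against numeric normalisation of the explicit mixture posterior (mode
σ = 0.005, agreement < 1e-4). A corollary is that on ambiguous overlaps the
stereodisparity weight cancels exactly from the posterior, so `π_stereo` is
informed only by replay data.

**Response model.** `y_predicted = p^ζ / (p^ζ + (1−p)^ζ)` — the unit-square
sigmoid with inverse decision temperature ζ, the standard form for binary
responses in hierarchical-filter toolboxes. ζ defaults to 1 (identity),
the convention used for all headline fits.

**Prediction error and update.** `PE = |y − P(θ > 0.5)|` is the residual
posterior mass of the suppressed percept. If the decision differs from the
prior mean, the state resets to `(y, π_init)`; otherwise the PE accumulates
additively on the variance, `1/π ← 1/π + PE`. The additive, parameter-free
law is the simplest accumulation consistent with the model's three-parameter
table; with `π_init = 3.5` at 0.33 Hz it puts the mean dominance duration at
≈ 10.8 s (observed behavioural means are near 10 s), which we treat as its
validation anchor.

**Phase-duration structure.** Conditional on the percept surviving, the
within-phase dynamics under ambiguity are deterministic, so the phase-length
distribution is an exact survival product of per-overlap stay probabilities
along the all-stay PE path. `expected_mean_duration` evaluates this
semi-analytically and serves as an independent oracle for the stochastic
simulator (agreement within 10% is asserted in tests; observed agreement is
well inside 1%). Durations are reported on the overlap grid (multiples of
the ≈ 3.03 s overlap interval at 0.33 Hz), which is why the simulated median
(9.09 s = 3 overlaps) can sit one grid point from off-grid references.

## Session structure and synthetic cohort

Sessions follow the underlying experiment: three runs of eight
ambiguous→replay block pairs, 10 s fixation before the first block and after
every block, overlap frequency one of {0.24, 0.30, 0.40} Hz with block
durations {42.8, 40.90, 41} s paired in that order (the pairing is stated as
a set in the source; printed order is an assumption). Overlaps sit at whole
multiples of the overlap period after block onset; per-block overlap count is
`floor(duration × frequency)`.

Synthetic subjects are simulated from the model itself. Ambiguous blocks run
freely; each replay block's disparity track (`μ_stereo ∈ {0,1}` per overlap,
piecewise-constant at overlap resolution) copies the subject's own decisions
from the preceding ambiguous block, exactly as the experimental replay
mimicked the preceding ambiguous percept sequence. Cohort ground truth:
`π_init ~ LogNormal(log 3.5, 0.3²)` and `π_stereo ~ LogNormal(log 5, 0.3²)`
(centred on the scale the behavioural fits centre on, with realistic
between-subject spread), ζ fixed at 1; 20 subjects balanced over the three
frequencies. All randomness derives from a single master seed through
`numpy.random.SeedSequence` substreams.

The generator emulates the study design's structure, not every property of
real reports: there are no mixed percepts, reaction-time jitter, attentional
lapses or non-stationarity (missing reports can be injected with
`missing_prob`). Passing recovery tests therefore demonstrates internal
consistency of model, fitting and selection machinery at study scale — not
that real observers obey the model.

**Transition frequency** is summarised per overlap (a transition
probability), not per second, because transitions are only possible at
overlaps and the overlap frequency varies across subjects by design.

## Model inversion

Four behavioural variants switch the two factors on/off (1: neither, 2:
stability only, 3: stereodisparity only, 4: both); a disabled factor has its
precision fixed to zero, removing it exactly. Enabled precisions are
log-normal: `log π_init ~ N(log 3, 5)`, `log π_stereo ~ N(log 5, 5)`; ζ may
optionally be freed with `log ζ ~ N(0, 1)`.

The negative log joint sums Bernoulli log-probabilities of the observed
decisions at *scored* overlaps plus the log-priors, with predictions
obtained by deterministically filtering the observed decisions through the
model. Conventions: the state re-initialises at each block start on the
block's first reported percept, whose overlap is excluded from the
likelihood; missing/mixed reports carry the previous decision forward for
state propagation but are not scored.

Optimisation is multi-start quasi-Newton (BFGS) in log-parameter space
(default 8 starts: prior means plus prior draws clipped to ±2.5 prior SD;
gradient tolerance 1e-6). The log model evidence is the Laplace
approximation at the MAP, `−NLJ + d/2·log 2π − ½ log|H|`, with a central
finite-difference Hessian (step 1e-4); non-positive-definite Hessians are
clamped to the nearest positive-definite matrix and flagged. Runs are fitted
independently; per-subject evidence is the sum over runs and parameters are
summarised by their geometric mean (log-space arithmetic mean) across runs.
A 1-D grid-integration oracle bounds the Laplace error (< 0.5 nats) in tests.

## Random-effects model selection

Subjects are random effects over models with Dirichlet-distributed
population frequencies (flat prior, one count per model). The variational
fixed point `u_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))`, `α = α₀ + Σ_n u_n` iterates
to `max |Δα| < 1e-6` (≤ 500 iterations). Exceedance probabilities are
Monte-Carlo frequencies of each model having the largest sampled frequency
(default 10⁶ seeded Dirichlet draws; the K = 2 case is validated against the
Beta tail in closed form). The Bayes omnibus risk compares the
random-effects free energy with the equal-frequency null,
`BOR = 1/(1 + exp(F₁ − F₀))`, and protected exceedance probabilities are
`PXP_k = XP_k (1 − BOR) + BOR/K`. Note that with a flat prior the expected
frequency of even a unanimous winner is bounded by `(N+1)/(N+K)`.

## Rival models

Three canonical classes of bistability models are implemented for formal
comparison, in their standard published forms:

- **Oscillator** — two rate-coded populations with cross-inhibition (weight
  2.0), sigmoidal gain (slope 8, drive 1), self-adaptation (weight 1.2,
  time constant 3.5 s) and fast time constant 0.1 s, Euler-integrated at
  20 ms. Defaults produce deterministic alternations with ≈ 9.8 s half
  periods (duration CV ≈ 0).
- **Attractor** — an overdamped particle in the symmetric double well
  `dx = (h/τ)(x − x³)dt + σ dW` (defaults h = 1.2, σ = 0.6, τ = 1 s). The
  percept readout uses a ±0.5 hysteresis so barrier-top jitter does not
  fragment dwell times; dwell times are approximately exponential (CV ≈ 1)
  and grow with the barrier, the Kramers signature.
- **Intermediate** — the oscillator with additive noise on the activities,
  combining adaptation and stochastic switching (gamma-like durations with
  intermediate CV).

For fitting, each model's decision variable at the overlap times is scaled
by a free response gain and mapped through a logistic to a Bernoulli choice
probability at the same scored overlaps, and the same multi-start
BFGS + Laplace machinery produces evidences directly comparable with the
predictive-coding variants. Two numerical choices matter here. The
deterministic oscillator's initial phase is unidentifiable a priori and
makes the likelihood comb-like, so it is profiled out over a grid of
offsets inside the objective rather than exposed to the quasi-Newton
search; for the same reason fits over the adaptation time constant start
from a coarse-to-fine grid profile before BFGS polishing. Stochastic rivals
are integrated under common random numbers (a fixed simulation seed per
fit) so their objectives are deterministic.

## Model-based fMRI stage

Three GLMs operationalise competing accounts of transition-related BOLD:
*PE* (overlap sticks + transition sticks + |PE| parametric modulator on
overlaps), *Conventional* (overlap sticks + ambiguous-transition and
replay-transition sticks) and *Block* (overlap sticks + transition sticks +
ambiguous box-car modulator sampled at overlaps).

Events are laid on a fine grid of 16 bins per TR (TR = 2 s), convolved with
the canonical double-gamma HRF (response delay 6 s, undershoot delay 16 s,
dispersions 1 s, response:undershoot 6, 32 s support, unit-peak
normalisation so regressors keep modulator units) and sampled at scan
onsets. Parametric modulators are mean-centred within run before
convolution; they are *not* serially orthogonalised against the overlap
stick beyond that, so each model's evidence reflects its stated regressors.
Per-run constants are appended; drifts are handled by projecting a per-run
discrete-cosine basis (cutoff 128 s) out of both design and data at fit
time. Synthetic BOLD is a linear mixture plus white Gaussian noise (AR noise
is out of scope).

Voxel-wise evidence uses a conjugate Gaussian linear model: after filtering,
voxel series are standardised, task regressors are unit-normed, and with
`w ~ N(0, s² I)` (s = 1, identical across models) and unit noise the
marginal likelihood is `N(y; 0, I + s² XXᵀ)`, evaluated via the Woodbury
identity; a quadrature oracle on a two-regressor toy validates the closed
form. Group inference runs the random-effects selection per voxel and
reports exceedance maps; a thresholding utility reproduces the display
convention (exceedance > 0.99, clusters > 10 voxels).

**Synthetic generating conditions.** Voxel populations are generated from
each design with overlap sticks at 0.5, transition sticks at 1.0 and
modulators at 1.0, noise SD 1.0. Under the Conventional account the
transition response is ambiguity-specific: ambiguous transitions 2.0 versus
replay transitions 0.5. With *equal* condition betas the Conventional data
would lie exactly in the PE design's span and no comparison could identify
them; the asymmetry encodes that account's own hypothesis.

**Pre-transition ramp.** The epoch-averaged course of a noiseless voxel
carrying only the |PE| modulator is sampled with a 4 s hemodynamic delay at
the overlaps preceding ambiguous transitions whose look-back window stays
within one dominance phase; this isolates the prediction-error build-up
from the previous transition's reset and from transition-stick responses.

## Problem sizes and determinism

Headline statistics use the full-length 6×10⁵ s simulation (~55 000 phases,
about two seconds of compute). Recovery studies use the study-scale cohort
(20 subjects × 3 runs, all four variants, ~1 minute) and the fMRI stage uses
10 subjects × 300 voxels. Every stochastic routine takes an explicit seed
and derives substreams via `SeedSequence`; identical seeds reproduce results
bit-for-bit.

## Known limitations

- The two-mode likelihood reduction, the additive PE-on-variance law and the
  unit-square response sigmoid are the simplest forms consistent with the
  model's stated quantities; alternatives (e.g. gain-modulated updates)
  are not explored.
- Continuous-time perception between overlaps, mixed percepts and
  attentional control are out of scope, as are preprocessing of real scans,
  family-wise-error correction and anatomical labelling.
- Rival models are class representatives, not tuned replicas of any specific
  published parameterisation; only class-level behaviour (periodicity,
  exponentiality, intermediate variability) is claimed.
- The conjugate evidence model is a desk-scale analogue of first-level
  Bayesian GLM estimation, not a bit-match to any neuroimaging package.
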