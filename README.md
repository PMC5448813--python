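# bistablepc

Predictive-coding modelling of bistable perception: a Bayesian
belief-updating model of perceptual alternations, tools to invert it on
behavioural data, rival dynamical models for formal comparison, and
model-based fMRI design construction with voxel-wise Bayesian model
selection — all exercisable end-to-end on synthetic data.

## The scientific problem

When observers view an ambiguous stimulus such as a rotating Lissajous
figure, perception alternates spontaneously between the two depth
interpretations (clockwise vs counter-clockwise rotation), even though the
input never changes. What drives these endogenous transitions? This package
implements a predictive-coding account: the current percept installs a
*stability prior* over the perceptual variable θ (coded 0/1 for the two
rotation directions), and the residual posterior evidence for the suppressed
interpretation acts as a *prediction error* that progressively erodes that
prior until a transition becomes likely.

At each "overlap" of the stimulus (the depth-symmetric configurations where
transitions occur, the model's sampling grid) the observer combines

- the stability prior `N(μ_stability, 1/π_stability)`, centred on the
  previous decision `y(t−1)`, and
- a stereodisparity weight `N(μ_stereo, 1/π_stereo)` carrying any external
  disambiguation (`μ_stereo = 0.5` when the display is ambiguous, 0 or 1 in
  a disambiguated "replay" condition),

into a joint prior `(μ_m, π_m)` over a bimodal likelihood with narrow modes
at θ = 0 and θ = 1. In the narrow-mode limit the posterior weight of the
counter-clockwise interpretation has the closed form

    P(θ > 0.5) = σ(π_m (μ_m − ½)),        σ = logistic

and the response model maps it through a unit-square sigmoid with inverse
temperature ζ. The prediction error `PE = |y − P(θ > 0.5)|` accumulates on
the prior's variance, `1/π ← 1/π + PE`, and the precision resets to
`π_init` after each transition. Three free parameters — `π_init`,
`π_stereo`, ζ — control stabilisation strength, disambiguation efficacy and
decision noise.

The package is aimed at computational-neuroscience users who want to
simulate this model, fit its variants to per-overlap binary reports, compare
it against oscillator / attractor / intermediate models of bistability via
random-effects Bayesian model selection, and construct prediction-error
parametric regressors for model-based fMRI analyses.

## Worked example

```sh
python examples/01_simulate_dominance.py
```

```
complete dominance phases: 18387
mean duration:             10.88 s
median duration:           9.09 s
gamma shape (ML fit):      2.94
survival-product oracle:   10.84 s
```

Simulating 2×10⁵ s of ambiguous viewing at 0.33 Hz with `π_init = 3.5`
produces dominance phases whose mean (~10.9 s) agrees with the semi-analytic
survival-product expectation and whose maximum-likelihood gamma shape (≈ 2.9)
reproduces the right-skewed, "sharp rise and slow fall" distribution that is
the behavioural signature of bistable perception. The other examples cover
the synthetic cohort (`02`), variant fitting and random-effects model
selection (`03`), the rival dynamical models (`04`), and voxel-wise fMRI
model identification (`05`).

The same functionality is available from the shell:

```sh
bistablepc simulate --pi-init 3.5 --rate 0.33 --seconds 600000 --seed 1 --out sim.tsv
bistablepc synth --n-subjects 20 --seed 1 --out cohort/
bistablepc fit --responses cohort/sub-01_responses.tsv \
               --session cohort/sub-01_session.json --variant 4
bistablepc compare --evidence evidence.tsv
bistablepc recover --seed 1 --out study/
```

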