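"""Rival dynamical models of bistable perception.

Three canonical model classes serve as comparison points for the
predictive-coding account:

* **Oscillator** -- two rate-coded neural populations with mutual inhibition
  and slow self-adaptation.  The dominant population suppresses its rival
  until adaptation reverses the relation, producing quasi-periodic
  alternations even without noise.
* **Attractor** -- an overdamped particle in a symmetric double well; white
  noise triggers Kramers-type escapes between the two stable states, giving
  approximately exponential dominance durations at low noise.
* **Intermediate** -- the oscillator with additive noise on the population
  activities, combining adaptive and stochastic switching.

For fitting, each model's decision variable (difference of population
activities, or well position) is read out at the session's overlap times and
mapped through a logistic response function to a Bernoulli choice
probability, so the likelihood convention (Bernoulli at scored overlaps) and
the Laplace evidence are identical to those of the predictive-coding
variants, making evidences comparable in random-effects model selection.
The deterministic oscillator's unidentified initial phase is profiled out
on a grid of offsets inside the likelihood (without alignment it could not
score stochastic data); the stochastic models are evaluated under common
random numbers (a fixed simulation seed per fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bistablepc.exceptions import DataError, InvalidParameterError
from bistablepc.cohort import Session
from bistablepc.invert import map_laplace

#: Euler step used for simulation and fitting (s); small against the fast
#: population time constant (0.1 s) and the adaptation time constant.
DEFAULT_DT = 0.02

_TAU_R = 0.1  # fast population time constant (s)
_DIVERGE = 1e6


@dataclass(frozen=True)
class OscillatorParams:
    """Mutual-inhibition oscillator with self-adaptation."""

    inhibition: float = 2.0  # cross-inhibition weight
    adaptation: float = 1.2  # adaptation weight on the own population
    tau_adapt: float = 3.5  # adaptation time constant (s)
    drive: float = 1.0  # common input drive
    gain: float = 8.0  # slope of the sigmoidal rate function
    noise: float = 0.0  # additive noise on activities (0: pure oscillator)

    def __post_init__(self) -> None:
        if self.tau_adapt <= 0:
            raise InvalidParameterError("tau_adapt must be > 0")
        if self.inhibition < 0 or self.adaptation < 0 or self.noise < 0:
            raise InvalidParameterError("weights and noise must be >= 0")


@dataclass(frozen=True)
class AttractorParams:
    """Noise-driven double-well attractor."""

    barrier: float = 1.2  # well stiffness; barrier height scales with it
    noise: float = 0.6  # additive white-noise amplitude
    tau: float = 1.0  # relaxation time constant (s)

    def __post_init__(self) -> None:
        if self.barrier <= 0 or self.tau <= 0 or self.noise < 0:
            raise InvalidParameterError("barrier and tau must be > 0, noise >= 0")


@dataclass
class RivalTrajectory:
    """State time-series of a rival model with derived percepts."""

    times: np.ndarray
    state: np.ndarray  # decision variable: u1 - u2, or well position x
    percepts: np.ndarray  # argmax population / hysteresis sign
    dt: float

    def state_at(self, t: Sequence[float]) -> np.ndarray:
        """Decision variable sampled (nearest-neighbour) at times ``t``."""
        idx = np.clip(
            np.round(np.asarray(t) / self.dt).astype(int), 0, len(self.state) - 1
        )
        return self.state[idx]


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def simulate_oscillator(
    params: OscillatorParams,
    total_s: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    burn_in_s: float = 0.0,
) -> RivalTrajectory:
    """Euler(-Maruyama) integration of the two-population rate model.

    ``tau_r du_i = (-u_i + S(gain (drive - inhibition*u_j - adaptation*a_i)))
    dt + noise dW`` with slow adaptation ``tau_a da_i = (u_i - a_i) dt``.
    The percept is the currently larger activity.  ``burn_in_s`` shifts the
    recording window, which acts as an initial-phase offset for the
    deterministic oscillator.
    """
    if dt <= 0 or dt > params.tau_adapt / 10:
        raise InvalidParameterError("dt must be positive and << tau_adapt")
    rng = np.random.default_rng(seed)
    n_burn = int(round(burn_in_s / dt))
    n = int(round(total_s / dt))
    u1, u2, a1, a2 = 0.6, 0.1, 0.3, 0.1
    g, beta, phi, drive = params.gain, params.inhibition, params.adaptation, params.drive
    tau_a, sigma = params.tau_adapt, params.noise
    sq = math.sqrt(dt)
    state = np.empty(n)
    noise_draws = rng.standard_normal((n_burn + n, 2)) if sigma > 0 else None
    exp = math.exp

    for i in range(n_burn + n):
        x1 = g * (drive - beta * u2 - phi * a1)
        x2 = g * (drive - beta * u1 - phi * a2)
        f1 = 1.0 / (1.0 + exp(-x1)) if x1 >= 0 else exp(x1) / (1.0 + exp(x1))
        f2 = 1.0 / (1.0 + exp(-x2)) if x2 >= 0 else exp(x2) / (1.0 + exp(x2))
        du1 = (-u1 + f1) / _TAU_R * dt
        du2 = (-u2 + f2) / _TAU_R * dt
        if sigma > 0:
            du1 += sigma * noise_draws[i, 0] * sq
            du2 += sigma * noise_draws[i, 1] * sq
        u1 += du1
        u2 += du2
        a1 += (u1 - a1) / tau_a * dt
        a2 += (u2 - a2) / tau_a * dt
        if abs(u1) > _DIVERGE or abs(u2) > _DIVERGE:
            raise InvalidParameterError(
                "oscillator state diverged; reduce the integration step"
            )
        if i >= n_burn:
            state[i - n_burn] = u1 - u2
    percepts = (state > 0).astype(np.int8)
    return RivalTrajectory(np.arange(n) * dt, state, percepts, dt)


def simulate_attractor(
    params: AttractorParams,
    total_s: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    x0: float = 1.0,
    hysteresis: float = 0.5,
) -> RivalTrajectory:
    """Overdamped double-well dynamics ``dx = (barrier/tau)(x - x^3) dt + noise dW``.

    Wells sit at x = +/-1.  The percept switches only when the state crosses
    ``+/-hysteresis``, which suppresses spurious re-crossing jitter at the
    barrier top and leaves the Kramers escape statistics intact.
    """
    if dt <= 0 or dt > params.tau / 10:
        raise InvalidParameterError("dt must be positive and << tau")
    rng = np.random.default_rng(seed)
    n = int(round(total_s / dt))
    x = x0
    k = params.barrier / params.tau
    sigma = params.noise
    sq = math.sqrt(dt)
    draws = rng.standard_normal(n) if sigma > 0 else None
    state = np.empty(n)
    percepts = np.empty(n, dtype=np.int8)
    current = 1 if x0 >= 0 else 0
    for i in range(n):
        dx = k * (x - x * x * x) * dt
        if sigma > 0:
            dx += sigma * draws[i] * sq
        x += dx
        if abs(x) > _DIVERGE:
            raise InvalidParameterError(
                "attractor state diverged; reduce the integration step"
            )
        if current == 1 and x < -hysteresis:
            current = 0
        elif current == 0 and x > hysteresis:
            current = 1
        state[i] = x
        percepts[i] = current
    return RivalTrajectory(np.arange(n) * dt, state, percepts, dt)


def simulate_intermediate(
    params: OscillatorParams,
    total_s: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    burn_in_s: float = 0.0,
) -> RivalTrajectory:
    """Oscillator dynamics with additive noise (adaptation *and* noise).

    With ``noise = 0`` this is exactly :func:`simulate_oscillator`.
    """
    return simulate_oscillator(params, total_s, dt, seed=seed, burn_in_s=burn_in_s)


# ---------------------------------------------------------------------------
# Fitting rivals to response data
# ---------------------------------------------------------------------------

#: Free parameters per model kind: (name, prior mean in log space, prior var).
_RIVAL_PRIORS: dict[str, list[tuple[str, float, float]]] = {
    "oscillator": [
        ("adaptation", math.log(1.2), 0.5),
        ("tau_adapt", math.log(3.5), 0.5),
        ("resp_gain", math.log(5.0), 1.0),
    ],
    "attractor": [
        ("barrier", math.log(1.2), 0.5),
        ("noise", math.log(0.6), 0.5),
        ("resp_gain", math.log(5.0), 1.0),
    ],
    "intermediate": [
        ("adaptation", math.log(1.2), 0.5),
        ("tau_adapt", math.log(3.5), 0.5),
        ("noise", math.log(0.1), 0.5),
        ("resp_gain", math.log(5.0), 1.0),
    ],
}


@dataclass
class RivalFitResult:
    """MAP fit of one rival model on one subject's responses."""

    model_kind: str
    free_names: tuple[str, ...]
    map_log_params: np.ndarray
    posterior_cov: np.ndarray
    log_evidence: float
    neg_log_joint: float
    n_scored: int
    converged: bool
    hessian_fixed: bool = False

    @property
    def map_params(self) -> dict[str, float]:
        return {
            n: float(np.exp(v)) for n, v in zip(self.free_names, self.map_log_params)
        }


#: Phase offsets (as fractions of 6 * tau_adapt, roughly one alternation
#: cycle) profiled for the deterministic oscillator.
_PHASE_GRID = np.linspace(0.0, 1.0, 24, endpoint=False)


def _rival_state_at_overlaps(
    model_kind: str,
    values: dict[str, float],
    run_duration: float,
    overlap_times: np.ndarray,
    dt: float,
    sim_seed: int,
) -> np.ndarray:
    """Decision variable at overlap times.

    For the deterministic oscillator the initial phase is unidentified from
    priors alone, so the trajectory is simulated over one extra alternation
    cycle and returned at a grid of phase offsets (rows); the caller
    profiles the offset by taking the best likelihood.
    """
    if model_kind == "oscillator":
        span = 6.0 * values["tau_adapt"]
        traj = simulate_oscillator(
            OscillatorParams(
                adaptation=values["adaptation"],
                tau_adapt=values["tau_adapt"],
                noise=0.0,
            ),
            run_duration + span,
            dt,
            seed=sim_seed,
        )
        return np.stack(
            [traj.state_at(overlap_times + off * span) for off in _PHASE_GRID]
        )
    elif model_kind == "attractor":
        traj = simulate_attractor(
            AttractorParams(barrier=values["barrier"], noise=values["noise"]),
            run_duration,
            dt,
            seed=sim_seed,
        )
    elif model_kind == "intermediate":
        traj = simulate_intermediate(
            OscillatorParams(
                adaptation=values["adaptation"],
                tau_adapt=values["tau_adapt"],
                noise=values["noise"],
            ),
            run_duration,
            dt,
            seed=sim_seed,
        )
    else:
        raise InvalidParameterError(f"unknown rival model kind {model_kind!r}")
    return traj.state_at(overlap_times)


def fit_rival(
    model_kind: str,
    responses: pd.DataFrame,
    session: Session,
    n_starts: int = 4,
    seed: int = 0,
    dt: float = DEFAULT_DT,
) -> RivalFitResult:
    """MAP + Laplace fit of a rival model, evidence-comparable with the
    predictive-coding variants.

    The model is simulated over each run's duration, its decision variable
    is sampled at the overlap times, scaled by a free response gain and
    mapped through a logistic to a Bernoulli choice probability at the same
    scored overlaps used by the predictive-coding likelihood.  Stochastic
    rivals are integrated under a fixed simulation seed so the objective is
    deterministic.
    """
    if model_kind not in _RIVAL_PRIORS:
        raise InvalidParameterError(f"unknown rival model kind {model_kind!r}")
    spec = _RIVAL_PRIORS[model_kind]
    names = tuple(n for n, _, _ in spec)
    means = np.array([m for _, m, _ in spec])
    variances = np.array([v for _, _, v in spec])

    # per-run overlap times and scored decisions, on the run clock
    from bistablepc.model import _prepare_run_arrays

    run_data = []
    merged = session.overlaps.merge(
        responses[["run", "block", "overlap_index", "response"]],
        on=["run", "block", "overlap_index"],
        how="left",
        validate="one_to_one",
    )
    for run, frame in merged.groupby("run", sort=True):
        frame = frame.sort_values("time_s")
        prep = _prepare_run_arrays(frame)
        if prep is None:
            continue
        kept = frame.loc[prep["keep"]]
        run_data.append(
            {
                "times": kept["time_s"].to_numpy(dtype=float),
                "y": np.asarray(prep["y"]),
                "scored": np.asarray(prep["scored"]),
                "duration": session.run_duration_s(int(run)),
            }
        )
    n_sc = int(sum(r["scored"].sum() for r in run_data))
    if n_sc == 0:
        raise DataError("no scored overlaps")

    sim_seed = seed + 7919

    def objective(x: np.ndarray) -> float:
        if np.any(np.abs(x) > 6):
            return 1e8
        values = dict(zip(names, np.exp(x)))
        nll = 0.0
        for rd in run_data:
            try:
                s = values["resp_gain"] * _rival_state_at_overlaps(
                    model_kind, values, rd["duration"], rd["times"], dt, sim_seed
                )
            except InvalidParameterError:
                return 1e8
            p = 1.0 / (1.0 + np.exp(-np.clip(s, -35, 35)))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = np.where(rd["y"] == 1, np.log(p), np.log1p(-p))
            if ll.ndim == 2:  # phase offsets profiled: best-aligned offset
                nll -= float(ll[:, rd["scored"]].sum(axis=1).max())
            else:
                nll -= float(ll[rd["scored"]].sum())
        for value, m, v in zip(x, means, variances):
            nll += 0.5 * (math.log(2 * math.pi * v) + (value - m) ** 2 / v)
        return nll

    # the oscillatory likelihood is comb-like in the adaptation time
    # constant (period mismatch accumulates phase drift), so quasi-Newton
    # polishing is preceded by a coarse-to-fine profile over tau_adapt
    extra_starts = []
    if "tau_adapt" in names:
        j = names.index("tau_adapt")

        def with_tau(log_tau: float) -> np.ndarray:
            x = means.copy()
            x[j] = log_tau
            return x

        coarse = np.log(np.geomspace(1.5, 9.0, 40))
        best_tau = min(coarse, key=lambda g: objective(with_tau(g)))
        fine = best_tau + np.linspace(-0.05, 0.05, 11)
        best_tau = min(fine, key=lambda g: objective(with_tau(g)))
        extra_starts.append(with_tau(best_tau))

    x, fun, lme, cov, fixed, success = map_laplace(
        objective,
        means,
        variances,
        n_starts=n_starts,
        seed=seed,
        extra_starts=extra_starts,
    )
    return RivalFitResult(
        model_kind=model_kind,
        free_names=names,
        map_log_params=x,
        posterior_cov=cov,
        log_evidence=lme,
        neg_log_joint=fun,
        n_scored=n_sc,
        converged=success,
        hessian_fixed=fixed,
    )
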