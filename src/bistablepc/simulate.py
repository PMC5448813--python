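"""Generative simulation of perceptual time-courses and dominance statistics.

The model is iterated on the overlap grid (default sampling rate 0.33 Hz,
matching the average overlap frequency of the underlying experiment) with
sampled Bernoulli decisions.  Dominance phases are runs of constant decision;
their durations are classically gamma-like, with a sharp rise and slow fall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bistablepc.exceptions import DataError, InvalidParameterError
from bistablepc.model import (
    AMBIGUOUS,
    ModelParams,
    OverlapInput,
    PerceptualState,
    step,
)


@dataclass
class SimulationResult:
    """A simulated perceptual time-course on the overlap grid."""

    decisions: np.ndarray
    records: pd.DataFrame
    dt: float
    seed: int


def simulate_timecourse(
    params: ModelParams,
    total_seconds: float,
    sampling_rate_hz: float = 0.33,
    inputs: Optional[Sequence[OverlapInput]] = None,
    seed: int = 0,
) -> SimulationResult:
    """Iterate the belief-update engine with sampled decisions.

    When ``inputs`` is omitted every overlap is ambiguous
    (``mu_stereo = 0.5``), the configuration used for the dominance-duration
    simulation.  The initial percept is drawn uniformly and the state starts
    at full precision ``pi_init``.
    """
    if sampling_rate_hz <= 0:
        raise InvalidParameterError("sampling rate must be > 0")
    n_steps = int(total_seconds * sampling_rate_hz)
    if n_steps < 2:
        raise InvalidParameterError("need at least two overlaps to simulate")
    dt = 1.0 / sampling_rate_hz
    if inputs is None:
        inputs = [OverlapInput(0.5, AMBIGUOUS, k * dt) for k in range(n_steps)]
    else:
        inputs = list(inputs)[:n_steps]
        n_steps = len(inputs)

    rng = np.random.default_rng(seed)
    state = PerceptualState(float(rng.integers(0, 2)), params.pi_init)
    decisions = np.empty(n_steps, dtype=np.int8)
    rows = []
    for k in range(n_steps):
        state, rec = step(state, inputs[k], params, decision=None, rng=rng)
        decisions[k] = rec.y
        rows.append((rec.mu_m, rec.pi_m, rec.p_ccw, rec.y_predicted, rec.y, rec.pe))
    records = pd.DataFrame(
        rows, columns=["mu_m", "pi_m", "p_ccw", "y_predicted", "y", "pe"]
    )
    records["time_s"] = np.arange(n_steps) * dt
    return SimulationResult(decisions=decisions, records=records, dt=dt, seed=seed)


def phase_durations(decisions: Sequence[int], dt: float) -> np.ndarray:
    """Durations (seconds) of complete dominance phases.

    Runs of constant decision are converted to seconds; the first and last
    runs are truncated by the observation window and are excluded.
    """
    decisions = np.asarray(decisions)
    if decisions.size == 0:
        raise DataError("empty decision sequence")
    if decisions.size < 2:
        return np.empty(0)
    change = np.flatnonzero(np.diff(decisions) != 0)
    if change.size < 2:
        return np.empty(0)
    # run lengths between successive changes; boundary runs dropped
    lengths = np.diff(change)
    return lengths * dt


def duration_stats(durations: Sequence[float]) -> dict:
    """Summary statistics and an ML gamma fit of dominance durations."""
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise DataError("need at least two complete phases")
    out = {
        "n": int(durations.size),
        "mean": float(np.mean(durations)),
        "median": float(np.median(durations)),
        "cv": float(np.std(durations) / np.mean(durations)),
    }
    if durations.size >= 30 and np.std(durations) > 0:
        shape, _, scale = stats.gamma.fit(durations, floc=0)
        out["gamma_shape"] = float(shape)
        out["gamma_scale"] = float(scale)
    else:
        out["gamma_shape"] = float("nan")
        out["gamma_scale"] = float("nan")
    return out


def expected_mean_duration(
    params: ModelParams,
    sampling_rate_hz: float = 0.33,
    max_steps: int = 100_000,
    tol: float = 1e-12,
) -> float:
    """Semi-analytic expected dominance duration via the survival product.

    Conditional on the percept surviving, the within-phase dynamics under
    ambiguous input are deterministic: the stay probability after j updates,
    p_stay(j), follows the all-stay PE path.  The expected phase length in
    overlaps is then exactly ``1 + sum_k prod_{j<=k} p_stay(j)``, converted
    to seconds by the overlap interval.  Serves as an independent check on
    the stochastic simulation.
    """
    if sampling_rate_hz <= 0:
        raise InvalidParameterError("sampling rate must be > 0")
    pi = params.pi_init
    survival = 1.0
    expected = 1.0
    for _ in range(max_steps):
        p_stay = 1.0 / (1.0 + np.exp(-pi / 2.0))
        p_stay = float(
            response_probability_scalar(p_stay, params.zeta)
        )
        survival *= p_stay
        expected += survival
        if survival < tol:
            break
        pe = 1.0 - p_stay_posterior(pi)
        if pi > 0 and pe > 0:
            pi = 1.0 / (1.0 / pi + pe)
    return expected / sampling_rate_hz


def p_stay_posterior(pi_stability: float) -> float:
    """Posterior weight of the dominant percept under ambiguous input."""
    return 1.0 / (1.0 + np.exp(-pi_stability / 2.0))


def response_probability_scalar(p: float, zeta: float) -> float:
    if zeta == 1.0:
        return p
    a = p**zeta
    return a / (a + (1.0 - p) ** zeta)
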