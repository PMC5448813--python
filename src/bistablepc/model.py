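"""Per-overlap Bayesian belief updating for bistable perception.

The perceptual variable theta codes the rotation direction of an ambiguous
structure-from-motion (Lissajous) stimulus: 0 for clockwise, 1 for
counter-clockwise.  Perceptual decisions are made at "overlaps", the
depth-symmetric stimulus configurations where transitions occur, so the model
operates on a discrete per-overlap grid.

At each overlap the observer combines two Gaussian factors into a joint prior
over theta:

* a *stability prior* N(mu_stability, 1/pi_stability) centred on the previous
  perceptual decision, and
* a *stereodisparity weight* N(mu_stereo, 1/pi_stereo) carrying any external
  disambiguation (mu_stereo = 0.5 for ambiguous display; 0 or 1 in the replay
  condition).

The joint prior weights a bimodal likelihood with narrow modes at theta = 0
and theta = 1.  In the narrow-mode limit the posterior probability of the
counter-clockwise interpretation reduces to a logistic function of the joint
prior alone,

    P(theta > 0.5) = logistic(pi_m * (mu_m - 0.5)),

which is the closed form used throughout.  The residual posterior mass for
the suppressed percept defines the prediction error PE = |y - P(theta > 0.5)|
for decision y.  While the percept is stable, the prediction error
accumulates on the variance of the stability prior (1/pi <- 1/pi + PE), so
the prior decays and a transition becomes increasingly likely; after a
transition the precision resets to its initial value pi_init.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from bistablepc.exceptions import DataError, InvalidParameterError

#: Percept codes.
CLOCKWISE = 0
COUNTER_CLOCKWISE = 1

AMBIGUOUS = "ambiguous"
REPLAY = "replay"


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the belief-update model.

    Parameters
    ----------
    pi_init:
        Initial precision of the stability prior, set immediately after a
        perceptual transition.  ``0`` disables the stability prior entirely
        (the model variant without perceptual stability).
    pi_stereo:
        Precision of the stereodisparity weight.  ``0`` disables external
        disambiguation (the variant without stereodisparity).
    zeta:
        Inverse decision temperature of the unit-square-sigmoid response
        model.  ``1`` makes the predicted response equal the posterior
        weight, the convention used for the main fit.
    """

    pi_init: float = 3.5
    pi_stereo: float = 0.0
    zeta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pi_init", "pi_stereo", "zeta"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidParameterError(f"{name} must be finite, got {value!r}")
        if self.pi_init < 0 or self.pi_stereo < 0:
            raise InvalidParameterError("precisions must be >= 0")
        if self.zeta <= 0:
            raise InvalidParameterError("zeta must be > 0")


@dataclass(frozen=True)
class PerceptualState:
    """Evolving stability prior: previous decision and its precision."""

    mu_stability: float
    pi_stability: float

    def __post_init__(self) -> None:
        if self.mu_stability not in (0.0, 1.0):
            raise InvalidParameterError("mu_stability must be 0 or 1")
        if not (self.pi_stability >= 0 and math.isfinite(self.pi_stability)):
            raise InvalidParameterError("pi_stability must be finite and >= 0")


@dataclass(frozen=True)
class OverlapInput:
    """Stimulus information available at one overlap configuration."""

    mu_stereo: float = 0.5
    condition: str = AMBIGUOUS
    time: float = 0.0


@dataclass(frozen=True)
class StepRecord:
    """Model quantities emitted at a single overlap."""

    mu_m: float
    pi_m: float
    p_ccw: float
    y_predicted: float
    y: int
    pe: float


def combine_prior(
    state: PerceptualState, overlap: OverlapInput, params: ModelParams
) -> tuple[float, float]:
    """Combine stability prior and stereodisparity weight into the joint prior.

    Returns the precision-weighted mean ``mu_m`` and summed precision
    ``pi_m`` of the product of the two Gaussian factors.  When both
    precisions vanish the joint prior is flat and ``mu_m = 0.5`` by
    convention.
    """
    pi_s = state.pi_stability
    pi_e = params.pi_stereo
    if pi_s < 0 or pi_e < 0:
        raise InvalidParameterError("precisions must be >= 0")
    pi_m = pi_s + pi_e
    if pi_m == 0.0:
        return 0.5, 0.0
    mu_m = (pi_s * state.mu_stability + pi_e * overlap.mu_stereo) / pi_m
    return mu_m, pi_m


def posterior_ccw(mu_m: float, pi_m: float) -> float:
    """Posterior probability of the counter-clockwise percept.

    Closed form of the two-mode likelihood reduction:
    ``logistic(pi_m * (mu_m - 0.5))``.  Equals 0.5 for a flat or symmetric
    joint prior and is strictly inside (0, 1) for finite arguments.
    """
    if not (math.isfinite(mu_m) and math.isfinite(pi_m)):
        raise InvalidParameterError("mu_m and pi_m must be finite")
    if pi_m < 0:
        raise InvalidParameterError("pi_m must be >= 0")
    x = pi_m * (mu_m - 0.5)
    # numerically symmetric logistic, clamped to the open unit interval
    if x >= 0:
        p = 1.0 / (1.0 + math.exp(-x)) if x < 700 else 1.0
    else:
        e = math.exp(x) if x > -700 else 0.0
        p = e / (1.0 + e)
    return min(max(p, 1e-300), 1.0 - 1e-16)


def response_probability(p_ccw: float, zeta: float) -> float:
    """Map the posterior weight through the unit-square sigmoid response model.

    ``y_predicted = p^zeta / (p^zeta + (1-p)^zeta)``; the identity for
    ``zeta = 1`` and a fixed point at 0.5 for any temperature.
    """
    if zeta <= 0:
        raise InvalidParameterError("zeta must be > 0")
    if not 0.0 < p_ccw < 1.0:
        raise InvalidParameterError("p_ccw must lie strictly in (0, 1)")
    if zeta == 1.0:
        return p_ccw
    a = p_ccw**zeta
    b = (1.0 - p_ccw) ** zeta
    return a / (a + b)


def prediction_error(y: int, p_ccw: float) -> float:
    """Residual posterior evidence for the suppressed percept, ``|y - p_ccw|``."""
    if y not in (0, 1):
        raise DataError(f"decision must be 0 or 1, got {y!r}")
    return abs(y - p_ccw)


def update_state(
    state: PerceptualState, y_t: int, pe_t: float, params: ModelParams
) -> PerceptualState:
    """Advance the stability prior given the current decision and PE.

    A decision differing from the prior mean is a perceptual transition: the
    prior recentres on the new percept with precision reset to ``pi_init``.
    Otherwise the prediction error accumulates additively on the variance,
    ``1/pi <- 1/pi + PE``, leaving the mean unchanged.
    """
    if not 0.0 <= pe_t <= 1.0:
        raise DataError("prediction error must lie in [0, 1]")
    if float(y_t) != state.mu_stability:
        return PerceptualState(float(y_t), params.pi_init)
    if state.pi_stability == 0.0 or pe_t == 0.0:
        return state
    return PerceptualState(
        state.mu_stability, 1.0 / (1.0 / state.pi_stability + pe_t)
    )


def step(
    state: PerceptualState,
    overlap: OverlapInput,
    params: ModelParams,
    decision: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PerceptualState, StepRecord]:
    """Run one full overlap: combine, decide, compute PE, update.

    ``decision`` supplies an observed report; when ``None`` the decision is
    sampled from a Bernoulli with probability ``y_predicted`` using ``rng``.
    """
    mu_m, pi_m = combine_prior(state, overlap, params)
    p_ccw = posterior_ccw(mu_m, pi_m)
    y_pred = response_probability(p_ccw, params.zeta)
    if decision is None:
        if rng is None:
            raise InvalidParameterError("sampled decisions require an rng")
        y = 1 if rng.random() < y_pred else 0
    else:
        if decision not in (0, 1):
            raise DataError(f"observed decision must be 0 or 1, got {decision!r}")
        y = int(decision)
    pe = prediction_error(y, p_ccw)
    new_state = update_state(state, y, pe, params)
    return new_state, StepRecord(mu_m, pi_m, p_ccw, y_pred, y, pe)


# ---------------------------------------------------------------------------
# Filtering observed responses through the model
# ---------------------------------------------------------------------------

def _prepare_run_arrays(frame: pd.DataFrame) -> Optional[dict]:
    """Carry decisions over missing reports and mark scored overlaps.

    ``frame`` holds one run's overlaps in time order with columns
    ``block``, ``mu_stereo`` and ``response`` (0/1/NaN).  Returns plain
    Python lists for the tight likelihood loop, or ``None`` when no block of
    the run has any valid report.
    """
    block = frame["block"].to_numpy()
    mu_stereo = frame["mu_stereo"].to_numpy(dtype=float)
    response = frame["response"].to_numpy(dtype=float)

    y: list[int] = []
    scored: list[bool] = []
    new_block: list[bool] = []
    keep = np.ones(len(frame), dtype=bool)

    prev_block = None
    current: Optional[int] = None
    for i in range(len(frame)):
        starts = block[i] != prev_block
        prev_block = block[i]
        if starts:
            # state re-initialises on the first reported percept of the block
            in_block = block == block[i]
            valid = in_block & ~np.isnan(response)
            if not valid.any():
                keep[in_block] = False
                current = None
                continue
            current = int(response[np.flatnonzero(valid)[0]])
        if current is None:  # block skipped entirely
            keep[i] = False
            continue
        observed = not math.isnan(response[i])
        if observed:
            current = int(response[i])
        y.append(current)
        # first overlap of a block and unreported overlaps carry no likelihood
        scored.append(observed and not starts)
        new_block.append(starts)
    if not y:
        return None
    return {
        "y": y,
        "mu_stereo": [float(v) for v in mu_stereo[keep]],
        "scored": scored,
        "new_block": new_block,
        "keep": keep,
    }


def _run_filter(
    pi_init: float,
    pi_stereo: float,
    zeta: float,
    y: list[int],
    mu_stereo: list[float],
    new_block: list[bool],
    collect: bool = False,
):
    """Deterministic filtering of one run's observed decisions.

    Returns ``(log_lik_terms, records)`` where ``log_lik_terms`` is the list
    of per-overlap Bernoulli log-probabilities (for every overlap; callers
    mask unscored ones) and ``records`` the per-overlap model quantities when
    ``collect`` is set.  Written as a tight scalar loop because the
    recursion over overlaps cannot be vectorised.
    """
    exp = math.exp
    loglik: list[float] = []
    records = [] if collect else None
    mu = 0.0
    pi = 0.0
    for i in range(len(y)):
        yi = y[i]
        if new_block[i]:
            mu = float(yi)
            pi = pi_init
        pi_m = pi + pi_stereo
        if pi_m > 0.0:
            mu_m = (pi * mu + pi_stereo * mu_stereo[i]) / pi_m
        else:
            mu_m = 0.5
        x = pi_m * (mu_m - 0.5)
        if x >= 0.0:
            p = 1.0 / (1.0 + exp(-x))
        else:
            e = exp(x)
            p = e / (1.0 + e)
        if zeta == 1.0:
            yp = p
        else:
            a = p**zeta
            b = (1.0 - p) ** zeta
            yp = a / (a + b)
        prob = yp if yi == 1 else 1.0 - yp
        if prob < 1e-300:
            prob = 1e-300
        loglik.append(math.log(prob))
        pe = yi - p if yi == 1 else p - yi
        if collect:
            records.append((mu_m, pi_m, p, yp, yi, pe, pi))
        if float(yi) != mu:
            mu = float(yi)
            pi = pi_init
        elif pi > 0.0 and pe > 0.0:
            pi = 1.0 / (1.0 / pi + pe)
    return loglik, records


def filter_responses(
    responses: pd.DataFrame,
    session: "Session",  # noqa: F821 - forward ref to cohort.Session
    params: ModelParams,
) -> pd.DataFrame:
    """Filter observed reports through the model, one deterministic pass.

    ``responses`` must carry one row per session overlap with columns
    ``run, block, overlap_index, time_s, condition, response`` where
    ``response`` is 0, 1 or NaN (missing / mixed report).  The state is
    re-initialised at each block start on the first reported percept; first
    overlaps of a block and unreported overlaps are marked unscored and are
    excluded from fitting likelihoods.  Missing reports carry the previous
    decision forward for state propagation.

    Returns a per-overlap trajectory with the model quantities
    (``mu_m, pi_m, p_ccw, y_predicted, y, pe, pi_stability``), the Bernoulli
    log-likelihood term and the ``scored`` flag; this is also the PE
    time-course consumed by the fMRI design stage.
    """
    overlaps = session.overlaps
    if len(responses) != len(overlaps):
        raise DataError(
            f"responses ({len(responses)}) do not match session overlaps "
            f"({len(overlaps)})"
        )
    merged = overlaps.merge(
        responses[["run", "block", "overlap_index", "response"]],
        on=["run", "block", "overlap_index"],
        how="left",
        validate="one_to_one",
    )
    if merged["response"].isna().all():
        raise DataError("no valid reports in any block")

    out_frames = []
    for run, frame in merged.groupby("run", sort=True):
        frame = frame.sort_values("time_s")
        prepared = _prepare_run_arrays(frame)
        if prepared is None:
            continue
        loglik, records = _run_filter(
            params.pi_init,
            params.pi_stereo,
            params.zeta,
            prepared["y"],
            prepared["mu_stereo"],
            prepared["new_block"],
            collect=True,
        )
        kept = frame.loc[prepared["keep"]].reset_index(drop=True)
        rec = pd.DataFrame(
            records,
            columns=["mu_m", "pi_m", "p_ccw", "y_predicted", "y", "pe", "pi_stability"],
        )
        rec["log_lik"] = loglik
        rec["scored"] = prepared["scored"]
        out_frames.append(pd.concat([kept, rec], axis=1))
    if not out_frames:
        raise DataError("no scorable runs")
    return pd.concat(out_frames, ignore_index=True)
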