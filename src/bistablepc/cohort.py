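"""Experimental session structure and synthetic subjects.

The underlying experiment presented three runs, each containing eight pairs
of an ambiguous block followed by a replay block, separated by 10 s fixation.
The rotational speed of the Lissajous figure was titrated per observer to one
of three overlap frequencies (0.24, 0.30, 0.40 Hz), with block durations of
42.8, 40.90 and 41 s respectively.  In the replay block, disparity cues
reimpose the perceptual time-course the observer reported during the
preceding ambiguous block.

Synthetic subjects are generated from the belief-update model itself:
ambiguous blocks are simulated freely, the resulting decision sequence is
turned into the replay disparity track (``mu_stereo`` in {0, 1}), and the
replay block is then simulated under that disambiguation.  Ground-truth
parameters are retained for recovery studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from bistablepc.exceptions import DataError, InvalidParameterError
from bistablepc.model import (
    AMBIGUOUS,
    REPLAY,
    ModelParams,
    OverlapInput,
    PerceptualState,
    step,
)

#: Block duration (s) for each admissible overlap frequency (Hz), paired in
#: the order the study lists them.
BLOCK_DURATIONS = {0.24: 42.8, 0.30: 40.90, 0.40: 41.0}

RESPONSE_COLUMNS = ["run", "block", "overlap_index", "time_s", "condition", "response"]


@dataclass
class Session:
    """Deterministic timeline of one subject's scanning sessions.

    ``blocks`` has one row per block (``run, block, condition, onset_s,
    duration_s``); ``overlaps`` one row per overlap (``run, block,
    overlap_index, time_s, condition, mu_stereo``).  Replay ``mu_stereo``
    defaults to 0.5 until a perceptual time-course is assigned.
    """

    overlap_frequency_hz: float
    fixation_s: float
    blocks: pd.DataFrame
    overlaps: pd.DataFrame

    @property
    def run_ids(self) -> list[int]:
        return sorted(self.blocks["run"].unique().tolist())

    def run_duration_s(self, run: int) -> float:
        b = self.blocks[self.blocks["run"] == run]
        return float(b["onset_s"].max() + b["duration_s"].iloc[-1] + self.fixation_s)

    def subset(self, run: int) -> "Session":
        """Single-run view (overlap frame restricted to one run)."""
        return Session(
            self.overlap_frequency_hz,
            self.fixation_s,
            self.blocks[self.blocks["run"] == run].reset_index(drop=True),
            self.overlaps[self.overlaps["run"] == run].reset_index(drop=True),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "overlap_frequency_hz": self.overlap_frequency_hz,
            "fixation_s": self.fixation_s,
            "blocks": self.blocks.to_dict(orient="list"),
            "overlaps": self.overlaps.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Session":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["overlap_frequency_hz"],
            payload["fixation_s"],
            pd.DataFrame(payload["blocks"]),
            pd.DataFrame(payload["overlaps"]),
        )


def build_session(
    overlap_frequency_hz: float,
    runs: int = 3,
    pairs_per_run: int = 8,
    fixation_s: float = 10.0,
) -> Session:
    """Construct the block/overlap timeline for one admissible frequency.

    Each run opens with a fixation period and alternates
    ambiguous -> replay blocks, every block followed by fixation.  Overlaps
    within a block are spaced at the overlap period, the first one full
    period after block onset; the per-block overlap count is
    ``floor(duration * frequency)``.
    """
    if overlap_frequency_hz not in BLOCK_DURATIONS:
        raise InvalidParameterError(
            f"unsupported overlap frequency {overlap_frequency_hz!r}; "
            f"choose one of {sorted(BLOCK_DURATIONS)}"
        )
    if runs < 1 or pairs_per_run < 1:
        raise InvalidParameterError("runs and pairs_per_run must be >= 1")
    duration = BLOCK_DURATIONS[overlap_frequency_hz]
    period = 1.0 / overlap_frequency_hz
    n_overlaps = int(np.floor(duration * overlap_frequency_hz))

    block_rows = []
    overlap_rows = []
    for run in range(1, runs + 1):
        t = fixation_s
        block_id = 0
        for _pair in range(pairs_per_run):
            for condition in (AMBIGUOUS, REPLAY):
                block_id += 1
                block_rows.append((run, block_id, condition, t, duration))
                for k in range(n_overlaps):
                    overlap_rows.append(
                        (run, block_id, k, t + (k + 1) * period, condition, 0.5)
                    )
                t += duration + fixation_s
    blocks = pd.DataFrame(
        block_rows, columns=["run", "block", "condition", "onset_s", "duration_s"]
    )
    overlaps = pd.DataFrame(
        overlap_rows,
        columns=["run", "block", "overlap_index", "time_s", "condition", "mu_stereo"],
    )
    return Session(overlap_frequency_hz, fixation_s, blocks, overlaps)


def replay_from_decisions(
    ambiguous_decisions: Sequence[int], n_replay: Optional[int] = None
) -> np.ndarray:
    """Disparity track mimicking a reported ambiguous time-course.

    ``mu_stereo`` at replay overlap k equals the decision at overlap k of the
    preceding ambiguous block, truncated or padded (with the last decision)
    to the replay block's overlap count.
    """
    decisions = np.asarray(ambiguous_decisions, dtype=float)
    if decisions.size == 0:
        raise DataError("empty decision sequence")
    if n_replay is None:
        n_replay = decisions.size
    if n_replay <= decisions.size:
        return decisions[:n_replay].copy()
    pad = np.full(n_replay - decisions.size, decisions[-1])
    return np.concatenate([decisions, pad])


@dataclass
class SyntheticSubject:
    """One simulated observer with known ground truth."""

    subject_id: int
    true_params: ModelParams
    session: Session
    responses: pd.DataFrame
    seed: int
    fits: dict = field(default_factory=dict, repr=False)


def simulate_subject(
    params: ModelParams,
    session: Session,
    seed: int = 0,
    missing_prob: float = 0.0,
) -> tuple[pd.DataFrame, Session]:
    """Simulate one subject's reports over a session.

    Ambiguous blocks are simulated under ``mu_stereo = 0.5``; each replay
    block inherits its disparity track from the simulated decisions of the
    preceding ambiguous block and is then simulated under that
    disambiguation.  ``missing_prob`` marks reports as missing (NaN) at
    random, never the first overlap of a block.

    Returns the response table and a copy of the session with replay
    ``mu_stereo`` filled in.
    """
    rng = np.random.default_rng(seed)
    overlaps = session.overlaps.copy().reset_index(drop=True)
    rows = []
    last_ambiguous: dict[int, np.ndarray] = {}
    for (run, block), frame in overlaps.groupby(["run", "block"], sort=True):
        frame = frame.sort_values("time_s")
        condition = frame["condition"].iloc[0]
        n = len(frame)
        if condition == REPLAY and run in last_ambiguous:
            track = replay_from_decisions(last_ambiguous[run], n)
        else:
            track = np.full(n, 0.5)
        overlaps.loc[frame.index, "mu_stereo"] = track
        state = PerceptualState(float(rng.integers(0, 2)), params.pi_init)
        decisions = np.empty(n, dtype=int)
        for i, (idx, row) in enumerate(frame.iterrows()):
            state, rec = step(
                state,
                OverlapInput(track[i], condition, row["time_s"]),
                params,
                decision=None,
                rng=rng,
            )
            decisions[i] = rec.y
        if condition == AMBIGUOUS:
            last_ambiguous[run] = decisions.copy()
        for i, (idx, row) in enumerate(frame.iterrows()):
            resp: float = float(decisions[i])
            if missing_prob > 0 and i > 0 and rng.random() < missing_prob:
                resp = np.nan
            rows.append(
                (
                    run,
                    block,
                    row["overlap_index"],
                    row["time_s"],
                    condition,
                    resp,
                )
            )
    responses = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    filled = Session(
        session.overlap_frequency_hz, session.fixation_s, session.blocks.copy(), overlaps
    )
    return responses, filled


def default_param_sampler(rng: np.random.Generator) -> ModelParams:
    """Cohort-level parameter distribution for synthetic observers.

    Precisions are log-normal around the scale the behavioural fits centre
    on: ``pi_init ~ LogNormal(log 3.5, 0.3^2)`` and
    ``pi_stereo ~ LogNormal(log 5, 0.3^2)``; the inverse decision
    temperature stays fixed at 1.
    """
    return ModelParams(
        pi_init=float(np.exp(rng.normal(np.log(3.5), 0.3))),
        pi_stereo=float(np.exp(rng.normal(np.log(5.0), 0.3))),
        zeta=1.0,
    )


def synth_cohort(
    n_subjects: int = 20,
    param_sampler: Optional[Callable[[np.random.Generator], ModelParams]] = None,
    frequencies: Sequence[float] = (0.24, 0.30, 0.40),
    master_seed: int = 0,
    runs: int = 3,
    pairs_per_run: int = 8,
    missing_prob: float = 0.0,
) -> list[SyntheticSubject]:
    """Generate a reproducible cohort balanced over overlap frequencies."""
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    if param_sampler is None:
        param_sampler = default_param_sampler
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n_subjects)
    subjects = []
    for s in range(n_subjects):
        param_rng = np.random.default_rng(int(seeds[2 * s]))
        params = param_sampler(param_rng)
        freq = frequencies[s % len(frequencies)]
        session = build_session(freq, runs=runs, pairs_per_run=pairs_per_run)
        subject_seed = int(seeds[2 * s + 1])
        responses, filled = simulate_subject(
            params, session, seed=subject_seed, missing_prob=missing_prob
        )
        subjects.append(
            SyntheticSubject(s + 1, params, filled, responses, subject_seed)
        )
    return subjects


def transition_frequency(
    responses: pd.DataFrame, condition: str = AMBIGUOUS, per: str = "overlap"
) -> float:
    """Empirical transition frequency within blocks of a condition.

    Counts within-block decision changes between consecutive reported
    overlaps.  With ``per="overlap"`` (the study's transition-probability
    measure, comparable across overlap frequencies) the count is divided by
    the number of scored transitions opportunities; with ``per="second"`` by
    the total stimulation time.
    """
    if per not in ("overlap", "second"):
        raise InvalidParameterError("per must be 'overlap' or 'second'")
    sel = responses[responses["condition"] == condition]
    if sel.empty:
        raise DataError(f"no overlaps with condition {condition!r}")
    n_transitions = 0
    n_opportunities = 0
    total_time = 0.0
    for (_run, _block), frame in sel.groupby(["run", "block"], sort=True):
        frame = frame.sort_values("time_s")
        reported = frame.dropna(subset=["response"])
        if len(reported) >= 2:
            n_transitions += int(
                (np.diff(reported["response"].to_numpy()) != 0).sum()
            )
            n_opportunities += len(reported) - 1
        total_time += float(frame["time_s"].max() - frame["time_s"].min())
    denom = n_opportunities if per == "overlap" else total_time
    if denom <= 0:
        raise DataError("degenerate block timing")
    return n_transitions / denom


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    """Write a response table as tab-separated text (NA for missing)."""
    responses.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_responses(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(RESPONSE_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"response table missing columns {sorted(missing)}")
    return frame
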