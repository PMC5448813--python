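"""Model-based fMRI design construction and voxel-wise model comparison.

Three general linear models operationalise competing accounts of
transition-related BOLD activity:

* **PE model** -- sticks for overlaps and perceptual transitions, plus the
  absolute model prediction error as a parametric modulator on the overlap
  sticks;
* **Conventional model** -- overlap sticks plus transition sticks split into
  ambiguous and replay transitions;
* **Block model** -- like the PE model but with an ambiguous-block indicator
  (box-car sampled at overlaps) as the parametric modulator.

Events are convolved with the canonical double-gamma haemodynamic response
on a fine time grid and down-sampled to scans; slow drifts below 1/128 Hz
are removed from data and design by projecting out a per-run discrete-cosine
basis.  Voxel-wise log model evidence uses a conjugate Gaussian linear model
(zero-mean, scaled-identity weight prior on standardised data), identical
across the compared designs; group-level inference runs random-effects model
selection per voxel to produce exceedance-probability maps.

All of this operates on synthetic BOLD: the package targets desk-scale model
recovery, not preprocessing of real scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from bistablepc.bms import exceedance_prob, rfx_bms
from bistablepc.exceptions import DataError, InvalidParameterError
from bistablepc.cohort import Session
from bistablepc.model import AMBIGUOUS, REPLAY

MODEL_KINDS = ("PE", "Conventional", "Block")


@dataclass
class RunEvents:
    """Stick onsets and parametric modulators for one run (run clock, s)."""

    run: int
    duration_s: float
    onsets: dict[str, np.ndarray]
    modulators: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class EventList:
    model_kind: str
    runs: list[RunEvents]

    @property
    def regressor_names(self) -> list[str]:
        names: list[str] = []
        for r in self.runs:
            for n in list(r.onsets) + list(r.modulators):
                if n not in names:
                    names.append(n)
        return names


def build_events(
    session: Session, trajectory: pd.DataFrame, model_kind: str = "PE"
) -> EventList:
    """Assemble stick events and modulators from a filtered trajectory.

    ``trajectory`` is the per-overlap output of
    :func:`bistablepc.model.filter_responses` (columns ``run, block, time_s,
    condition, y, pe``).  Transitions are within-block changes of the
    decision between consecutive overlaps.  The PE modulator is the absolute
    prediction error; the Block modulator is the ambiguous-block indicator.
    """
    if model_kind not in MODEL_KINDS:
        raise InvalidParameterError(
            f"model_kind must be one of {MODEL_KINDS}, got {model_kind!r}"
        )
    needed = {"run", "block", "time_s", "condition", "y", "pe"}
    if not needed.issubset(trajectory.columns):
        raise DataError(f"trajectory missing columns {sorted(needed - set(trajectory.columns))}")
    runs = []
    for run, frame in trajectory.groupby("run", sort=True):
        frame = frame.sort_values("time_s")
        times = frame["time_s"].to_numpy(dtype=float)
        same_block = frame["block"].to_numpy()[1:] == frame["block"].to_numpy()[:-1]
        changed = frame["y"].to_numpy()[1:] != frame["y"].to_numpy()[:-1]
        is_transition = np.concatenate([[False], same_block & changed])
        onsets = {"overlaps": times}
        modulators: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if model_kind == "Conventional":
            amb = frame["condition"].to_numpy() == AMBIGUOUS
            onsets["transitions_ambiguous"] = times[is_transition & amb]
            onsets["transitions_replay"] = times[is_transition & ~amb]
        else:
            onsets["transitions"] = times[is_transition]
            if model_kind == "PE":
                values = np.abs(frame["pe"].to_numpy(dtype=float))
                modulators["overlaps_x_pe"] = (times, values)
            else:
                values = (frame["condition"] == AMBIGUOUS).to_numpy(dtype=float)
                modulators["overlaps_x_ambiguous"] = (times, values)
        runs.append(
            RunEvents(int(run), session.run_duration_s(int(run)), onsets, modulators)
        )
    return EventList(model_kind, runs)


def hrf_kernel(dt: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``dt``.

    Response gamma with delay 6 s, undershoot with delay 16 s, both with
    dispersion 1 s, response:undershoot amplitude ratio 6, 32 s support.
    The kernel is normalised to unit peak, so convolved regressors keep the
    modulator's units.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    t = np.arange(0, length_s + dt / 2, dt)
    kernel = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(
        t, a=16.0, scale=1.0
    ) / 6.0
    return kernel / kernel.max()


def dct_basis(n_scans: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis (including the constant column).

    Columns are ``cos(pi k (2n + 1) / (2N))`` for ``k = 0 .. K-1`` with
    ``K = floor(2 N TR / cutoff) + 1``, the standard high-pass basis.
    """
    if n_scans < 1 or tr <= 0 or cutoff_s <= 0:
        raise InvalidParameterError("bad DCT basis arguments")
    order = int(np.floor(2.0 * n_scans * tr / cutoff_s)) + 1
    order = max(1, min(order, n_scans))
    n = np.arange(n_scans)
    basis = np.cos(
        np.pi * np.outer(2 * n + 1, np.arange(order)) / (2.0 * n_scans)
    )
    return basis


@dataclass
class DesignMatrix:
    """Scans x regressors design with its high-pass basis."""

    X: np.ndarray
    names: list[str]
    tr: float
    run_index: np.ndarray  # scan -> run position (0-based)
    dct: np.ndarray  # block-diagonal drift basis (scans x n_basis)
    model_kind: str = ""

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)


def highpass_project(M: np.ndarray, dct: np.ndarray) -> np.ndarray:
    """Residualise columns/series of ``M`` against the drift basis."""
    coef, *_ = np.linalg.lstsq(dct, M, rcond=None)
    return M - dct @ coef


def build_design(
    events: EventList,
    tr: float = 2.0,
    n_scans: Optional[dict[int, int] | int] = None,
    highpass_s: float = 128.0,
    oversample: int = 16,
    center_modulators: bool = True,
    nuisance: Optional[dict[int, np.ndarray]] = None,
) -> DesignMatrix:
    """Convolve events with the canonical HRF and sample at scan times.

    Sticks (and modulated sticks) are laid on a fine grid of ``oversample``
    bins per TR, convolved, and read out at scan onsets.  Parametric
    modulators are mean-centred within run before convolution, so the
    modulator column is orthogonal to its stick regressor's mean but not
    serially orthogonalised beyond that.  Per-run constants and optional
    nuisance columns are appended; the drift basis is stored for projection
    at fit time.  Events beyond the scan horizon are truncated with a
    warning.
    """
    fine_dt = tr / oversample
    kernel = hrf_kernel(fine_dt)
    names = events.regressor_names
    run_blocks = []
    dct_blocks = []
    run_index = []
    nuisance_blocks = []
    for pos, run_ev in enumerate(events.runs):
        if n_scans is None:
            ns = int(np.ceil(run_ev.duration_s / tr))
        elif isinstance(n_scans, dict):
            ns = n_scans[run_ev.run]
        else:
            ns = int(n_scans)
        n_fine = ns * oversample
        horizon = ns * tr
        cols = []
        for name in names:
            fine = np.zeros(n_fine)
            if name in run_ev.onsets:
                onsets = np.asarray(run_ev.onsets[name], dtype=float)
                values = np.ones_like(onsets)
            elif name in run_ev.modulators:
                onsets, values = run_ev.modulators[name]
                onsets = np.asarray(onsets, dtype=float)
                values = np.asarray(values, dtype=float)
                if center_modulators and values.size:
                    values = values - values.mean()
            else:
                cols.append(np.zeros(ns))
                continue
            inside = onsets < horizon
            if not inside.all():
                print(
                    f"run {run_ev.run}: {np.sum(~inside)} events beyond the "
                    f"scan horizon truncated"
                )
            idx = np.round(onsets[inside] / fine_dt).astype(int)
            np.add.at(fine, np.clip(idx, 0, n_fine - 1), values[inside])
            conv = np.convolve(fine, kernel)[:n_fine]
            cols.append(conv[::oversample])
        run_blocks.append(np.column_stack(cols) if cols else np.zeros((ns, 0)))
        dct_blocks.append(dct_basis(ns, tr, highpass_s))
        run_index.extend([pos] * ns)
        if nuisance is not None and run_ev.run in nuisance:
            nuisance_blocks.append(np.asarray(nuisance[run_ev.run], dtype=float))

    X = np.vstack(run_blocks)
    all_names = list(names)
    # per-run constants
    run_index = np.asarray(run_index)
    n_runs = len(events.runs)
    consts = np.zeros((X.shape[0], n_runs))
    for pos in range(n_runs):
        consts[run_index == pos, pos] = 1.0
    X = np.hstack([X, consts])
    all_names += [f"constant_run{r.run}" for r in events.runs]
    if nuisance_blocks:
        nuis = np.vstack(nuisance_blocks)
        X = np.hstack([X, nuis])
        all_names += [f"nuisance_{j}" for j in range(nuis.shape[1])]
    # block-diagonal drift basis
    total = X.shape[0]
    width = sum(b.shape[1] for b in dct_blocks)
    dct = np.zeros((total, width))
    row = col = 0
    for b in dct_blocks:
        dct[row : row + b.shape[0], col : col + b.shape[1]] = b
        row += b.shape[0]
        col += b.shape[1]
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite design entries")
    return DesignMatrix(X, all_names, tr, run_index, dct, events.model_kind)


def default_generating_betas(design: DesignMatrix) -> np.ndarray:
    """Generating coefficients for synthetic BOLD under each design's account.

    Overlap sticks respond weakly (0.5); transitions respond with unit
    amplitude; parametric modulators (|PE| or the ambiguity box-car) carry
    unit weight.  Under the Conventional account, transition responses are
    specific to endogenous transitions: ambiguous transitions at 2.0 versus
    replay transitions at 0.5.  Units are arbitrary BOLD amplitude per
    unit-peak HRF response.
    """
    beta = np.zeros(len(design.names))
    for i, name in enumerate(design.names):
        if name == "overlaps":
            beta[i] = 0.5
        elif name == "transitions":
            beta[i] = 1.0
        elif name == "transitions_ambiguous":
            beta[i] = 2.0
        elif name == "transitions_replay":
            beta[i] = 0.5
        elif "_x_" in name:
            beta[i] = 1.0
    return beta


def simulate_bold(
    design: DesignMatrix,
    betas: Sequence[float] | np.ndarray,
    noise_sd: float = 1.0,
    n_voxels: int = 1,
    seed: int = 0,
    drift: float = 0.0,
) -> np.ndarray:
    """Linear mixture of the design plus white Gaussian noise.

    ``betas`` is either one coefficient vector shared by all voxels or a
    ``n_voxels x regressors`` matrix.  ``drift`` adds a slow sinusoidal
    confound (period 256 s) that the high-pass stage should remove.
    """
    rng = np.random.default_rng(seed)
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    if betas.shape[0] == 1 and n_voxels > 1:
        betas = np.repeat(betas, n_voxels, axis=0)
    if betas.shape != (n_voxels, design.X.shape[1]):
        raise InvalidParameterError(
            f"betas must have shape ({n_voxels}, {design.X.shape[1]})"
        )
    Y = betas @ design.X.T
    if drift:
        t = np.arange(design.n_scans) * design.tr
        Y = Y + drift * np.sin(2 * np.pi * t / 256.0)
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    return Y


def _filtered(Y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    Xf = highpass_project(design.X, design.dct)
    Yf = highpass_project(np.asarray(Y, dtype=float).T, design.dct).T
    return Yf, Xf


def glm_contrast(
    Y: np.ndarray, design: DesignMatrix, contrast: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS estimates and t-statistics for a contrast.

    ``Y`` is voxels x scans.  Data and design are high-pass filtered first;
    the residual degrees of freedom account for both the regressors and the
    drift basis.  Rank-deficient designs raise an error naming the
    collinear columns.
    """
    contrast = np.asarray(contrast, dtype=float)
    Yf, Xf = _filtered(Y, design)
    p = Xf.shape[1]
    if contrast.shape != (p,):
        raise InvalidParameterError(f"contrast must have length {p}")
    # constants are absorbed by the drift basis; drop all-zero columns from
    # the rank check but flag genuinely collinear task regressors
    norms = np.linalg.norm(Xf, axis=0)
    active = norms > 1e-10 * max(1.0, norms.max())
    if contrast[~active].any():
        raise DataError("contrast loads on a regressor removed by filtering")
    Xa = Xf[:, active]
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        # name an offending pair via correlations
        c = np.corrcoef(Xa.T)
        np.fill_diagonal(c, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
        names = [n for n, a in zip(design.names, active) if a]
        raise DataError(
            f"rank-deficient design: columns {names[i]!r} and {names[j]!r} "
            "are collinear"
        )
    pinv = np.linalg.pinv(Xa)
    beta_a = Yf @ pinv.T
    resid = Yf - beta_a @ Xa.T
    dof = Yf.shape[1] - rank - design.dct.shape[1]
    if dof <= 0:
        raise DataError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=1) / dof
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    ca = contrast[active]
    var_scale = float(ca @ xtx_inv @ ca)
    effect = beta_a @ ca
    t = effect / np.sqrt(sigma2 * var_scale + 1e-300)
    betas = np.zeros((Y.shape[0], p))
    betas[:, active] = beta_a
    return betas, t


def voxel_evidence(
    Y: np.ndarray, design: DesignMatrix, prior_scale: float = 1.0
) -> np.ndarray:
    """Log model evidence per voxel under a conjugate Gaussian linear model.

    After high-pass filtering, each voxel's series is standardised to unit
    variance and the task regressors (constants excluded; they are absorbed
    by the drift basis) are scaled to unit norm per column.  With weights
    ``w ~ N(0, prior_scale^2 I)`` and unit noise variance the marginal
    likelihood is the Gaussian ``N(y; 0, I + s^2 X X^T)``, evaluated via the
    Woodbury identity.  The prior scale is identical across compared models,
    which keeps evidences comparable.
    """
    Yf, Xf = _filtered(Y, design)
    keep = [
        i
        for i, n in enumerate(design.names)
        if not n.startswith("constant_run")
    ]
    X = Xf[:, keep]
    norms = np.linalg.norm(X, axis=0)
    good = norms > 1e-12
    X = X[:, good] / norms[good]
    sd = Yf.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Yz = Yf / sd
    n = Yz.shape[1]
    s2 = prior_scale**2
    G = np.eye(X.shape[1]) + s2 * (X.T @ X)
    sign, logdet = np.linalg.slogdet(G)
    Xty = X.T @ Yz.T  # p x voxels
    quad = (Yz**2).sum(axis=1) - s2 * np.einsum(
        "pv,pq,qv->v", Xty, np.linalg.inv(G), Xty
    )
    return -0.5 * (n * math.log(2 * math.pi) + logdet + quad)


def group_epm(
    subject_maps: Sequence[np.ndarray],
    n_samples: int = 10_000,
    seed: int = 0,
) -> dict:
    """Voxel-wise random-effects model selection across subjects.

    ``subject_maps`` holds one voxels x models log-evidence array per
    subject, on identical voxel grids.  Returns expected frequencies,
    exceedance probabilities and the winning model per voxel.
    """
    maps = [np.asarray(m, dtype=float) for m in subject_maps]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise DataError("subject evidence maps have mismatching shapes")
    n_vox, n_models = shape
    xp = np.empty((n_vox, n_models))
    freq = np.empty((n_vox, n_models))
    rng = np.random.default_rng(seed)
    for v in range(n_vox):
        L = np.stack([m[v] for m in maps])
        res = rfx_bms(L)
        freq[v] = res.expected_freq
        xp[v] = exceedance_prob(
            res.alpha, n_samples=n_samples, seed=int(rng.integers(2**31))
        )
    return {
        "expected_freq": freq,
        "xp": xp,
        "assignment": np.argmax(xp, axis=1),
    }


def threshold_epm(
    xp_map: np.ndarray, gamma: float = 0.99, cluster_size: int = 10
) -> np.ndarray:
    """Display-convention thresholding: exceedance above ``gamma`` in
    connected clusters larger than ``cluster_size``.

    Works on maps of any dimensionality (1-D voxel lists or 3-D grids).
    """
    mask = np.asarray(xp_map) > gamma
    labels, n = ndimage.label(mask)
    keep = np.zeros_like(mask)
    for lab in range(1, n + 1):
        component = labels == lab
        if component.sum() > cluster_size:
            keep |= component
    return keep


def pre_transition_average(
    signal: np.ndarray,
    transition_times: Sequence[float],
    sample_times: Sequence[float],
    tr: float,
    n_pre: int = 5,
) -> np.ndarray:
    """Average a scan series over the samples preceding each transition.

    ``signal`` is a per-scan series; it is read out at the ``n_pre`` sample
    times (e.g. overlap times) before each transition and averaged across
    transitions, yielding the epoch-averaged pre-transition time-course.
    """
    signal = np.asarray(signal, dtype=float)
    sample_times = np.asarray(sample_times, dtype=float)
    segments = []
    for t in transition_times:
        before = sample_times[sample_times < t]
        if before.size < n_pre:
            continue
        sel = before[-n_pre:]
        idx = np.clip(np.round(sel / tr).astype(int), 0, signal.size - 1)
        segments.append(signal[idx])
    if not segments:
        raise DataError("no transition has enough preceding samples")
    return np.mean(segments, axis=0)
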