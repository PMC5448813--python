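"""End-to-end study workflows: dominance simulation and recovery studies.

These functions wire the stages together into reproducible, seeded studies:
the long dominance-duration simulation under purely ambiguous input, and a
synthetic-cohort recovery study (generate -> fit variants -> random-effects
model selection -> recovery metrics).  All randomness flows from one master
seed through documented substreams.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats as sps

from bistablepc.bms import protected_exceedance
from bistablepc.cohort import synth_cohort, transition_frequency
from bistablepc.invert import fit_cohort
from bistablepc.model import AMBIGUOUS, REPLAY, ModelParams, filter_responses
from bistablepc.simulate import (
    duration_stats,
    expected_mean_duration,
    phase_durations,
    simulate_timecourse,
)

DEFAULT_STUDY_CONFIG: dict = {
    "cohort": {
        "n_subjects": 20,
        "runs": 3,
        "pairs_per_run": 8,
        "frequencies": [0.24, 0.30, 0.40],
    },
    "variants": [1, 2, 3, 4],
    "n_starts": 8,
    "bms_samples": 100_000,
}


def run_paper_simulation(
    pi_init: float = 3.5,
    zeta: float = 1.0,
    sampling_rate_hz: float = 0.33,
    total_seconds: float = 6e5,
    seed: int = 0,
    n_seeds: int = 1,
) -> dict:
    """Dominance-duration statistics under purely ambiguous input.

    Simulates the model with the stereodisparity weight suppressed
    (``mu_stereo = 0.5``, ``pi_stereo = 0``) and returns duration statistics
    plus the semi-analytic survival-product expectation.  With ``n_seeds``
    greater than one the durations of several seeded replicates are pooled.
    """
    params = ModelParams(pi_init=pi_init, pi_stereo=0.0, zeta=zeta)
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds)
    durations = []
    for s in seeds:
        sim = simulate_timecourse(
            params, total_seconds, sampling_rate_hz, seed=int(s)
        )
        durations.append(phase_durations(sim.decisions, sim.dt))
    stats = duration_stats(np.concatenate(durations))
    stats["expected_mean"] = expected_mean_duration(params, sampling_rate_hz)
    stats["pi_init"] = pi_init
    stats["sampling_rate_hz"] = sampling_rate_hz
    stats["total_seconds"] = total_seconds
    return stats


def run_recovery_study(
    config: Optional[dict] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    make_figures: bool = False,
) -> dict:
    """Synthetic-cohort recovery study.

    Generates a cohort from the full model, fits all requested variants,
    runs random-effects model selection and computes the recovery metrics:
    the correlation between fitted initial precision and empirical
    transition frequency, the winning model's protected exceedance
    probability, and the per-subject ambiguous-vs-replay mean prediction
    errors.
    """
    cfg = json.loads(json.dumps(DEFAULT_STUDY_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value

    sub_seeds = np.random.SeedSequence(seed).generate_state(3)
    subjects = synth_cohort(
        n_subjects=cfg["cohort"]["n_subjects"],
        frequencies=tuple(cfg["cohort"]["frequencies"]),
        runs=cfg["cohort"]["runs"],
        pairs_per_run=cfg["cohort"]["pairs_per_run"],
        master_seed=int(sub_seeds[0]),
    )
    evidence, fits = fit_cohort(
        subjects,
        variants=tuple(cfg["variants"]),
        n_starts=cfg["n_starts"],
        seed=int(sub_seeds[1]),
    )

    report: dict = {
        "seed": seed,
        "n_subjects": len(subjects),
        "variants": list(cfg["variants"]),
        "evidence": evidence.to_dict(orient="index"),
    }

    if len(subjects) < 2:
        report["bms"] = None
        print("single subject: random-effects model selection skipped")
    else:
        bms_res = protected_exceedance(
            evidence.to_numpy(),
            n_samples=cfg["bms_samples"],
            seed=int(sub_seeds[2]),
        )
        report["bms"] = {
            "expected_freq": bms_res.expected_freq.tolist(),
            "xp": bms_res.xp.tolist(),
            "pxp": bms_res.pxp.tolist(),
            "bor": bms_res.bor,
        }

    full = max(cfg["variants"])
    rows = []
    for s in subjects:
        sf = fits[(s.subject_id, full)]
        if not sf.run_fits:
            continue
        traj = filter_responses(s.responses, s.session, sf.model_params())
        rows.append(
            {
                "subject": s.subject_id,
                "true_pi_init": s.true_params.pi_init,
                "true_pi_stereo": s.true_params.pi_stereo,
                "fit": sf.params_geomean,
                "transition_freq": transition_frequency(s.responses),
                "mean_pe_ambiguous": float(
                    traj.loc[traj["condition"] == AMBIGUOUS, "pe"].mean()
                ),
                "mean_pe_replay": float(
                    traj.loc[traj["condition"] == REPLAY, "pe"].mean()
                ),
            }
        )
    report["subjects"] = rows
    if len(rows) >= 2 and all("pi_init" in r["fit"] for r in rows):
        fit_pi = [r["fit"]["pi_init"] for r in rows]
        tf = [r["transition_freq"] for r in rows]
        if len(rows) >= 3:
            r_val, p_val = sps.pearsonr(fit_pi, tf)
            report["pi_init_transition_corr"] = {"r": float(r_val), "p": float(p_val)}
        true_pi = [r["true_pi_init"] for r in rows]
        report["pi_init_recovery_corr"] = float(
            np.corrcoef(np.log(true_pi), np.log(fit_pi))[0, 1]
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "recovery_report.json").write_text(json.dumps(report, indent=1))
        evidence.to_csv(out_dir / "evidence.tsv", sep="\t")
        if make_figures:
            _recovery_figures(report, out_dir)
    return report


def _pe_ramp(
    design,
    trajectory,
    tr: float,
    n_pre: int = 4,
    bold_delay_s: float = 4.0,
) -> np.ndarray:
    """Epoch-averaged pre-transition course of the PE-modulator response.

    Uses a noiseless voxel carrying only the parametric |PE| regressor,
    sampled with a hemodynamic delay at the overlaps preceding ambiguous
    transitions whose look-back window lies within a single dominance phase
    (so the build-up is not mixed with the previous transition's reset).
    """
    from bistablepc import fmri

    beta = np.array([1.0 if "_x_" in n else 0.0 for n in design.names])
    clean = fmri.simulate_bold(design, beta, noise_sd=0.0, n_voxels=1)
    amb = trajectory[trajectory["condition"] == AMBIGUOUS].sort_values("time_s")
    t = amb["time_s"].to_numpy()
    blk = amb["block"].to_numpy()
    y = amb["y"].to_numpy()
    is_trans = np.concatenate([[False], (blk[1:] == blk[:-1]) & (y[1:] != y[:-1])])
    t_trans = []
    for i in np.flatnonzero(is_trans):
        if i < n_pre or is_trans[i - n_pre : i].any() or blk[i - n_pre] != blk[i]:
            continue
        t_trans.append(t[i])
    return fmri.pre_transition_average(
        clean[0], np.asarray(t_trans), t + bold_delay_s, tr, n_pre=n_pre
    )


def run_fmri_recovery(
    n_subjects: int = 10,
    voxels_per_model: int = 100,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr: float = 2.0,
    epm_samples: int = 5000,
) -> dict:
    """Voxel-wise model recovery on synthetic BOLD.

    For each synthetic subject, builds the three designs (PE, Conventional,
    Block) from a simulated session, generates one voxel population per
    design under its own account (see
    :func:`bistablepc.fmri.default_generating_betas`), computes voxel-wise
    log evidences for all three designs and runs group random-effects
    selection per voxel.  Also returns the epoch-averaged pre-transition
    time-course of a noiseless PE voxel, whose build-up mirrors the
    prediction-error ramp.
    """
    from bistablepc import fmri

    ss = np.random.SeedSequence(seed).generate_state(2 * n_subjects + 1)
    maps = []
    ramp = None
    for s in range(n_subjects):
        session = synth_cohort(
            1, master_seed=int(ss[2 * s]), runs=1, pairs_per_run=8
        )[0]
        traj = filter_responses(
            session.responses, session.session, session.true_params
        )
        designs = {
            kind: fmri.build_design(
                fmri.build_events(session.session, traj, kind), tr=tr
            )
            for kind in fmri.MODEL_KINDS
        }
        pops = []
        for j, kind in enumerate(fmri.MODEL_KINDS):
            dm = designs[kind]
            pops.append(
                fmri.simulate_bold(
                    dm,
                    fmri.default_generating_betas(dm),
                    noise_sd=noise_sd,
                    n_voxels=voxels_per_model,
                    seed=(int(ss[2 * s + 1]) + j) % 2**31,
                )
            )
        Y = np.vstack(pops)
        maps.append(
            np.column_stack(
                [fmri.voxel_evidence(Y, designs[k]) for k in fmri.MODEL_KINDS]
            )
        )
        if ramp is None:
            ramp = _pe_ramp(designs["PE"], traj, tr)
    res = fmri.group_epm(maps, n_samples=epm_samples, seed=int(ss[-1]))
    truth = np.repeat(np.arange(len(fmri.MODEL_KINDS)), voxels_per_model)
    accuracy = float((res["assignment"] == truth).mean())
    return {
        "accuracy": accuracy,
        "assignment": res["assignment"],
        "xp": res["xp"],
        "truth": truth,
        "model_kinds": list(fmri.MODEL_KINDS),
        "pre_transition_ramp": ramp,
    }


def _recovery_figures(report: dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = report["subjects"]
    if not rows:
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    fit_pi = [r["fit"].get("pi_init", float("nan")) for r in rows]
    axes[0].scatter([r["transition_freq"] for r in rows], fit_pi)
    axes[0].set_xlabel("transition frequency (1/s)")
    axes[0].set_ylabel(r"fitted $\pi_{init}$")
    axes[1].scatter(
        [r["mean_pe_replay"] for r in rows],
        [r["mean_pe_ambiguous"] for r in rows],
    )
    lim = max(r["mean_pe_ambiguous"] for r in rows) * 1.1
    axes[1].plot([0, lim], [0, lim], "k--", lw=0.8)
    axes[1].set_xlabel("mean |PE| replay")
    axes[1].set_ylabel("mean |PE| ambiguous")
    fig.tight_layout()
    fig.savefig(out_dir / "recovery.png", dpi=120)
    plt.close(fig)
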