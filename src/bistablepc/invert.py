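"""MAP inversion of the behavioural model variants with Laplace evidence.

Four variants arise from switching the two Gaussian factors on and off:

1. neither stereodisparity nor perceptual stability (chance responding),
2. perceptual stability only,
3. stereodisparity only,
4. both (the full model).

Disabling a factor fixes its precision to zero, which removes the
distribution from the joint prior exactly.  Enabled precisions are given
log-normal priors (``pi_init``: mean log 3, variance 5; ``pi_stereo``: mean
log 5, variance 5) and optimised in log space by multi-start quasi-Newton
(BFGS) minimisation of the negative log joint.  The log model evidence is
approximated at the MAP by the Laplace method; per-run evidences are summed
per subject and parameters are summarised by their geometric mean across
runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from bistablepc.exceptions import ConvergenceError, DataError, InvalidParameterError
from bistablepc.cohort import Session, SyntheticSubject
from bistablepc.model import ModelParams, _prepare_run_arrays, _run_filter


@dataclass(frozen=True)
class VariantSpec:
    """One behavioural model variant."""

    id: int
    use_stereo: bool
    use_stability: bool

    @property
    def free_names(self) -> tuple[str, ...]:
        names = []
        if self.use_stability:
            names.append("pi_init")
        if self.use_stereo:
            names.append("pi_stereo")
        return tuple(names)


VARIANTS: dict[int, VariantSpec] = {
    1: VariantSpec(1, use_stereo=False, use_stability=False),
    2: VariantSpec(2, use_stereo=False, use_stability=True),
    3: VariantSpec(3, use_stereo=True, use_stability=False),
    4: VariantSpec(4, use_stereo=True, use_stability=True),
}


@dataclass(frozen=True)
class PriorSpec:
    """Log-space Gaussian priors over the model parameters."""

    mean_log_pi_init: float = math.log(3.0)
    var_log_pi_init: float = 5.0
    mean_log_pi_stereo: float = math.log(5.0)
    var_log_pi_stereo: float = 5.0
    zeta_free: bool = False
    mean_log_zeta: float = 0.0
    var_log_zeta: float = 1.0

    def moments(self, name: str) -> tuple[float, float]:
        return {
            "pi_init": (self.mean_log_pi_init, self.var_log_pi_init),
            "pi_stereo": (self.mean_log_pi_stereo, self.var_log_pi_stereo),
            "zeta": (self.mean_log_zeta, self.var_log_zeta),
        }[name]


@dataclass
class FitResult:
    """MAP fit of one variant on one run of responses."""

    variant_id: int
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
            name: float(np.exp(v))
            for name, v in zip(self.free_names, self.map_log_params)
        }

    def model_params(self, priors: Optional[PriorSpec] = None) -> ModelParams:
        return params_from_log(
            self.map_log_params, VARIANTS[self.variant_id], priors or PriorSpec()
        )


def free_param_names(variant: VariantSpec, priors: PriorSpec) -> tuple[str, ...]:
    names = list(variant.free_names)
    if priors.zeta_free:
        names.append("zeta")
    return tuple(names)


def params_from_log(
    log_params: Sequence[float], variant: VariantSpec, priors: PriorSpec
) -> ModelParams:
    """Expand a free-parameter vector into full model parameters."""
    names = free_param_names(variant, priors)
    log_params = np.asarray(log_params, dtype=float)
    if log_params.shape != (len(names),):
        raise InvalidParameterError(
            f"expected {len(names)} free parameters {names}, got {log_params.shape}"
        )
    values = dict(zip(names, np.exp(log_params)))
    return ModelParams(
        pi_init=values.get("pi_init", 0.0),
        pi_stereo=values.get("pi_stereo", 0.0),
        zeta=values.get("zeta", 1.0),
    )


def _prepare_session(responses: pd.DataFrame, session: Session) -> list[dict]:
    """Merge responses onto the session timeline, one prepared dict per run."""
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
    prepared = []
    for _run, frame in merged.groupby("run", sort=True):
        p = _prepare_run_arrays(frame.sort_values("time_s"))
        if p is not None:
            prepared.append(p)
    if not prepared:
        raise DataError("no scorable overlaps in any run")
    return prepared


def _data_nll(
    log_params: np.ndarray,
    prepared: list[dict],
    variant: VariantSpec,
    priors: PriorSpec,
) -> float:
    params = params_from_log(log_params, variant, priors)
    nll = 0.0
    for run in prepared:
        loglik, _ = _run_filter(
            params.pi_init,
            params.pi_stereo,
            params.zeta,
            run["y"],
            run["mu_stereo"],
            run["new_block"],
        )
        nll -= sum(l for l, s in zip(loglik, run["scored"]) if s)
    return nll


def _prior_nll(
    log_params: np.ndarray, variant: VariantSpec, priors: PriorSpec
) -> float:
    nll = 0.0
    for name, value in zip(free_param_names(variant, priors), log_params):
        m, v = priors.moments(name)
        nll += 0.5 * (math.log(2 * math.pi * v) + (value - m) ** 2 / v)
    return nll


def neg_log_joint(
    log_params: Sequence[float],
    responses: pd.DataFrame,
    session: Session,
    variant: VariantSpec | int,
    priors: Optional[PriorSpec] = None,
) -> float:
    """Negative log joint of responses and log-parameters under a variant.

    The data term sums Bernoulli log-probabilities of the observed decisions
    at scored overlaps, with predicted probabilities obtained by filtering
    the responses through the model; the prior term evaluates the log-normal
    parameter priors in log space.
    """
    if isinstance(variant, int):
        variant = VARIANTS[variant]
    priors = priors or PriorSpec()
    log_params = np.asarray(log_params, dtype=float)
    if log_params.size and not np.all(np.isfinite(log_params)):
        raise InvalidParameterError("log-parameters must be finite")
    prepared = _prepare_session(responses, session)
    return _data_nll(log_params, prepared, variant, priors) + _prior_nll(
        log_params, variant, priors
    )


def n_scored(prepared: list[dict]) -> int:
    return sum(sum(run["scored"]) for run in prepared)


def _finite_diff_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    d = x.size
    h = np.eye(d) * step
    f0 = fun(x)
    hess = np.empty((d, d))
    for i in range(d):
        hess[i, i] = (fun(x + h[i]) - 2 * f0 + fun(x - h[i])) / step**2
        for j in range(i + 1, d):
            hess[i, j] = hess[j, i] = (
                fun(x + h[i] + h[j])
                - fun(x + h[i] - h[j])
                - fun(x - h[i] + h[j])
                + fun(x - h[i] - h[j])
            ) / (4 * step**2)
    return hess


def _laplace_from_hessian(
    f_map: float, hess: np.ndarray
) -> tuple[float, np.ndarray, bool]:
    """Log evidence, posterior covariance and a nearest-PD flag."""
    d = hess.shape[0]
    if d == 0:
        return -f_map, np.empty((0, 0)), False
    eigval, eigvec = np.linalg.eigh(hess)
    fixed = bool(np.any(eigval <= 0))
    if fixed:
        eigval = np.clip(eigval, 1e-8, None)
        hess = eigvec @ np.diag(eigval) @ eigvec.T
    sign, logdet = np.linalg.slogdet(hess)
    cov = eigvec @ np.diag(1.0 / eigval) @ eigvec.T
    lme = -f_map + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    return lme, cov, fixed


def map_laplace(
    objective,
    prior_means: np.ndarray,
    prior_vars: np.ndarray,
    n_starts: int = 8,
    seed: int = 0,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
):
    """Multi-start BFGS MAP search with Laplace evidence at the optimum.

    Generic over the objective (a negative log joint over log-parameters);
    used by both the predictive-coding variants and the rival dynamical
    models so that their evidences share one approximation.  The first start
    sits at the prior means; the rest are drawn from the priors, clipped to
    +/- 2.5 prior standard deviations.  Returns
    ``(x_map, f_map, log_evidence, cov, hessian_fixed, converged)``.
    """
    means = np.asarray(prior_means, dtype=float)
    sds = np.sqrt(np.asarray(prior_vars, dtype=float))
    rng = np.random.default_rng(seed)
    starts = [means]
    for _ in range(n_starts - 1):
        draw = rng.normal(means, sds)
        starts.append(np.clip(draw, means - 2.5 * sds, means + 2.5 * sds))
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 300}
        )
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
            continue
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError("all optimisation starts failed")

    hess = _finite_diff_hessian(objective, best.x)
    lme, cov, fixed = _laplace_from_hessian(best.fun, hess)
    return best.x, float(best.fun), lme, cov, fixed, any_success


def fit_map(
    responses: pd.DataFrame,
    session: Session,
    variant: VariantSpec | int,
    priors: Optional[PriorSpec] = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Multi-start BFGS minimisation of the negative log joint in log space.

    Deterministic given ``seed``.  Also computes the Laplace log evidence at
    the MAP.
    """
    if isinstance(variant, int):
        variant = VARIANTS[variant]
    priors = priors or PriorSpec()
    if n_starts < 1:
        raise InvalidParameterError("n_starts must be >= 1")
    prepared = _prepare_session(responses, session)
    names = free_param_names(variant, priors)
    d = len(names)

    def objective(x: np.ndarray) -> float:
        return _data_nll(x, prepared, variant, priors) + _prior_nll(
            x, variant, priors
        )

    if d == 0:
        f0 = objective(np.empty(0))
        return FitResult(
            variant_id=variant.id,
            free_names=names,
            map_log_params=np.empty(0),
            posterior_cov=np.empty((0, 0)),
            log_evidence=-f0,
            neg_log_joint=f0,
            n_scored=n_scored(prepared),
            converged=True,
        )

    means = np.array([priors.moments(n)[0] for n in names])
    variances = np.array([priors.moments(n)[1] for n in names])
    x, fun, lme, cov, fixed, success = map_laplace(
        objective, means, variances, n_starts=n_starts, seed=seed
    )
    return FitResult(
        variant_id=variant.id,
        free_names=names,
        map_log_params=x,
        posterior_cov=cov,
        log_evidence=lme,
        neg_log_joint=fun,
        n_scored=n_scored(prepared),
        converged=success,
        hessian_fixed=fixed,
    )


def laplace_evidence(
    fit: FitResult,
    responses: pd.DataFrame,
    session: Session,
    variant: VariantSpec | int,
    priors: Optional[PriorSpec] = None,
) -> float:
    """Laplace log model evidence (nats) at a previously found MAP.

    ``-neg_log_joint(MAP) + d/2 log 2pi - 1/2 log det H`` with a
    finite-difference Hessian; a non-positive-definite Hessian is replaced
    by its nearest positive-definite correction and flagged on the fit.
    """
    if isinstance(variant, int):
        variant = VARIANTS[variant]
    priors = priors or PriorSpec()
    prepared = _prepare_session(responses, session)

    def objective(x: np.ndarray) -> float:
        return _data_nll(x, prepared, variant, priors) + _prior_nll(
            x, variant, priors
        )

    if fit.map_log_params.size == 0:
        return -objective(np.empty(0))
    hess = _finite_diff_hessian(objective, fit.map_log_params)
    lme, cov, fixed = _laplace_from_hessian(
        objective(fit.map_log_params), hess
    )
    fit.posterior_cov = cov
    fit.hessian_fixed = fixed
    return lme


@dataclass
class SubjectFit:
    """Per-run fits of one variant for one subject, with summed evidence."""

    subject_id: int
    variant_id: int
    run_fits: list[FitResult] = field(repr=False, default_factory=list)
    log_evidence: float = 0.0

    @property
    def params_geomean(self) -> dict[str, float]:
        """Geometric mean of fitted parameters across runs."""
        if not self.run_fits:
            return {}
        names = self.run_fits[0].free_names
        logs = np.array([f.map_log_params for f in self.run_fits])
        return {
            name: float(np.exp(v))
            for name, v in zip(names, logs.mean(axis=0))
        }

    def model_params(self, priors: Optional[PriorSpec] = None) -> ModelParams:
        priors = priors or PriorSpec()
        variant = VARIANTS[self.variant_id]
        names = free_param_names(variant, priors)
        logs = np.array([f.map_log_params for f in self.run_fits]).mean(axis=0)
        return params_from_log(logs, variant, priors)


def fit_subject(
    responses: pd.DataFrame,
    session: Session,
    variant: VariantSpec | int,
    priors: Optional[PriorSpec] = None,
    n_starts: int = 8,
    seed: int = 0,
    subject_id: int = 0,
) -> SubjectFit:
    """Fit one variant run by run; evidences sum, parameters geometric-mean."""
    if isinstance(variant, int):
        variant = VARIANTS[variant]
    run_fits = []
    total = 0.0
    for k, run in enumerate(sorted(session.run_ids)):
        sub = session.subset(run)
        resp = responses[responses["run"] == run].reset_index(drop=True)
        fit = fit_map(
            resp, sub, variant, priors, n_starts=n_starts, seed=seed + 1000 * k
        )
        run_fits.append(fit)
        total += fit.log_evidence
    return SubjectFit(subject_id, variant.id, run_fits, total)


def fit_cohort(
    subjects: Sequence[SyntheticSubject],
    variants: Sequence[int] = (1, 2, 3, 4),
    priors: Optional[PriorSpec] = None,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[int, int], SubjectFit]]:
    """Fit every variant to every subject.

    Returns the subjects x models log-evidence matrix and the individual
    :class:`SubjectFit` objects keyed by ``(subject_id, variant_id)``.
    Failures on individual fits are recorded as NaN evidence and the cohort
    continues.
    """
    if len(subjects) < 1:
        raise InvalidParameterError("need at least one subject")
    evidence = pd.DataFrame(
        index=[s.subject_id for s in subjects],
        columns=[f"variant_{v}" for v in variants],
        dtype=float,
    )
    fits: dict[tuple[int, int], SubjectFit] = {}
    for i, subject in enumerate(subjects):
        for variant in variants:
            try:
                sf = fit_subject(
                    subject.responses,
                    subject.session,
                    variant,
                    priors,
                    n_starts=n_starts,
                    seed=seed + 17 * i + variant,
                    subject_id=subject.subject_id,
                )
                evidence.loc[subject.subject_id, f"variant_{variant}"] = (
                    sf.log_evidence
                )
                fits[(subject.subject_id, variant)] = sf
            except (ConvergenceError, DataError) as err:  # pragma: no cover
                evidence.loc[subject.subject_id, f"variant_{variant}"] = np.nan
                fits[(subject.subject_id, variant)] = SubjectFit(
                    subject.subject_id, variant, [], float("nan")
                )
                print(f"subject {subject.subject_id} variant {variant}: {err}")
    return evidence, fits
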