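"""Random-effects Bayesian model selection over a log-evidence matrix.

Subjects are treated as random effects: each subject's responses may be
generated by a different model, with population model frequencies r drawn
from a Dirichlet distribution.  A variational update estimates the Dirichlet
counts alpha; exceedance probabilities (the posterior probability that a
model is the most frequent one) follow by Monte-Carlo sampling of the
Dirichlet posterior.  The "protected" exceedance probability discounts by
the Bayes omnibus risk (BOR), the posterior probability that model
frequencies are all equal, estimated by comparing the free energies of the
random-effects model and the equal-frequency null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from bistablepc.exceptions import InvalidParameterError


@dataclass
class BMSResult:
    """Output of random-effects model selection."""

    alpha: np.ndarray
    expected_freq: np.ndarray
    xp: Optional[np.ndarray] = None
    pxp: Optional[np.ndarray] = None
    bor: Optional[float] = None
    converged: bool = True
    free_energy: float = float("nan")


def _as_matrix(log_evidence) -> np.ndarray:
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise InvalidParameterError("need a subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(L)):
        raise InvalidParameterError("log evidences must be finite")
    return L


def rfx_bms(
    log_evidence,
    alpha0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> BMSResult:
    """Variational Dirichlet update for random-effects model frequencies.

    Iterates the fixed point: posterior assignments
    ``u_nk \\propto exp(L_nk + psi(alpha_k) - psi(sum alpha))`` and counts
    ``alpha = alpha0 + sum_n u_n`` until ``max |delta alpha| < tol``.  Also
    records the variational free energy of the random-effects model, used by
    :func:`protected_exceedance`.
    """
    L = _as_matrix(log_evidence)
    n, k = L.shape
    alpha = np.full(k, float(alpha0))
    u = np.full((n, k), 1.0 / k)
    converged = False
    for _ in range(max_iter):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()
    f1 = _rfx_free_energy(L, alpha, u, alpha0)
    return BMSResult(
        alpha=alpha, expected_freq=expected, converged=converged, free_energy=f1
    )


def _dirichlet_kl(alpha: np.ndarray, alpha0: float) -> float:
    """KL divergence Dir(alpha) || Dir(alpha0 * 1)."""
    a0 = np.full_like(alpha, alpha0)
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        - gammaln(a0.sum())
        + gammaln(a0).sum()
        + ((alpha - a0) * (digamma(alpha) - digamma(alpha.sum()))).sum()
    )


def _rfx_free_energy(
    L: np.ndarray, alpha: np.ndarray, u: np.ndarray, alpha0: float
) -> float:
    """Variational free energy of the random-effects model at the VB solution."""
    elog_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.where(u > 0, u * np.log(u), 0.0).sum()
    return float((u * (L + elog_r)).sum() + entropy - _dirichlet_kl(alpha, alpha0))


def _null_free_energy(L: np.ndarray) -> float:
    """Log evidence of the equal-frequency null: r fixed at 1/K."""
    n, k = L.shape
    return float(logsumexp(L, axis=1).sum() - n * np.log(k))


def exceedance_prob(
    alpha: Sequence[float], n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior.

    The exceedance probability of model k is the posterior probability that
    its population frequency is the largest.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise InvalidParameterError("alpha must be positive")
    rng = np.random.default_rng(seed)
    k = alpha.size
    counts = np.zeros(k)
    chunk = 200_000
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        samples = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(samples, axis=1), minlength=k)
        remaining -= m
    return counts / n_samples


def protected_exceedance(
    log_evidence,
    result: Optional[BMSResult] = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
    alpha0: float = 1.0,
) -> BMSResult:
    """Exceedance probabilities protected by the Bayes omnibus risk.

    ``bor = 1 / (1 + exp(F_rfx - F_null))`` compares the free energy of the
    random-effects model against the equal-frequency null; then
    ``pxp_k = xp_k (1 - bor) + bor / K``.  Returns a completed
    :class:`BMSResult` with ``xp``, ``pxp`` and ``bor`` filled in.
    """
    L = _as_matrix(log_evidence)
    if result is None:
        result = rfx_bms(L, alpha0=alpha0)
    xp = exceedance_prob(result.alpha, n_samples=n_samples, seed=seed)
    f1 = result.free_energy
    f0 = _null_free_energy(L)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    k = L.shape[1]
    result.xp = xp
    result.bor = bor
    result.pxp = xp * (1.0 - bor) + bor / k
    return result
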