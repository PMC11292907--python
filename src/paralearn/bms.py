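"""Random-effects Bayesian model selection over the RW variant family.

Given per-subject approximate log model evidences (by default -BIC/2 from
the maximum-likelihood fits), the population frequencies of the K models
are given a Dirichlet prior and estimated with the standard variational
scheme: subject-wise model responsibilities and Dirichlet concentrations
are updated in turn until the concentrations converge.

Reported quantities:

* expected model frequencies  E[r_k] = alpha_k / sum(alpha)
* exceedance probability      EP_k = P(r_k > r_j for all j) under the
  Dirichlet posterior (analytic Beta comparison when K = 2, Monte-Carlo
  otherwise; an exactly symmetric posterior short-circuits to 1/K)
* Bayes omnibus risk          BOR = posterior probability that all models
  are equally frequent, from the free-energy comparison of the
  random-effects model against the equal-frequency null
* protected exceedance prob.  PXP_k = (1 - BOR) EP_k + BOR / K
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

__all__ = ["BMSResult", "fit_bms", "evidence_from_fits"]


@dataclass
class BMSResult:
    alpha: np.ndarray        # Dirichlet posterior concentrations, (K,)
    expected_freq: np.ndarray
    ep: np.ndarray           # exceedance probabilities
    bor: float               # Bayes omnibus risk
    pxp: np.ndarray          # protected exceedance probabilities
    responsibilities: np.ndarray  # (N, K) posterior model assignments
    model_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        names = self.model_names or tuple(f"M{k}" for k in range(len(self.alpha)))
        return {
            "models": list(names),
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "ep": self.ep.tolist(),
            "bor": self.bor,
            "pxp": self.pxp.tolist(),
        }


def evidence_from_fits(fits_by_model: dict[str, list], criterion: str = "bic") -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack per-subject log evidences from BlockingFit lists.

    ``criterion='bic'`` uses -BIC/2 (the default evidence approximation),
    ``'aic'`` uses -AIC/2.
    """
    names = tuple(fits_by_model)
    cols = []
    for name in names:
        fits = fits_by_model[name]
        vals = [-(f.bic if criterion == "bic" else f.aic) / 2.0 for f in fits]
        cols.append(vals)
    lme = np.array(cols, dtype=float).T
    return lme, names


def _exceedance(alpha: np.ndarray, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    K = alpha.size
    if np.all(alpha == alpha[0]):
        return np.full(K, 1.0 / K)  # symmetric posterior: exact by symmetry
    if K == 2:
        # r1 ~ Beta(a1, a2); EP1 = P(r1 > 1/2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    draws = rng.dirichlet(alpha, size=n_mc)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=K) / n_mc


def fit_bms(
    lme: np.ndarray,
    alpha0: float = 1.0,
    n_mc: int = 100_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    model_names: tuple[str, ...] = (),
) -> BMSResult:
    """Random-effects model selection from an (N subjects x K models) log
    evidence matrix."""
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2 or lme.shape[0] < 2:
        raise ValueError("need a 2-D evidence matrix with >=2 subjects and >=2 models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence matrix contains non-finite entries")
    n, K = lme.shape
    a0 = np.full(K, float(alpha0))

    alpha = a0.copy()
    u = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        logu = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    rng = np.random.default_rng(seed)
    ep = _exceedance(alpha, n_mc, rng)

    # free energy of the random-effects model (variational bound)
    Elogr = digamma(alpha) - digamma(alpha.sum())
    elj = (gammaln(a0.sum()) - gammaln(a0).sum() + ((a0 - 1.0) * Elogr).sum()
           + (u * (Elogr[None, :] + lme)).sum())
    sqf = gammaln(alpha).sum() - gammaln(alpha.sum()) - ((alpha - 1.0) * Elogr).sum()
    sqm = -(u * np.log(u + 1e-300)).sum()
    f1 = elj + sqf + sqm
    # null model: every model equally frequent
    f0 = float((logsumexp(lme, axis=1) - np.log(K)).sum())
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))

    pxp = (1.0 - bor) * ep + bor / K
    return BMSResult(
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        ep=ep,
        bor=bor,
        pxp=pxp,
        responsibilities=u,
        model_names=tuple(model_names),
    )
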