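"""Three-level hierarchical Gaussian filter (HGF) for the 3-deck PRL task.

Each deck j carries a level-2 Gaussian belief (mu2_j, sigma2_j) on the
log-odds of that deck paying out; a single shared level-3 belief
(mu3, sigma3) tracks the log-volatility of the environment. Per trial:

prediction (every deck):
    muhat2_j = mu2_j
    sighat2_j = sigma2_j + exp(kappa * mu3 + omega2)
    muhat1_j = logistic(muhat2_j)          # predicted win probability

update (chosen deck c, binary outcome u in {0, 1}):
    delta1  = u - muhat1_c
    sigma2_c = 1 / (1 / sighat2_c + muhat1_c (1 - muhat1_c))
    mu2_c    = muhat2_c + sigma2_c * delta1
    (unchosen decks keep mu2 and take sigma2 <- sighat2: uncertainty grows)

level 3 (shared):
    sighat3 = sigma3 + exp(omega3)
    v       = exp(kappa mu3 + omega2) / sighat2_c
    delta2  = (sigma2_c + (mu2_c - muhat2_c)^2) / sighat2_c - 1
    pi3     = 1/sighat3 + (kappa^2 / 2) v (v + (2v - 1) delta2)
    mu3    <- mu3 + (kappa / (2 pi3)) v delta2
    sigma3  = 1 / pi3

omega2 is the tonic level-2 log-volatility, omega3 the meta-volatility
learning rate (the rate of change of the volatility belief itself), kappa
the phasic level 2-3 coupling. Any parameter set that drives pi3 or a
variance non-positive is rejected (infinite penalty during fitting).

Choices are modelled with a softmax on the predicted win probabilities,
P(j) proportional to exp(beta * muhat1_j). Fitting is maximum a posteriori
with broad Gaussian priors in unconstrained space (log transforms for
sigma's, kappa and beta); with ``per_block=True`` each 80-trial block is
fitted separately and omega3 reported as the block average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .tasks import PRLSession, WIN_POINTS

__all__ = [
    "HGFParams",
    "HGFTrajectory",
    "HGFFit",
    "HGFPriors",
    "HGFInvalidError",
    "hgf_step",
    "response_probabilities",
    "run_hgf",
    "choice_loglik",
    "fit_hgf",
]


class HGFInvalidError(ValueError):
    """A parameter set produced a non-positive precision or variance."""


@dataclass(frozen=True)
class HGFParams:
    mu0_2: float = 0.0    # initial level-2 mean (all decks)
    sigma0_2: float = 1.0  # initial level-2 variance, > 0
    mu0_3: float = 1.0    # initial volatility belief
    sigma0_3: float = 1.0  # initial level-3 variance, > 0
    kappa: float = 1.0    # level 2-3 coupling (phasic learning rate), > 0
    omega2: float = -3.0  # level-2 tonic log-volatility
    omega3: float = -6.0  # meta-volatility learning rate
    beta: float = 5.0     # response inverse temperature, >= 0

    def __post_init__(self) -> None:
        if self.sigma0_2 <= 0 or self.sigma0_3 <= 0:
            raise ValueError("initial variances must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class HGFState:
    mu2: list[float]
    sigma2: list[float]
    mu3: float
    sigma3: float


def _initial_state(params: HGFParams, n_decks: int = 3) -> HGFState:
    return HGFState(
        mu2=[params.mu0_2] * n_decks,
        sigma2=[params.sigma0_2] * n_decks,
        mu3=params.mu0_3,
        sigma3=params.sigma0_3,
    )


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def hgf_step(state: HGFState, chosen: int, u: int, params: HGFParams):
    """One filter update; returns (new_state, record dict).

    Raises :class:`HGFInvalidError` when the update would produce a
    non-positive variance or level-3 precision.
    """
    n = len(state.mu2)
    if not 0 <= chosen < n:
        raise ValueError(f"chosen deck {chosen} outside 0..{n - 1}")
    if u not in (0, 1):
        raise ValueError(f"binary outcome expected, got {u}")
    kappa, omega2, omega3 = params.kappa, params.omega2, params.omega3

    arg = kappa * state.mu3 + omega2
    if not -700.0 < arg < 700.0 or not math.isfinite(state.mu3):
        raise HGFInvalidError(f"volatility exponent diverged (kappa*mu3+omega2={arg})")
    vol = math.exp(arg)
    sighat2 = [s + vol for s in state.sigma2]
    muhat1 = [_logistic(m) for m in state.mu2]
    if any(s <= 0 for s in sighat2):
        raise HGFInvalidError("non-positive predicted level-2 variance")

    c = chosen
    try:
        return _step_inner(state, c, u, muhat1, sighat2, vol, kappa, omega3)
    except OverflowError as e:  # float overflow == diverged trajectory
        raise HGFInvalidError(f"trajectory diverged: {e}") from e


def _step_inner(state, c, u, muhat1, sighat2, vol, kappa, omega3):
    delta1 = u - muhat1[c]
    prec1 = muhat1[c] * (1.0 - muhat1[c])
    sigma2_c = 1.0 / (1.0 / sighat2[c] + prec1)
    mu2_c = state.mu2[c] + sigma2_c * delta1

    mu2 = list(state.mu2)
    sigma2 = list(sighat2)
    mu2[c] = mu2_c
    sigma2[c] = sigma2_c

    sighat3 = state.sigma3 + math.exp(omega3)
    v = vol / sighat2[c]
    delta2 = (sigma2_c + (mu2_c - state.mu2[c]) ** 2) / sighat2[c] - 1.0
    if not (math.isfinite(mu2_c) and math.isfinite(delta2)):
        raise HGFInvalidError("level-2 update diverged")
    pi3 = 1.0 / sighat3 + (kappa**2 / 2.0) * v * (v + (2.0 * v - 1.0) * delta2)
    if pi3 <= 0:
        raise HGFInvalidError(f"non-positive level-3 precision pi3={pi3}")
    mu3 = state.mu3 + (kappa / (2.0 * pi3)) * v * delta2
    sigma3 = 1.0 / pi3

    record = {
        "muhat1": muhat1,
        "delta1": delta1,
        "delta2": delta2,
        "sighat2": sighat2,
    }
    return HGFState(mu2=mu2, sigma2=sigma2, mu3=mu3, sigma3=sigma3), record


def response_probabilities(state: HGFState, beta: float) -> np.ndarray:
    """Softmax choice probabilities over the decks' predicted win rates."""
    muhat1 = np.array([_logistic(m) for m in state.mu2])
    z = beta * muhat1
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class HGFTrajectory:
    """Per-trial beliefs and choice probabilities from one filter pass."""

    muhat1: np.ndarray      # (n, decks) predicted win probability
    mu2: np.ndarray         # (n, decks) post-update level-2 mean
    sigma2: np.ndarray      # (n, decks) post-update level-2 variance
    mu3: np.ndarray         # (n,)
    sigma3: np.ndarray      # (n,)
    delta1: np.ndarray      # (n,)
    delta2: np.ndarray      # (n,)
    choice_probs: np.ndarray  # (n, decks), from the pre-update state
    loglik: float           # sum log P(realized choice)


def run_hgf(choices, us, params: HGFParams, n_decks: int = 3) -> HGFTrajectory:
    """Filter a full choice/outcome sequence (u = 1 win, 0 loss)."""
    choices = np.asarray(choices, dtype=int)
    us = np.asarray(us, dtype=int)
    n = choices.size
    state = _initial_state(params, n_decks)
    muhat1 = np.empty((n, n_decks))
    mu2 = np.empty((n, n_decks))
    sigma2 = np.empty((n, n_decks))
    mu3 = np.empty(n)
    sigma3 = np.empty(n)
    d1 = np.empty(n)
    d2 = np.empty(n)
    probs = np.empty((n, n_decks))
    ll = 0.0
    for t in range(n):
        # log-softmax directly: stable for large beta
        z = params.beta * np.array([_logistic(m) for m in state.mu2])
        z -= z.max()
        lse = math.log(np.exp(z).sum())
        probs[t] = np.exp(z - lse)
        ll += float(z[choices[t]]) - lse
        state, rec = hgf_step(state, int(choices[t]), int(us[t]), params)
        muhat1[t] = rec["muhat1"]
        mu2[t] = state.mu2
        sigma2[t] = state.sigma2
        mu3[t] = state.mu3
        sigma3[t] = state.sigma3
        d1[t] = rec["delta1"]
        d2[t] = rec["delta2"]
    return HGFTrajectory(muhat1, mu2, sigma2, mu3, sigma3, d1, d2, probs, ll)


def outcomes_to_u(outcomes) -> np.ndarray:
    """Map point outcomes (+100 / -50) to the binary win indicator."""
    return (np.asarray(outcomes) == WIN_POINTS).astype(int)


def choice_loglik(choices, us, params: HGFParams, n_decks: int = 3) -> float:
    """Sum of log softmax probabilities of the realized choices."""
    return run_hgf(choices, us, params, n_decks).loglik


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

#: parameters estimated by default; the remaining fields are pinned at their
#: HGFParams defaults (they are weakly identified from 160 binary trials)
DEFAULT_FIT_FIELDS = ("mu0_2", "kappa", "omega2", "omega3", "beta")

_LOG_FIELDS = {"sigma0_2", "sigma0_3", "kappa", "beta"}


@dataclass(frozen=True)
class HGFPriors:
    """Gaussian priors in unconstrained space (log scale for positives)."""

    mean: dict = field(default_factory=lambda: {
        "mu0_2": 0.0, "sigma0_2": 0.0, "mu0_3": 1.0, "sigma0_3": 0.0,
        "kappa": 0.0, "omega2": -3.0, "omega3": -6.0, "beta": math.log(5.0),
    })
    var: dict = field(default_factory=lambda: {
        "mu0_2": 4.0, "sigma0_2": 4.0, "mu0_3": 4.0, "sigma0_3": 4.0,
        "kappa": 4.0, "omega2": 4.0, "omega3": 4.0, "beta": 4.0,
    })


def _to_constrained(field_name: str, x: float) -> float:
    return math.exp(x) if field_name in _LOG_FIELDS else x


@dataclass
class HGFFit:
    params: HGFParams
    log_joint: float
    loglik: float
    omega3: float              # block-averaged when per_block
    omega3_blocks: tuple[float, ...]
    converged: bool
    n_starts: int
    block_fits: tuple["HGFFit", ...] = ()

    def to_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k) for k in (
                "mu0_2", "sigma0_2", "mu0_3", "sigma0_3",
                "kappa", "omega2", "omega3", "beta")},
            "log_joint": self.log_joint,
            "loglik": self.loglik,
            "omega3": self.omega3,
            "omega3_blocks": list(self.omega3_blocks),
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


_PENALTY = 1e10


def _fit_segment(choices, us, priors: HGFPriors, fit_fields, n_starts, rng,
                 n_decks=3) -> HGFFit:
    base = HGFParams()
    mu = np.array([priors.mean[f] for f in fit_fields])
    var = np.array([priors.var[f] for f in fit_fields])

    def make_params(x) -> HGFParams:
        kw = {f: _to_constrained(f, xi) for f, xi in zip(fit_fields, x)}
        return replace(base, **kw)

    def neg_log_joint(x):
        try:
            params = make_params(x)
            ll = choice_loglik(choices, us, params, n_decks)
        except (HGFInvalidError, OverflowError):
            return _PENALTY
        prior = -0.5 * np.sum((x - mu) ** 2 / var + np.log(2 * np.pi * var))
        return -(ll + prior)

    best = None
    converged = False
    for k in range(n_starts):
        x0 = mu if k == 0 else mu + rng.normal(scale=np.sqrt(var) / 2.0, size=mu.size)
        res = minimize(neg_log_joint, x0, method="L-BFGS-B")
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    if best is None:
        raise HGFInvalidError(
            "all starts rejected: every sampled parameter set produced an "
            "invalid trajectory (non-positive variance or precision)")
    params = make_params(best.x)
    ll = choice_loglik(choices, us, params, n_decks)
    return HGFFit(
        params=params,
        log_joint=-float(best.fun),
        loglik=ll,
        omega3=params.omega3,
        omega3_blocks=(params.omega3,),
        converged=converged,
        n_starts=n_starts,
    )


def fit_hgf(
    session: PRLSession,
    priors: HGFPriors | None = None,
    per_block: bool = False,
    fit_fields: tuple[str, ...] = DEFAULT_FIT_FIELDS,
    n_starts: int = 6,
    seed: int = 0,
) -> HGFFit:
    """MAP-fit the filter to a completed PRL session.

    With ``per_block=True`` each block is fitted separately and the reported
    ``omega3`` is the arithmetic mean of the per-block estimates; the
    returned params are those of the full-session fit structure's first
    block otherwise.
    """
    if not session.completed:
        raise ValueError("session has no choices; play it first")
    if priors is None:
        priors = HGFPriors()
    rng = np.random.default_rng(seed)
    choices = session.choices
    us = outcomes_to_u(session.outcomes)
    n_decks = session.n_decks
    if not per_block:
        return _fit_segment(choices, us, priors, fit_fields, n_starts, rng, n_decks)
    per = session.trials_per_block
    block_fits = []
    for b in range(session.n_blocks):
        sl = slice(b * per, (b + 1) * per)
        block_fits.append(
            _fit_segment(choices[sl], us[sl], priors, fit_fields, n_starts, rng, n_decks)
        )
    omega3_blocks = tuple(f.params.omega3 for f in block_fits)
    lead = block_fits[0]
    return HGFFit(
        params=lead.params,
        log_joint=sum(f.log_joint for f in block_fits),
        loglik=sum(f.loglik for f in block_fits),
        omega3=float(np.mean(omega3_blocks)),
        omega3_blocks=omega3_blocks,
        converged=all(f.converged for f in block_fits),
        n_starts=n_starts,
        block_fits=tuple(block_fits),
    )
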