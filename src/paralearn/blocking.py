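"""Rescorla-Wagner model family for the Kamin blocking task.

The learner keeps one associative weight per cue (elemental representation)
and responds with a prediction r-hat in [-1, 1]:

* single cue:   r = w_cue
* compound:     r = clip(w_p + gamma * w_s, -1, 1), where the primary cue p
  is the one with the larger current weight (ties broken by cue-label
  order). gamma = 1 recovers additive integration, gamma = 0 maximum-only.

After feedback o in {+1, -1} both present cues update with a single static
learning rate alpha, but the error is attributed per cue rather than summed:

* single / primary:  w <- w + alpha * (o - w)
* secondary:         w <- w + alpha * (lam * o - w)

lam sets the secondary cue's learning asymptote: lam = 0 gives classical
blocking (the redundant cue is never updated toward the outcome), lam = 1
drives it fully toward the outcome (unselective learning), and lam < 0
implements counterfactual inference ("A causes it, therefore B prevents
it"). On the first trial of a new phase all weights are multiplied by the
retention parameter eta (eta = 1 keeps them, eta = 0 wipes them).

Responses are fitted by maximum likelihood under a Gaussian centred on
r-hat whose variance is profiled from the residuals (variant RW1 instead
frees the noise SD sigma). Five variants nest inside RW2 (alpha, gamma,
lam, eta): RW1 adds free sigma, RW3 drops forgetting, RW4/RW5 fix the
integration rule at its additive / maximum-only endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .tasks import BlockingTrial, first_probe_index

__all__ = [
    "RWParams",
    "WeightState",
    "ModelVariant",
    "BlockingFit",
    "VARIANTS",
    "SIGMA2_FLOOR",
    "predict_response",
    "update_weights",
    "apply_phase_decay",
    "run_model",
    "log_likelihood",
    "fit_participant",
]

#: lower bound on the profiled residual variance, keeping the likelihood
#: finite on perfect fits
SIGMA2_FLOOR = 1e-6

#: metadata attached to every fit: the retention convention for eta. Under
#: the convention used here eta is the fraction of each weight RETAINED at a
#: phase change; some treatments quote the complementary decay 1 - eta, so
#: the convention travels with the numbers.
ETA_CONVENTION = "retention: eta=1 keeps weights, eta=0 clears them; decay = 1 - eta"


@dataclass(frozen=True)
class RWParams:
    """Parameters of the blocking model; bounds checked at construction."""

    alpha: float  # learning rate, [0, 1]
    gamma: float  # cue-integration weight, [0, 1] (1 additive, 0 max-only)
    lam: float    # secondary-cue learning asymptote, [-1, 1]
    eta: float = 1.0   # phase retention multiplier, [0, 1]
    sigma: float | None = None  # free response-noise SD (RW1 only)

    def __post_init__(self) -> None:
        for name, val, lo, hi in (
            ("alpha", self.alpha, 0.0, 1.0),
            ("gamma", self.gamma, 0.0, 1.0),
            ("lam", self.lam, -1.0, 1.0),
            ("eta", self.eta, 0.0, 1.0),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError(f"sigma={self.sigma} must be > 0")


@dataclass
class WeightState:
    """Cue -> associative weight map; unseen cues read as 0."""

    weights: dict[str, float] = field(default_factory=dict)

    def get(self, cue: str) -> float:
        return self.weights.get(cue, 0.0)

    def copy(self) -> "WeightState":
        return WeightState(dict(self.weights))


@dataclass(frozen=True)
class ModelVariant:
    name: str
    has_free_sigma: bool
    has_forgetting: bool
    integration: str  # flexible | additive_fixed | max_fixed

    @property
    def free_params(self) -> tuple[str, ...]:
        names = ["alpha"]
        if self.integration == "flexible":
            names.append("gamma")
        names.append("lam")
        if self.has_forgetting:
            names.append("eta")
        if self.has_free_sigma:
            names.append("sigma")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.free_params)

    def fixed_gamma(self) -> float | None:
        if self.integration == "additive_fixed":
            return 1.0
        if self.integration == "max_fixed":
            return 0.0
        return None


#: The model family. Which of RW4/RW5 is the additive vs maximum-only
#: endpoint is a labelling choice; swap here if a different convention is
#: needed.
VARIANTS: dict[str, ModelVariant] = {
    "RW1": ModelVariant("RW1", has_free_sigma=True, has_forgetting=True, integration="flexible"),
    "RW2": ModelVariant("RW2", has_free_sigma=False, has_forgetting=True, integration="flexible"),
    "RW3": ModelVariant("RW3", has_free_sigma=False, has_forgetting=False, integration="flexible"),
    "RW4": ModelVariant("RW4", has_free_sigma=False, has_forgetting=True, integration="additive_fixed"),
    "RW5": ModelVariant("RW5", has_free_sigma=False, has_forgetting=True, integration="max_fixed"),
}

_BOUNDS = {
    "alpha": (0.0, 1.0),
    "gamma": (0.0, 1.0),
    "lam": (-1.0, 1.0),
    "eta": (0.0, 1.0),
    "sigma": (1e-3, 2.0),
}


def _clip1(x: float) -> float:
    return -1.0 if x < -1.0 else (1.0 if x > 1.0 else x)


def _split_compound(state: WeightState, cues: tuple[str, ...]) -> tuple[str, str]:
    """Primary (larger weight; label order on ties) and secondary cue."""
    a, b = sorted(cues)
    return (b, a) if state.get(b) > state.get(a) else (a, b)


def predict_response(state: WeightState, cues, gamma: float) -> float:
    """Model response r-hat in [-1, 1] for a single cue or a 2-cue compound."""
    cues = tuple(cues)
    if len(cues) == 1:
        return state.get(cues[0])
    if len(cues) != 2:
        raise ValueError(f"a trial presents 1 or 2 cues, got {cues!r}")
    p, s = _split_compound(state, cues)
    return _clip1(state.get(p) + gamma * state.get(s))


def update_weights(state: WeightState, cues, outcome: int, params: RWParams) -> WeightState:
    """One feedback update; returns a new state, absent cues untouched."""
    if outcome not in (1, -1):
        raise ValueError(f"outcome must be +1 or -1, got {outcome}")
    cues = tuple(cues)
    new = state.copy()
    if len(cues) == 1:
        c = cues[0]
        new.weights[c] = _clip1(new.get(c) + params.alpha * (outcome - new.get(c)))
    elif len(cues) == 2:
        p, s = _split_compound(state, cues)
        new.weights[p] = _clip1(new.get(p) + params.alpha * (outcome - new.get(p)))
        new.weights[s] = _clip1(new.get(s) + params.alpha * (params.lam * outcome - new.get(s)))
    else:
        raise ValueError(f"a trial presents 1 or 2 cues, got {cues!r}")
    return new


def apply_phase_decay(state: WeightState, eta: float) -> WeightState:
    """Multiply every weight by the retention eta (phase-boundary forgetting)."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta={eta} outside [0, 1]")
    return WeightState({c: w * eta for c, w in state.weights.items()})


# ---------------------------------------------------------------------------
# Trial-stream compilation and the fast trajectory kernel
# ---------------------------------------------------------------------------


class CompiledTrials:
    """Array view of a trial stream for repeated trajectory evaluation.

    Cue pairs are stored label-sorted so that on tied weights the kernel's
    "first index is primary" rule reproduces the label-order tie-break.
    """

    def __init__(self, trials: list[BlockingTrial]):
        self.trials = list(trials)
        labels = sorted({c for t in trials for c in t.cues})
        self.cue_labels = labels
        idx = {c: i for i, c in enumerate(labels)}
        n = len(trials)
        self.cue1 = np.empty(n, dtype=np.int64)
        self.cue2 = np.empty(n, dtype=np.int64)
        self.outcome = np.empty(n, dtype=np.float64)
        self.decay = np.zeros(n, dtype=np.bool_)
        self.feedback = np.zeros(n, dtype=np.bool_)
        for t, tr in enumerate(trials):
            cues = sorted(tr.cues)
            self.cue1[t] = idx[cues[0]]
            self.cue2[t] = idx[cues[1]] if len(cues) == 2 else -1
            self.outcome[t] = float(tr.outcome)
            self.decay[t] = tr.is_first_of_phase
            self.feedback[t] = tr.gives_feedback
        self.n_cues = len(labels)


def _trajectory_py(cue1, cue2, outcome, decay, feedback, n_cues,
                   alpha, gamma, lam, eta, apply_decay):
    w = np.zeros(n_cues)
    preds = np.empty(cue1.shape[0])
    for t in range(cue1.shape[0]):
        if apply_decay and decay[t]:
            for j in range(n_cues):
                w[j] *= eta
        i1 = cue1[t]
        i2 = cue2[t]
        if i2 < 0:
            r = w[i1]
            preds[t] = r
            if feedback[t]:
                w[i1] += alpha * (outcome[t] - w[i1])
                if w[i1] > 1.0:
                    w[i1] = 1.0
                elif w[i1] < -1.0:
                    w[i1] = -1.0
        else:
            if w[i2] > w[i1]:
                p, s = i2, i1
            else:
                p, s = i1, i2
            r = w[p] + gamma * w[s]
            if r > 1.0:
                r = 1.0
            elif r < -1.0:
                r = -1.0
            preds[t] = r
            if feedback[t]:
                o = outcome[t]
                w[p] += alpha * (o - w[p])
                w[s] += alpha * (lam * o - w[s])
                for j in (p, s):
                    if w[j] > 1.0:
                        w[j] = 1.0
                    elif w[j] < -1.0:
                        w[j] = -1.0
    return preds, w


try:  # optional JIT: same kernel, ~100x faster when numba is present
    from numba import njit

    _trajectory_jit = njit(cache=True)(_trajectory_py)
except Exception:  # pragma: no cover - numba absent or broken
    _trajectory_jit = None


def _trajectory(compiled: CompiledTrials, alpha, gamma, lam, eta, apply_decay):
    fn = _trajectory_jit if _trajectory_jit is not None else _trajectory_py
    return fn(compiled.cue1, compiled.cue2, compiled.outcome, compiled.decay,
              compiled.feedback, compiled.n_cues,
              float(alpha), float(gamma), float(lam), float(eta), bool(apply_decay))


@dataclass
class ModelTrajectory:
    predictions: np.ndarray
    final_state: WeightState


def run_model(trials, params: RWParams, variant: ModelVariant | str = "RW2") -> ModelTrajectory:
    """Run the learner over a trial stream, returning per-trial predictions.

    The response is generated before feedback; weights update only on
    feedback trials; the phase-boundary decay applies iff the variant has
    forgetting.
    """
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    if variant.has_free_sigma and params.sigma is None:
        raise ValueError(f"variant {variant.name} requires a free sigma")
    gamma = variant.fixed_gamma()
    gamma = params.gamma if gamma is None else gamma
    compiled = trials if isinstance(trials, CompiledTrials) else CompiledTrials(trials)
    preds, w = _trajectory(compiled, params.alpha, gamma, params.lam, params.eta,
                           variant.has_forgetting)
    state = WeightState({c: w[i] for i, c in enumerate(compiled.cue_labels)})
    return ModelTrajectory(predictions=preds, final_state=state)


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------


def log_likelihood(responses, predictions, variant: ModelVariant | str = "RW2",
                   sigma: float | None = None) -> float:
    """Gaussian log-likelihood of responses around the model predictions.

    For profiled-noise variants the variance is the mean squared residual,
    floored at ``SIGMA2_FLOOR``; at the profile optimum this reduces to
    -n/2 (log(2 pi s2) + 1). RW1 evaluates at its free sigma instead.
    """
    responses = np.asarray(responses, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if responses.shape != predictions.shape or responses.size == 0:
        raise ValueError("responses and predictions must be equal-length and non-empty")
    n = responses.size
    msr = float(np.mean((responses - predictions) ** 2))
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    if variant.has_free_sigma:
        if sigma is None or sigma <= 0:
            raise ValueError(f"variant {variant.name} needs sigma > 0")
        return -0.5 * n * (math.log(2 * math.pi * sigma**2) + msr / sigma**2)
    s2 = max(msr, SIGMA2_FLOOR)
    return -0.5 * n * (math.log(2 * math.pi * s2) + msr / s2)


@dataclass
class BlockingFit:
    """Result of fitting one participant's blocking responses."""

    variant: str
    params: RWParams
    loglik: float
    sigma_hat: float
    n_params: int
    n_trials: int
    aic: float
    bic: float
    n_starts: int
    converged: bool
    model_blocking_score: float | None
    model_control_score: float | None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "params": {k: getattr(self.params, k) for k in
                       ("alpha", "gamma", "lam", "eta", "sigma")},
            "loglik": self.loglik,
            "sigma_hat": self.sigma_hat,
            "n_params": self.n_params,
            "n_trials": self.n_trials,
            "aic": self.aic,
            "bic": self.bic,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "model_blocking_score": self.model_blocking_score,
            "model_control_score": self.model_control_score,
            "metadata": self.metadata,
        }
        return d


def _params_from_vector(x, variant: ModelVariant) -> RWParams:
    vals = dict(zip(variant.free_params, x))
    gamma = variant.fixed_gamma()
    return RWParams(
        alpha=vals["alpha"],
        gamma=vals.get("gamma", gamma if gamma is not None else 1.0),
        lam=vals["lam"],
        eta=vals.get("eta", 1.0),
        sigma=vals.get("sigma"),
    )


def fit_participant(
    trials,
    responses,
    variant: ModelVariant | str = "RW2",
    n_starts: int = 25,
    seed: int = 0,
    blocking_category: str | None = "block_confirm",
    control_category: str | None = "block_control",
) -> BlockingFit:
    """Multi-start bounded maximum-likelihood fit of one participant.

    Starting points are drawn uniformly within the parameter bounds from a
    seeded generator; the best of ``n_starts`` L-BFGS-B runs is returned.
    Model blocking / control scores are the fitted model's responses at the
    first phase-3 probe of the score-bearing categories (``None`` when the
    design lacks them).
    """
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    responses = np.asarray(responses, dtype=float)
    compiled = trials if isinstance(trials, CompiledTrials) else CompiledTrials(trials)
    n = len(compiled.trials)
    if responses.shape != (n,):
        raise ValueError(f"need {n} responses aligned to trials, got {responses.shape}")
    if np.any(np.abs(responses) > 1.0):
        bad = int(np.argmax(np.abs(responses) > 1.0))
        raise ValueError(f"response at trial {bad} outside [-1, 1]: {responses[bad]}")

    names = variant.free_params
    bounds = [_BOUNDS[p] for p in names]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    apply_decay = variant.has_forgetting
    fixed_gamma = variant.fixed_gamma()

    def unpack(x):
        vals = dict(zip(names, x))
        gamma = vals.get("gamma", fixed_gamma if fixed_gamma is not None else 1.0)
        return vals["alpha"], gamma, vals["lam"], vals.get("eta", 1.0), vals.get("sigma")

    def neg_ll(x):
        alpha, gamma, lam, eta, sigma = unpack(x)
        preds, _ = _trajectory(compiled, alpha, gamma, lam, eta, apply_decay)
        msr = float(np.mean((responses - preds) ** 2))
        if variant.has_free_sigma:
            return 0.5 * n * (math.log(2 * math.pi * sigma**2) + msr / sigma**2)
        s2 = max(msr, SIGMA2_FLOOR)
        return 0.5 * n * (math.log(2 * math.pi * s2) + msr / s2)

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for _ in range(n_starts):
        x0 = rng.uniform(lo, hi)
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    params = _params_from_vector(best.x, variant)
    loglik = -float(best.fun)
    alpha, gamma, lam, eta, sigma = unpack(best.x)
    preds, _ = _trajectory(compiled, alpha, gamma, lam, eta, apply_decay)
    msr = float(np.mean((responses - preds) ** 2))
    sigma_hat = float(sigma) if variant.has_free_sigma else math.sqrt(max(msr, SIGMA2_FLOOR))

    def _probe_score(category):
        if category is None:
            return None
        try:
            i = first_probe_index(compiled.trials, category)
        except ValueError:
            return None
        return float(preds[i])

    k = variant.n_params
    return BlockingFit(
        variant=variant.name,
        params=params,
        loglik=loglik,
        sigma_hat=sigma_hat,
        n_params=k,
        n_trials=n,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        n_starts=n_starts,
        converged=converged,
        model_blocking_score=_probe_score(blocking_category),
        model_control_score=_probe_score(control_category),
        metadata={"eta_convention": ETA_CONVENTION, "seed": seed},
    )
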