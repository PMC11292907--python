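"""Synthetic cohorts with the statistical structure the analysis assumes.

A default cohort is a large transdiagnostic sample: 452 participants split into clinical
high-risk (181), help-seeking control (161) and healthy control (110)
phenotypes, of whom 65 are high-paranoia and 113 high in non-paranoid
delusion-like belief conviction (high PDI-C); the paranoia and PDI-C
labels overlap with positive dependence. Phenotype carries no parameter
offset by default (group effects track symptoms, not phenotypes).

Latent parameters are drawn as Gaussians on transformed scales (logit for
[0,1]-bounded, atanh for the [-1,1] asymptote lam, log for positives) with
group-dependent means:

* high paranoia: lower learning rate alpha, lower phase retention eta,
  a higher meta-volatility rate omega3 (offset sign configurable) and a
  lower choice inverse temperature beta (noisier, switch-prone play);
* high PDI-C: higher secondary-cue asymptote lam (less counterfactual,
  more unselective compound updating).

Default offsets are sized so the behavioural group contrasts (blocked- and
control-cue responses) land in the |d| ~ 0.3-0.5 band. Each participant
then produces a full blocking trial table (model response plus truncated
Gaussian noise, clipped to [-1, 1]) and a completed PRL session played by
their own HGF agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .blocking import RWParams, run_model
from .hgf import (
    HGFInvalidError,
    HGFParams,
    HGFState,
    _initial_state,
    hgf_step,
    response_probabilities,
)
from .tasks import (
    BlockingDesign,
    BlockingTrial,
    PRLSession,
    build_blocking_design,
    build_prl_session,
    emit_trials,
    play_prl,
)

__all__ = [
    "CohortSpec",
    "SyntheticParticipant",
    "sample_cohort",
    "simulate_blocking_responses",
    "simulate_prl_choices",
]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GroupEffects:
    """Latent-scale means/SDs and group offsets for parameter draws."""

    # blocking-model latents (logit scale unless noted)
    alpha_mean: float = _logit(0.30)
    alpha_sd: float = 0.6
    alpha_paranoia_offset: float = -0.45    # lower learning rate
    gamma_mean: float = 0.0
    gamma_sd: float = 0.8
    lam_mean: float = -0.25                 # atanh scale: mild counterfactual bias
    lam_sd: float = 0.45
    lam_pdic_offset: float = 0.22           # unselective updating in high PDI-C
    eta_mean: float = _logit(0.88)
    eta_sd: float = 0.5
    eta_paranoia_offset: float = -0.45      # lower retention (more forgetting)
    # HGF latents: a strongly coupled, highly volatile regime (the task is
    # volatile from the start); omega3 is the individual-difference
    # parameter of interest and carries the widest population spread
    mu0_2_mean: float = 0.0
    mu0_2_sd: float = 0.2
    kappa_log_mean: float = float(np.log(1.8))
    kappa_log_sd: float = 0.15
    omega2_mean: float = -4.0
    omega2_sd: float = 0.5
    omega3_mean: float = -3.5
    omega3_sd: float = 1.5
    omega3_paranoia_offset: float = 1.0     # sign configurable (see docs)
    beta_log_mean: float = float(np.log(16.0))
    beta_log_sd: float = 0.3
    beta_log_paranoia_offset: float = -0.25  # noisier play in high paranoia


@dataclass(frozen=True)
class CohortSpec:
    n_total: int = 452
    n_chr: int = 181
    n_hsc: int = 161
    n_hc: int = 110
    n_high_paranoia: int = 65
    n_high_pdic: int = 113
    #: odds ratio of high PDI-C given high paranoia (label overlap)
    paranoia_pdic_odds_ratio: float = 1.5
    blocking_noise_sd: float = 0.2
    effects: GroupEffects = field(default_factory=GroupEffects)
    reps_per_phase: tuple[int, int, int] = (10, 6, 6)

    def __post_init__(self) -> None:
        if self.n_chr + self.n_hsc + self.n_hc != self.n_total:
            raise ValueError("phenotype counts must sum to n_total")
        if not 0 <= self.n_high_paranoia <= self.n_total:
            raise ValueError("infeasible paranoia count")
        if not 0 <= self.n_high_pdic <= self.n_total:
            raise ValueError("infeasible PDI-C count")


@dataclass
class SyntheticParticipant:
    id: str
    phenotype: str                 # CHR | HSC | HC
    high_paranoia: bool
    high_pdic: bool
    rw: RWParams
    hgf: HGFParams
    design: BlockingDesign
    blocking_trials: list[BlockingTrial]
    blocking_responses: np.ndarray | None = None
    prl: PRLSession | None = None


def _draw_params(spec: CohortSpec, high_par: bool, high_pdic: bool,
                 rng: np.random.Generator) -> tuple[RWParams, HGFParams]:
    e = spec.effects
    a_mu = e.alpha_mean + (e.alpha_paranoia_offset if high_par else 0.0)
    eta_mu = e.eta_mean + (e.eta_paranoia_offset if high_par else 0.0)
    lam_mu = e.lam_mean + (e.lam_pdic_offset if high_pdic else 0.0)
    rw = RWParams(
        alpha=float(_expit(rng.normal(a_mu, e.alpha_sd))),
        gamma=float(_expit(rng.normal(e.gamma_mean, e.gamma_sd))),
        lam=float(np.tanh(rng.normal(lam_mu, e.lam_sd))),
        eta=float(_expit(rng.normal(eta_mu, e.eta_sd))),
    )
    o3_mu = e.omega3_mean + (e.omega3_paranoia_offset if high_par else 0.0)
    b_mu = e.beta_log_mean + (e.beta_log_paranoia_offset if high_par else 0.0)
    hgf = HGFParams(
        mu0_2=float(rng.normal(e.mu0_2_mean, e.mu0_2_sd)),
        kappa=float(np.exp(rng.normal(e.kappa_log_mean, e.kappa_log_sd))),
        omega2=float(rng.normal(e.omega2_mean, e.omega2_sd)),
        omega3=float(rng.normal(o3_mu, e.omega3_sd)),
        beta=float(np.exp(rng.normal(b_mu, e.beta_log_sd))),
    )
    return rw, hgf


def simulate_blocking_responses(participant: SyntheticParticipant,
                                noise_sd: float, seed: int) -> np.ndarray:
    """Model prediction plus truncated Gaussian noise, clipped to [-1, 1]."""
    traj = run_model(participant.blocking_trials, participant.rw, "RW2")
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        resp = traj.predictions + rng.normal(0.0, noise_sd, traj.predictions.size)
    else:
        resp = traj.predictions.copy()
    return np.clip(resp, -1.0, 1.0)


def simulate_prl_choices(participant: SyntheticParticipant, seed: int,
                         session: PRLSession | None = None) -> PRLSession:
    """Play a PRL session with the participant's own HGF agent.

    The agent filters its observed choice/outcome history online and samples
    each choice from its softmax response probabilities.
    """
    if session is None:
        session = build_prl_session(seed=seed)
    params = participant.hgf
    rng = np.random.default_rng(seed + 1)
    state_box: list[HGFState] = [_initial_state(params, session.n_decks)]
    seen: list[int] = [0]  # trials already absorbed into the filter

    def agent(t, choices, outcomes):
        while seen[0] < len(choices):
            i = seen[0]
            u = 1 if outcomes[i] > 0 else 0
            state_box[0], _ = hgf_step(state_box[0], choices[i], u, params)
            seen[0] += 1
        p = response_probabilities(state_box[0], params.beta)
        return int(rng.choice(len(p), p=p))

    return play_prl(session, agent, seed=seed)


def sample_cohort(spec: CohortSpec | None = None, seed: int = 0,
                  simulate: bool = True) -> list[SyntheticParticipant]:
    """Draw a full cohort; with ``simulate=True`` every participant gets a
    blocking response table and a completed PRL session."""
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_total

    phenotypes = np.array(["CHR"] * spec.n_chr + ["HSC"] * spec.n_hsc + ["HC"] * spec.n_hc)
    rng.shuffle(phenotypes)

    high_par = np.zeros(n, dtype=bool)
    high_par[rng.choice(n, size=spec.n_high_paranoia, replace=False)] = True
    # PDI-C labels drawn with positive dependence on paranoia
    w = np.where(high_par, spec.paranoia_pdic_odds_ratio, 1.0)
    high_pdic = np.zeros(n, dtype=bool)
    high_pdic[rng.choice(n, size=spec.n_high_pdic, replace=False, p=w / w.sum())] = True

    participants: list[SyntheticParticipant] = []
    for i in range(n):
        rw, hgf = _draw_params(spec, bool(high_par[i]), bool(high_pdic[i]), rng)
        design_seed = int(rng.integers(0, 2**31 - 1))
        design = build_blocking_design(reps_per_phase=spec.reps_per_phase,
                                       seed=design_seed)
        p = SyntheticParticipant(
            id=f"S{i:04d}",
            phenotype=str(phenotypes[i]),
            high_paranoia=bool(high_par[i]),
            high_pdic=bool(high_pdic[i]),
            rw=rw,
            hgf=hgf,
            design=design,
            blocking_trials=emit_trials(design),
        )
        if simulate:
            p.blocking_responses = simulate_blocking_responses(
                p, spec.blocking_noise_sd, seed=design_seed + 1)
            # the generative population is restricted to filter-valid HGF
            # parameter sets (fitting rejects invalid ones the same way):
            # redraw on a non-positive precision during forward play
            for attempt in range(100):
                try:
                    p.prl = simulate_prl_choices(p, seed=design_seed + 2 + attempt)
                    break
                except HGFInvalidError:
                    _, p.hgf = _draw_params(spec, bool(high_par[i]),
                                            bool(high_pdic[i]), rng)
            else:  # pragma: no cover
                raise RuntimeError(f"{p.id}: no valid HGF parameter draw found")
        participants.append(p)
    return participants
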