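"""Task designs: the food-allergy Kamin-blocking task and the 3-deck
probabilistic reversal-learning (PRL) task.

The blocking task is a three-phase causal-learning schedule. In each trial a
"meal" of one or two food cues is shown and the participant predicts whether
it causes an allergic reaction, responding on a [-1, 1] scale. Phase 1 trains
single cues (10 repetitions each), phase 2 pairs trained cues with novel ones
(6 repetitions), and phase 3 probes the novel cues alone (6 repetitions). The
score-bearing categories are the blocking-confirmation triple
(A2+ -> A2B2+ -> B2-) and its control (C1- -> C1D1+ -> D1+).

The PRL task is a 160-trial, two-block, three-deck bandit paying +100 for a
win and -50 for a loss. Unannounced to the player, the deck reward
probabilities are permuted (a "reversal") whenever the best deck was chosen
on 9 of the last 10 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrialTypeSpec",
    "BlockingDesign",
    "BlockingTrial",
    "PRLSession",
    "DEFAULT_TRIAL_TYPES",
    "DEFAULT_DECK_PROBS",
    "build_blocking_design",
    "emit_trials",
    "build_prl_session",
    "play_prl",
]

# outcome codes
ALLERGY = 1
NO_ALLERGY = -1


@dataclass(frozen=True)
class TrialTypeSpec:
    """One stimulus category: its cue compound and outcome in each phase.

    ``cues`` holds one tuple of cue labels per phase (1 or 2 labels);
    ``outcomes`` the corresponding outcome code, +1 = allergy, -1 = no
    allergy. Phase-3 probes may be feedback-free (see
    :func:`build_blocking_design`).
    """

    category_id: str
    cues: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]
    outcomes: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.cues) != 3 or len(self.outcomes) != 3:
            raise ValueError(f"{self.category_id}: need cues/outcomes for 3 phases")
        for phase, compound in enumerate(self.cues, start=1):
            if not 1 <= len(compound) <= 2:
                raise ValueError(
                    f"{self.category_id} phase {phase}: a compound holds 1 or 2 cues, "
                    f"got {compound!r}"
                )
            if len(set(compound)) != len(compound):
                raise ValueError(
                    f"{self.category_id} phase {phase}: duplicate cue in {compound!r}"
                )
        for phase, o in enumerate(self.outcomes, start=1):
            if o not in (ALLERGY, NO_ALLERGY):
                raise ValueError(
                    f"{self.category_id} phase {phase}: outcome must be +1/-1, got {o}"
                )


#: The two documented score-bearing categories plus five filler categories
#: (a second blocking set, single-cue causal/non-causal training, and two
#: novel-cue pairings), giving the 7-category, 154-trial schedule.
DEFAULT_TRIAL_TYPES: tuple[TrialTypeSpec, ...] = (
    TrialTypeSpec("block_confirm", (("A2",), ("A2", "B2"), ("B2",)), (1, 1, -1)),
    TrialTypeSpec("block_control", (("C1",), ("C1", "D1"), ("D1",)), (-1, 1, 1)),
    TrialTypeSpec("block_second", (("A1",), ("A1", "B1"), ("B1",)), (1, 1, -1)),
    TrialTypeSpec("single_causal", (("E",), ("E",), ("E",)), (1, 1, 1)),
    TrialTypeSpec("single_noncausal", (("F",), ("F",), ("F",)), (-1, -1, -1)),
    TrialTypeSpec("novel_causal", (("G",), ("G", "H"), ("H",)), (1, 1, 1)),
    TrialTypeSpec("novel_noncausal", (("I",), ("I", "J"), ("J",)), (-1, -1, -1)),
)


@dataclass(frozen=True)
class BlockingTrial:
    """One scheduled presentation of a stimulus category."""

    index: int
    phase: int
    category_id: str
    cues: tuple[str, ...]
    outcome: int
    is_first_of_phase: bool
    #: False on feedback-free probe trials (first phase-3 presentation by
    #: default): the response is recorded but no outcome is shown, so the
    #: learner does not update on it.
    gives_feedback: bool
    #: 1-based count of how many times this category has appeared so far.
    presentation: int


@dataclass(frozen=True)
class BlockingDesign:
    trial_types: tuple[TrialTypeSpec, ...]
    reps_per_phase: tuple[int, int, int]
    seed: int
    #: per-trial (category_id, phase), phases contiguous, shuffled within phase
    presentation_order: tuple[tuple[str, int], ...]
    #: whether phase-3 probes deliver feedback after the first presentation
    probe_feedback_after_first: bool = True

    @property
    def n_trials(self) -> int:
        return len(self.presentation_order)

    def trial_type(self, category_id: str) -> TrialTypeSpec:
        for tt in self.trial_types:
            if tt.category_id == category_id:
                return tt
        raise KeyError(category_id)


def build_blocking_design(
    trial_types: tuple[TrialTypeSpec, ...] | None = None,
    reps_per_phase: tuple[int, int, int] = (10, 6, 6),
    seed: int = 0,
    probe_feedback_after_first: bool = True,
) -> BlockingDesign:
    """Build a blocking-task schedule.

    Within each phase every category appears ``reps_per_phase[phase]`` times
    in a uniformly shuffled order (seeded); phases are contiguous. Defaults
    give the 7-category, 10/6/6-repetition, 154-trial schedule.
    """
    if trial_types is None:
        trial_types = DEFAULT_TRIAL_TYPES
    trial_types = tuple(trial_types)
    if not trial_types:
        raise ValueError("need at least one trial type")
    ids = [tt.category_id for tt in trial_types]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate category_id in {ids}")
    if len(reps_per_phase) != 3 or any(r < 1 for r in reps_per_phase):
        raise ValueError(f"reps_per_phase must be 3 positive integers, got {reps_per_phase}")

    rng = np.random.default_rng(seed)
    order: list[tuple[str, int]] = []
    for phase, reps in enumerate(reps_per_phase, start=1):
        block = [tt.category_id for tt in trial_types for _ in range(reps)]
        perm = rng.permutation(len(block))
        order.extend((block[i], phase) for i in perm)
    return BlockingDesign(
        trial_types=trial_types,
        reps_per_phase=tuple(reps_per_phase),
        seed=seed,
        presentation_order=tuple(order),
        probe_feedback_after_first=probe_feedback_after_first,
    )


def emit_trials(design: BlockingDesign) -> list[BlockingTrial]:
    """Expand a design into its per-trial stream, in presentation order."""
    if not design.presentation_order:
        raise ValueError("design schedules no trials")
    types = {tt.category_id: tt for tt in design.trial_types}
    seen: dict[str, int] = {cid: 0 for cid in types}
    probed: set[str] = set()
    trials: list[BlockingTrial] = []
    prev_phase = None
    for index, (cid, phase) in enumerate(design.presentation_order):
        tt = types[cid]
        seen[cid] += 1
        feedback = True
        if phase == 3:
            if cid not in probed:
                probed.add(cid)
                feedback = False  # the score-bearing probe: response only
            elif not design.probe_feedback_after_first:
                feedback = False
        trials.append(
            BlockingTrial(
                index=index,
                phase=phase,
                category_id=cid,
                cues=tuple(sorted(tt.cues[phase - 1])),
                outcome=tt.outcomes[phase - 1],
                is_first_of_phase=(prev_phase is not None and phase != prev_phase),
                gives_feedback=feedback,
                presentation=seen[cid],
            )
        )
        prev_phase = phase
    return trials


def first_probe_index(trials: list[BlockingTrial], category_id: str) -> int:
    """Index of the first phase-3 presentation of a category (the score trial)."""
    for t in trials:
        if t.phase == 3 and t.category_id == category_id:
            return t.index
    raise ValueError(f"no phase-3 trial for category {category_id!r}")


# ---------------------------------------------------------------------------
# Probabilistic reversal learning
# ---------------------------------------------------------------------------

#: per-block deck reward probabilities (block 1, block 2)
DEFAULT_DECK_PROBS: tuple[tuple[float, ...], ...] = ((0.9, 0.5, 0.1), (0.8, 0.4, 0.2))

WIN_POINTS = 100
LOSS_POINTS = -50


@dataclass
class PRLSession:
    """A PRL task environment, optionally filled in with one play-through.

    Until :func:`play_prl` runs, ``choices``/``outcomes``/``deck_probs`` are
    ``None``; reward probabilities cannot be laid out in advance because
    reversals are triggered by the player's own choices.
    """

    n_trials: int
    n_blocks: int
    block_probs: tuple[tuple[float, ...], ...]
    criterion: tuple[int, int]  # (hits, window): reversal after 9-of-10
    seed: int
    deck_probs: np.ndarray | None = None  # (n_trials, n_decks) once played
    choices: np.ndarray | None = None
    outcomes: np.ndarray | None = None
    reversal_trials: tuple[int, ...] = ()

    @property
    def n_decks(self) -> int:
        return len(self.block_probs[0])

    @property
    def trials_per_block(self) -> int:
        return self.n_trials // self.n_blocks

    @property
    def completed(self) -> bool:
        return self.choices is not None

    @property
    def total_points(self) -> int:
        if self.outcomes is None:
            raise ValueError("session not played yet")
        return int(self.outcomes.sum())


def build_prl_session(
    block_probs: tuple[tuple[float, ...], ...] = DEFAULT_DECK_PROBS,
    n_trials: int = 160,
    n_blocks: int | None = None,
    criterion: tuple[int, int] = (9, 10),
    seed: int = 0,
) -> PRLSession:
    """Build the PRL environment (choices unfilled).

    Defaults give 160 trials in 2 blocks of 80; the probability triple is
    re-dealt at each block boundary and permuted at each reversal.
    """
    if n_blocks is None:
        n_blocks = len(block_probs)
    if len(block_probs) != n_blocks:
        raise ValueError("one probability set per block required")
    if n_trials % n_blocks != 0:
        raise ValueError("n_trials must divide evenly into blocks")
    n_decks = len(block_probs[0])
    for probs in block_probs:
        if len(probs) != n_decks:
            raise ValueError("all blocks must use the same number of decks")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"probabilities must lie in [0,1]: {probs}")
        top = max(probs)
        if sum(1 for p in probs if p == top) != 1:
            raise ValueError(f"tied maximum reward probability in {probs}")
    hits, window = criterion
    if not 1 <= hits <= window:
        raise ValueError(f"criterion {criterion} must satisfy 1 <= hits <= window")
    return PRLSession(
        n_trials=n_trials,
        n_blocks=n_blocks,
        block_probs=tuple(tuple(p) for p in block_probs),
        criterion=criterion,
        seed=seed,
    )


def play_prl(session: PRLSession, agent, seed: int | None = None) -> PRLSession:
    """Play a session with a choice policy and return the completed record.

    ``agent(t, choices, outcomes)`` receives the 0-based trial index and the
    play history so far (lists of deck indices and point outcomes) and returns
    a deck index. Outcomes are drawn as +100 with the chosen deck's current
    reward probability, else -50. When the best deck was chosen on at least
    ``hits`` of the last ``window`` trials, the probabilities are rotated one
    position and the following trial is recorded as a reversal; the counting
    window restarts after each reversal and at block boundaries.
    """
    if session.completed:
        session = replace(session, deck_probs=None, choices=None, outcomes=None,
                          reversal_trials=())
    rng = np.random.default_rng(session.seed if seed is None else seed)
    n = session.n_trials
    n_decks = session.n_decks
    hits, window = session.criterion

    deck_probs = np.empty((n, n_decks))
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    reversals: list[int] = []

    probs = np.asarray(session.block_probs[0], dtype=float)
    best_window: list[bool] = []
    pending_reversal = False
    for t in range(n):
        if t % session.trials_per_block == 0 and t > 0:
            probs = np.asarray(session.block_probs[t // session.trials_per_block],
                               dtype=float)
            best_window.clear()
            pending_reversal = False
        if pending_reversal:
            probs = np.roll(probs, 1)
            reversals.append(t)
            best_window.clear()
            pending_reversal = False
        deck_probs[t] = probs
        c = int(agent(t, choices[:t].tolist(), outcomes[:t].tolist()))
        if not 0 <= c < n_decks:
            raise ValueError(f"agent chose deck {c} outside 0..{n_decks - 1} at trial {t}")
        choices[t] = c
        outcomes[t] = WIN_POINTS if rng.random() < probs[c] else LOSS_POINTS
        best_window.append(c == int(np.argmax(probs)))
        if len(best_window) > window:
            best_window.pop(0)
        if len(best_window) == window and sum(best_window) >= hits:
            pending_reversal = True
    return replace(
        session,
        deck_probs=deck_probs,
        choices=choices,
        outcomes=outcomes,
        reversal_trials=tuple(reversals),
    )
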