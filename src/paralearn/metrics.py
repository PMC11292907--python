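"""Behavioural summary statistics: win-switch rate, blocking and control
scores, and the effect sizes used for group contrasts.

The win-switch rate (WSR) is the fraction of rewarded trials followed by a
change of deck: switches-after-winning / total wins. Wins on the final
trial have no observable next choice and are excluded from the
denominator; with no eligible win the rate is undefined and returned as
NaN (never coerced to 0). The blocking score is the participant's response
to the blocked cue (B2) at its first phase-3 probe; the control score is
the response to the control cue (D1) at its first probe.

Group inferential tests (ANOVAs, t-tests) are delegated to standard
statistics backends; only the effect-size formulas are provided here.
"""

from __future__ import annotations

import numpy as np

from .tasks import BlockingTrial, first_probe_index

__all__ = [
    "win_switch_rate",
    "blocking_scores",
    "cohens_d",
    "partial_eta_squared",
]

#: WSR denominator convention, recorded alongside outputs
WSR_CONVENTION = "wins on the final trial are excluded (no observable next choice)"


def win_switch_rate(choices, outcomes, win_value: int = 100) -> float:
    """Switches after winning / total wins; NaN when no eligible win."""
    choices = np.asarray(choices)
    outcomes = np.asarray(outcomes)
    if choices.shape != outcomes.shape or choices.size < 2:
        raise ValueError("need aligned choice/outcome sequences of length >= 2")
    wins = outcomes[:-1] == win_value
    n_wins = int(wins.sum())
    if n_wins == 0:
        return float("nan")
    switches = choices[1:] != choices[:-1]
    return float((wins & switches).sum() / n_wins)


def blocking_scores(
    responses,
    trials: list[BlockingTrial],
    blocking_category: str = "block_confirm",
    control_category: str = "block_control",
) -> tuple[float, float]:
    """(blocking_score, control_score): responses at the first phase-3
    probes of the blocked and control cues."""
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (len(trials),):
        raise ValueError(f"need {len(trials)} responses aligned to trials")
    b = first_probe_index(trials, blocking_category)
    c = first_probe_index(trials, control_category)
    return float(responses[b]), float(responses[c])


def cohens_d(sample1, sample2) -> float:
    """Pooled-SD standardized mean difference (mean1 - mean2)."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per sample")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("both sums of squares are zero")
    return float(ss_effect / (ss_effect + ss_error))
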