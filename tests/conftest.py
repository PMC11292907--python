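"""Shared fixtures; the expensive cohort/recovery computations are
session-scoped so behavioural, dissociation and recovery tests reuse them."""

from __future__ import annotations

import pytest

from paralearn.blocking import fit_participant
from paralearn.cohort import CohortSpec, sample_cohort
from paralearn.hgf import fit_hgf
from paralearn.tasks import build_blocking_design, emit_trials


@pytest.fixture(scope="session")
def default_design():
    return build_blocking_design(seed=7)


@pytest.fixture(scope="session")
def default_trials(default_design):
    return emit_trials(default_design)


@pytest.fixture(scope="session")
def cohort_452():
    """The full-size synthetic cohort at the pinned seed."""
    return sample_cohort(CohortSpec(), seed=1)


@pytest.fixture(scope="session")
def cohort_452_rw_fits(cohort_452):
    """RW2 fits for every participant of the full cohort."""
    return [
        fit_participant(p.blocking_trials, p.blocking_responses, "RW2",
                        n_starts=10, seed=i)
        for i, p in enumerate(cohort_452)
    ]


@pytest.fixture(scope="session")
def blocking_recovery_100():
    """True vs fitted RW parameters, 100 subjects at response-noise SD 0.1."""
    spec = CohortSpec(n_total=100, n_chr=40, n_hsc=36, n_hc=24,
                      n_high_paranoia=14, n_high_pdic=25,
                      blocking_noise_sd=0.1)
    cohort = sample_cohort(spec, seed=1)
    out = {k: ([], []) for k in ("alpha", "gamma", "lam", "eta")}
    for i, p in enumerate(cohort):
        fit = fit_participant(p.blocking_trials, p.blocking_responses, "RW2",
                              n_starts=10, seed=i)
        for k in out:
            out[k][0].append(getattr(p.rw, k))
            out[k][1].append(getattr(fit.params, k))
    return out


@pytest.fixture(scope="session")
def hgf_recovery_50():
    """True vs fitted HGF parameters, 50 subjects, full-session MAP fits."""
    spec = CohortSpec(n_total=50, n_chr=20, n_hsc=18, n_hc=12,
                      n_high_paranoia=7, n_high_pdic=12)
    cohort = sample_cohort(spec, seed=1)
    out = {k: ([], []) for k in ("omega3", "kappa", "mu0_2")}
    for i, p in enumerate(cohort):
        fit = fit_hgf(p.prl, per_block=False, n_starts=5, seed=i)
        for k in out:
            out[k][0].append(getattr(p.hgf, k))
            out[k][1].append(getattr(fit.params, k))
    return out
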