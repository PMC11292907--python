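# paralearn

Computational models dissociating **paranoia** from **non-paranoid
delusion-like belief conviction** through two learning tasks: a Kamin
blocking (food-allergy causal learning) task and a three-deck
probabilistic reversal-learning (PRL) task. The package is aimed at
computational-psychiatry researchers who want to fit these models to
trial-level behaviour, compare model variants, and run fully synthetic
end-to-end analyses (cohort simulation → fitting → model selection →
group contrasts → parameter recovery) without any participant data.

## The models

**Blocking (Rescorla–Wagner family).** Each cue carries an associative
weight *w* (elemental representation). The response to a compound is

> r̂ = clip(w_p + γ·w_s, −1, 1),

where the *primary* cue p is the one with the larger current weight;
γ ∈ [0, 1] spans additive (γ = 1) to maximum-only (γ = 0) cue
integration. After feedback o ∈ {+1 allergy, −1 no allergy}:

> w_p ← w_p + α(o − w_p)   w_s ← w_s + α(λ·o − w_s)

with a single static learning rate α. λ ∈ [−1, 1] is the *secondary-cue
learning asymptote*: λ = 0 yields classical blocking, λ = 1 unselective
learning, λ < 0 counterfactual inference ("A causes the allergy, so B
prevents it"). On the first trial of each new phase, weights decay by a
retention factor η ∈ [0, 1]. Responses are fitted by maximum likelihood
under a Gaussian centred on r̂ with profiled residual variance; the
family RW1–RW5 (free noise σ, full model, no forgetting, additive-fixed,
maximum-fixed) is compared by random-effects Bayesian model selection
with **protected exceedance probabilities** (PXP), which correct
exceedance probabilities by the Bayes omnibus risk:
PXP = (1 − BOR)·EP + BOR/K.

**PRL (3-level hierarchical Gaussian filter).** Each deck has a Gaussian
belief on the log-odds of paying out (level 2); a shared level-3 belief
μ₃ tracks the environment's log-volatility. ω₂ is the tonic level-2
log-volatility, κ the phasic level 2–3 coupling, and ω₃ the
**meta-volatility learning rate** — how fast the volatility belief
itself moves. Choices follow a softmax on the predicted win
probabilities with inverse temperature β. Fitting is MAP with broad
Gaussian priors in unconstrained space; ω₃ can be reported averaged over
the two 80-trial task blocks.

The synthetic-cohort generator produces a large transdiagnostic sample: 452
participants (181 clinical high-risk, 161 help-seeking controls, 110
healthy controls), 65 high-paranoia and 113 high-conviction (PDI-C)
participants with overlapping labels, group-dependent latent parameters
(lower α and η with paranoia; higher λ with conviction; an ω₃ offset and
noisier choices with paranoia), blocking responses of model prediction
plus truncated Gaussian noise, and PRL sessions played by each
participant's own filter.

## Worked example

```python
from paralearn import CohortSpec, sample_cohort, fit_participant
from paralearn.metrics import blocking_scores, win_switch_rate

spec = CohortSpec(n_total=6, n_chr=3, n_hsc=2, n_hc=1,
                  n_high_paranoia=2, n_high_pdic=2)
cohort = sample_cohort(spec, seed=7)
p = cohort[0]
fit = fit_participant(p.blocking_trials, p.blocking_responses, "RW2",
                      n_starts=25, seed=0)
b, c = blocking_scores(p.blocking_responses, p.blocking_trials)
```

printing, for this seed:

```
participant S0000: paranoia=False, pdic=False
behavioural blocking score -0.168, control score +0.763
win-switch rate 0.036
true  alpha=0.308 gamma=0.745 lam=-0.439 eta=0.843
fitted alpha=0.273 gamma=0.787 lam=-0.454 eta=0.798
log-likelihood 57.0, BIC -93.9
model blocking score -0.309, model control score +0.680
```

The blocking score is the response to the blocked cue (B₂) at its first
test-phase probe and the control score the response to the matched
control cue (D₁): this simulant blocks (negative blocked-cue response —
its λ is counterfactual) while having learned the control cue as causal.
The fitted parameters land close to the generating ones, and the model's
own probe responses (bottom line) track the behavioural scores.

The same pipeline is scriptable from the shell:

```bash
paralearn simulate-cohort --n 30 --seed 1 --out cohort/
paralearn fit-blocking cohort/blocking.csv --variant RW2 --out fits_rw2.json
paralearn fit-blocking cohort/blocking.csv --variant RW3 --out fits_rw3.json
paralearn compare-models fits_rw2.json fits_rw3.json --out bms.json
paralearn metrics --blocking cohort/blocking.csv --prl cohort/prl.csv
paralearn recover --n 50 --seed 1
```

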