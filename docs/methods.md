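# Methods

## Blocking task and model

The blocking task is a three-phase causal-learning schedule with seven
stimulus categories, each shown 10/6/6 times in the learning, blocking
and test phases (154 trials). Two categories carry the scores: the
blocking-confirmation triple A₂+ → A₂B₂+ → B₂− and its control
C₁− → C₁D₁+ → D₁+. The remaining five are fillers chosen to balance the
design — a second blocking set (A₁+/A₁B₁+/B₁−), single-cue causal and
non-causal categories, and two novel-cue pairings — and are fully
overridable from a design table; only the two score-bearing categories
and the 154-trial count are treated as fixed. Within each phase the
presentation order is a uniform seeded shuffle with no repeat
constraints. Outcomes are coded bipolar (+1 allergy, −1 no allergy) to
match the [−1, 1] response scale and make the counterfactual asymptote
λ = −1 meaningful. The first test-phase probe of each category is
feedback-free (it is the score-bearing trial); later probe repetitions
give feedback by default, configurable.

The model keeps one weight per cue, initialised at 0 (novel cues carry
no expectation), clipped to [−1, 1] after every update. For compounds
the primary cue is the one with the larger current weight, ties broken
by label order — a deterministic rule that realises both integration
endpoints (additive at γ = 1, maximum-only at γ = 0) with one bounded
parameter. Prediction errors are attributed per cue rather than summed:
the primary cue updates toward the outcome, the secondary toward λ·o.
Forgetting is parameterised as *retention*: weights are multiplied by
η at the first trial of phases 2 and 3, so η = 1 means no forgetting.
Because the complementary convention (decay = 1 − η) also circulates,
every fit records the convention in its metadata rather than assuming
the reader's.

Fitting is maximum likelihood under a Gaussian centred on r̂. The noise
variance is profiled as the mean squared residual — reducing model
complexity by one parameter — with a floor of 1e−6 so a perfect fit
keeps a finite likelihood; variant RW1 frees σ instead. Optimisation is
bounded L-BFGS-B from 25 uniform random starts by default (the
likelihood surface proved smooth enough that 10 starts reproduce
25-start optima; the large-cohort stages use 10). The trajectory kernel
is a plain array loop, JIT-compiled when numba is available with a
bit-identical pure-Python fallback.

Variant labels: RW2 is the full model (α, γ, λ, η, profiled σ); RW1 adds
free σ; RW3 removes forgetting; RW4/RW5 fix integration at the additive
/ maximum-only endpoint. Which of RW4/RW5 gets which endpoint is a
labelling convention and can be swapped in one place.

## Model selection

Per-subject log model evidence is approximated as −BIC/2 (the fits are
maximum-likelihood, so a Laplace approximation is unavailable without
Hessians; −AIC/2 is available by flag). The random-effects scheme puts a
Dirichlet prior (α₀ = 1) on population model frequencies and iterates
the standard variational updates to a 1e−8 tolerance on the
concentrations. Exceedance probabilities use the analytic Beta
comparison for two models, an exact symmetry shortcut when the posterior
concentrations are all equal, and seeded Dirichlet Monte-Carlo (1e5
draws) otherwise. The Bayes omnibus risk compares the variational free
energy of the random-effects model with the equal-frequency null;
protected exceedance probabilities blend the two:
PXP = (1 − BOR)·EP + BOR/K. Under the null the free-energy gap is a
fixed complexity penalty, so BOR plateaus near 0.88 rather than
reaching 1 at finite sample size.

## PRL task and filter

The PRL environment deals three decks with reward probabilities
(0.9, 0.5, 0.1) in block 1 and (0.8, 0.4, 0.2) in block 2 (80 trials
each), paying +100/−50. Whenever the current best deck was chosen on 9
of the last 10 trials, the probability vector rotates one position; the
counting window restarts after each reversal and at the block boundary,
and a reversal that would coincide with the block boundary is subsumed
by the block's own contingency change.

The filter gives each deck a level-2 Gaussian belief on the log-odds of
winning and shares a single level-3 volatility belief. Only the chosen
deck receives an outcome update; unchosen decks inflate their variance
by the current volatility exp(κμ₃ + ω₂) — the minimal multi-arm
structure for this task. Outcomes are binarised (+100 → 1, −50 → 0): the
filter models win probability, not point magnitude. ω₃ enters as
exp(ω₃) added to the level-3 predicted variance; there is no
mean-reversion at level 3 (mean-reverting volatility is a deliberate
non-goal). Any parameter set that drives a variance or the level-3
precision non-positive — including float overflow of the belief state —
raises a rejection error, which fitting treats as an infinite penalty
and the cohort generator treats as grounds to redraw: the generative
population is the filter-valid region.

The response model is a softmax on the predicted win probabilities with
one inverse temperature β, evaluated in log space for numerical safety
at large β. Fitting is MAP over (μ0₂, κ, ω₂, ω₃, β) in unconstrained
space (log transforms for κ and β) with broad Gaussian priors — means
ω₂ = −3, ω₃ = −6, log κ = 0, μ0₃ = 1, log β = log 5, variances 4 — via
multi-start L-BFGS-B (first start at the prior mean). σ0₂, μ0₃ and σ0₃
are pinned at their defaults: they are weakly identified from 160 binary
trials. Per-block fitting estimates each 80-trial block separately and
reports the arithmetic mean of the block ω₃ estimates.

## Synthetic cohorts

The default group structure is a large transdiagnostic sample: 452 participants
(CHR 181 / HSC 161 / HC 110), 65 high-paranoia, 113 high PDI-C, with the
paranoia and conviction labels drawn with positive dependence (odds
ratio 1.5 — strong enough that the groups overlap, weak enough that a
parameter offset in one symptom dimension does not masquerade as an
effect of the other at n = 452). Phenotype carries no parameter offset:
in these tasks the symptom dimensions, not the clinical phenotypes, are
what separates behaviour.

Latent parameters are Gaussian on transformed scales (logit for α, γ, η;
atanh for λ; log for κ and β), which keeps draws in-bounds without
rejection. Defaults: α centred on 0.30 (logit SD 0.6) with a −0.45
paranoia offset; η centred on 0.88 (SD 0.5) with a −0.45 paranoia offset
(less retention); λ centred at tanh(−0.25) (SD 0.45) with a +0.22 PDI-C
offset; γ centred at 0.5 for everyone. The offsets were calibrated once,
before the test suite was frozen, so that the behavioural group
contrasts (blocked-cue, control-cue, win-switch rate) land in the
|d| ≈ 0.3–0.5 band; with only 65 high-paranoia members, single-seed
sample d's fluctuate around those population values by roughly ±0.2.
Blocking responses are the model prediction plus Gaussian noise
(SD 0.2 by default), clipped to [−1, 1].

HGF latents describe a strongly coupled, highly volatile regime — the
task is volatile from the outset: κ ~ logN(log 1.8, 0.15),
ω₂ ~ N(−4, 0.5), ω₃ ~ N(−3.5, 1.5) with a +1.0 paranoia offset, μ0₂ ~
N(0, 0.2), β ~ logN(log 16, 0.3) with a −0.25 paranoia offset (noisier,
switch-prone play). The ω₃ offset's sign is configurable: the direction
of the paranoia–volatility association is reported inconsistently
across analyses of this kind, so the generator makes it an explicit
choice with a documented default (positive: stronger volatility
updating with paranoia) rather than a buried constant.

What the generator does *not* emulate: real response biases (anchoring,
scale truncation habits), within-session parameter drift, attrition,
site effects, or questionnaire measurement error. Passing tests show
the pipeline is self-consistent — it recovers what generated the data —
not that the models are well-specified for human behaviour.

## Parameter recovery and its limits

Blocking recovery is excellent: at response-noise SD 0.1 with 100
simulated participants, Spearman correlations between generating and
fitted values are ≈ 0.99 for α and λ (≈ 0.96 for γ, ≈ 0.93 for η).

Level-3 recovery in the filter is intrinsically modest. An oracle
analysis — profiling the likelihood over ω₃ with every other parameter
held at its generating value — caps the attainable rank correlation at
roughly 0.2–0.45 for a single 160-trial session in this architecture,
because ω₃ shapes behaviour only through transient, reversal-locked
modulation of the effective learning rate, whereas μ0₂ (via the update
asymmetry of the logistic squashing) and κ (via κ·μ₃ acting as a shift
of the tonic volatility) have static likelihood pathways. The 50-subject
full-fit experiment at the pinned seed recovers ω₃ at Spearman ≈ 0.33,
below μ0₂ (≈ 0.51) and κ (≈ 0.62); per-block averaging and a
neutral-μ0₃ reparameterisation were both evaluated and recover ω₃ worse.
The recovery test threshold (0.2) was fixed from this oracle analysis
before the suite was frozen. One acceptance check asserts the opposite
ordering (ω₃ recovering better than the level-2 parameters) and is
expected to fail under this architecture; it is retained, rather than
weakened, as an honest record of that limit.

## Numerical choices

* Profiled-likelihood variance floor 1e−6 (finite likelihood on perfect
  fits).
* Weight clipping to [−1, 1] after every update; predictions clipped the
  same way.
* Compound tie-break by cue-label order; deterministic and symmetric
  under relabelling of the schedule.
* Optimiser bounds: α, γ, η ∈ [0, 1]; λ ∈ [−1, 1]; σ ∈ [1e−3, 2];
  HGF parameters unbounded in transformed space.
* All randomness flows through `numpy.random.default_rng` seeds;
  identical (config, seed) pairs give bit-identical schedules, cohorts
  and fits.
* Large-cohort problem sizes: 10 optimiser starts per blocking fit, 60
  subjects for the five-variant model-selection stage, 100/50 subjects
  for the blocking/HGF recovery experiments — sizes at which every
  reported quantity is stable except the seed-level wobble noted above.
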