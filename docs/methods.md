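# Methods

## Task model

The package simulates a two-session advice game. Session 1 captures the
advisor's independent opinion on each of 66 stimuli: a binary price
judgement (higher/lower than the true price, with the shown price deviating
from the true price by ±20 % before rounding) and a 1–60 wager. Session 2
repeats the same stimuli; on *shown* trials the advisor first sees the
scripted advisee's opinion, on *masked* trials (14 of 66 in the
observation-only studies) they do not. The advisee's judgement copies the
advisor's Session-1 advice on exactly half of the shown trials and flips it
on the other half; their wagers are Normal(10, 10) or Normal(50, 10) draws
rounded and clipped to the 1–60 scale (raw draws are kept accessible so
distributional tests can target the generating Normal rather than the
truncated export).

In the feedback studies, Session 2 has three 22-trial phases. Acceptance of
advice is an independent Bernoulli draw given (advice type, phase): a mild
advisee accepts at 30/50/70 % and an insusceptible one at 10/30/50 %, with
the neutral phase always first and the prefer-aligned / prefer-misaligned
phases counterbalanced across participants. Feedback is conditionally
independent given the schedule — the standard probabilistic-reversal
assumption. Averaged over phases, each advice type is accepted at exactly
50 % (mild) or 30 % (insusceptible), so a balanced advisor faces those
overall rates by construction.

The masked-trial count printed for the published task (14, i.e. "20 %" of
66) is internally inconsistent with an exact 20 %; the integer count 14 is
taken as authoritative and configurable. Feedback-study sessions default to
zero masked trials.

## Advisor models

Values are combined per trial and passed through an inverse logit.
`Φ(x) = x/60` normalizes wagers to (0, 1].

* Non-social value: `Q_ns(selected) = Φ(|OS_ns|)`, `Q_ns(other) = 0`.
* M1: `p(higher) = logistic(τ·(Q_ns(h) − Q_ns(l)))`, τ ∈ (0, 20).
* M2–M7: `Q = w_ns·Q_ns + w_s·Q_s` with `Q_s` mapped onto (higher, lower)
  by the advisee's judgement; no temperature parameter (the weights already
  set the logit scale, and a temperature would be unidentifiable).
  Weights are bounded to (0, 10).
* Masked trials under M2–M7 use the non-social term alone:
  `p(higher) = logistic(w_ns·(Q_ns(h) − Q_ns(l)))`. This is the structural
  reading of "identical to the baseline model" — M2–M7 have no τ, so the
  non-social weight plays its role.
* M4's published update rule adds `κ·R` to the aligned value with
  R ∈ {1, 0}; taken literally the value can only grow, and no upper cap is
  imposed. A `signed_feedback` variant (R ∈ {1, −1}), matching the verbal
  description that rejection decreases the value, is available but off by
  default.
* M5–M7 initialize `Q_s = (1, 0)` — a pre-existing tendency to align — and
  update only the chosen advice type by `Q += α(R − Q)`. With R ∈ {0, 1}
  and α ∈ (0, 1) the values provably stay in [0, 1].
* The published equation for the value combination prints the two weight
  subscripts opposite to their verbal definitions; this implementation
  follows the definitions (`w_ns` multiplies the non-social value).

Only Session-2 judgement choices enter the likelihood. Session-1 behavior,
all investments, observed advice types and feedback are conditioning
inputs. Advised investment magnitudes are not modelled; the simulator
fills them with clipped Normal(30, 10) draws (the advisor's typical wager
scale) so the metric pipeline has complete records.

## Behavioral measures

Opinion strength (OS) is the signed wager: + for "higher", − for "lower".
Opinion discrepancy is the absolute OS distance. The opinion shift rate is
the signed ratio

    OSR = (OS_s − OS_ns) / (OS_as − OS_ns),

i.e. the weight-of-advice convention: OSR > 0 is a shift toward the
advisee, > 0.5 over-weighing, > 1 overshoot. The signed (not absolute)
numerator is the only reading consistent with all three interpretive
thresholds and with the worked inexplicable example (OS_ns = −40,
OS_as = −5, OS_s = +10: ratio positive yet the final judgement disagrees
with the advisee). Two trial types are excluded as inexplicable: positive
ratio with an incongruent final judgement (type 1), and a zero baseline gap
(type 2). Remaining OSR values are trimmed per participant at mean ± 3 SD
in a single pass (mean and sample SD computed once on the pre-trim valid
values; the published procedure does not state a pass count, and a single
pass is the conservative choice). Trimming of a constant list removes
nothing (SD = 0 and every value equals the mean).

"Overall judgement switch" is the participant mean of the switch indicator
over opinion-shown trials; "overall alignment" the mean of the aligned
indicator over feedback trials; phase summaries report mean alignment per
(participant, phase) and adaptation scores relative to the neutral phase.

## Synthetic cohorts

Individual parameters are drawn Normal(mean, sd) on the unconstrained
scale and mapped to bounds with the same probit-style transform used in
inference, so the generator and the fitter share one hierarchy. Defaults
(constrained scale): τ = 2, w_ns = 2, w_s = 1, κ = 0.3, α = 0.3,
(α_al, α_mis) = (0.2, 0.4); M7's learning rates follow the reported
acceptance/rejection asymmetries — (0.60, 0.18, 0.09, 0.50) for the mild
schedule (differences 0.51 and −0.32) and (0.60, 0.05, 0.05, 0.50) for the
insusceptible one (0.55 and −0.45). Group sd defaults to 0.5
(unconstrained). w_ns = 2 and w_s = 1 are package choices (no group means
are published): they produce initial alignment around 0.7 on congruent-free
trials and switch rates near 0.25 — the qualitative regime of the observed
behavior. Session-1 judgements are fair coin flips (competence is not
modelled; only the congruency structure matters downstream), investments
clipped Normal(30, 10). Half the cohort gets each phase order; advisee risk
preference alternates between participants.

What the generator deliberately does *not* emulate: real participants'
judgement accuracy, stimulus-specific difficulty, response times, and any
serial dependence in wagers. Passing tests therefore demonstrate pipeline
correctness and identifiability under the assumed generative process, not
conclusions about human data.

## Inference

Hierarchical prior (non-centered): μ ~ Normal(0, 1),
σ ~ HalfNormal(1), z_i ~ Normal(0, 1), θ_i = F(μ + σ·z_i) with
F = bound × standard-normal CDF. Bounds: (0, 1) for learning rates and κ,
(0, 10) for weights, (0, 20) for τ (the upper bound for τ is a package
choice; the likelihood is flat in τ beyond the wager-scale logits).

Two fitters share this model:

* **MAP + Laplace** (default): each participant's unconstrained parameters
  are optimized under the standard-normal prior (L-BFGS-B, multi-start),
  and the posterior is approximated by a Gaussian at the mode with
  covariance from a numerical Hessian (eigenvalue-floored at 1e-4 for
  stability). Draws from this approximation feed the pointwise
  log-likelihood matrix. Deterministic given the seed.
* **Ensemble MCMC** (reference): affine-invariant ensemble sampling of the
  full hierarchy (group means, log-sds and all z's jointly). Walkers are
  folded into pseudo-chains for split-R̂; a fit with any R̂ > 1.05 raises a
  diagnostic error carrying the fit. Defaults: 1000 warmup + 1000 kept
  steps.

The pointwise unit for LOO is one trial (the likelihood factorizes by
trial given parameters). LOOIC = −2·elpd from PSIS-LOO; with a single draw
the estimate degenerates to the plug-in predictive density. Model weights
are pseudo-BMA+: Dirichlet(1) Bayesian-bootstrap resampling of the
pointwise elpd, softmax per replicate, averaged. Δa point estimates use
posterior means (medians available).

## Validation experiments

*Parameter recovery* simulates cohorts, refits, and reports per-parameter
truth–estimate correlation, bias and RMSE (posterior means as point
estimates). *Model recovery* tallies LOOIC winners per generating model
into a confusion matrix. For recovery the generating distributions span
each parameter's plausible range (unconstrained group sd = 1.0,
`recovery_group_config`) rather than the tight cohort default: recovery
probes identifiability across the space, and a cluster at the
confirmation-bias means pins the social values near (1, 0), making the
learning models' data genuinely indistinguishable from a constant bias —
an instructive property of the model family, visible in the README
example, not an artifact. *Posterior predictive checks* re-simulate
choices and feedback from posterior draws while holding the design,
Session-1 behavior and advisee opinions at their observed values, and
compare observed alignment with predictive intervals trial-wise, per
participant, per phase, and in the grand mean.

Default problem sizes (12 participants × 66 trials; 5 datasets per
generator; 100–200 approximation draws) are the package's desk-scale
choices; all are configurable upward.

## Numerical notes

Choice log-probabilities use `logaddexp` for stability. Ties in LOOIC are
broken by table order. Degenerate inputs (zero group variance, constant
OSR lists, single-draw LOO, all-identical draws) are handled explicitly
and covered by tests. Every stochastic component takes a seed; one run
seed is split hierarchically (SeedSequence) into design / advisee / agent /
sampler streams.
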