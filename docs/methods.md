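# Methods

`afchoice` implements the statistical pipeline of a gustatory affective-
forecasting experiment: a subject repeatedly chooses between two liquids, and
the analysis asks whether choices among *novel* mixes of familiar ingredients
are consistent, bias-free, and predicted by independently measured taste
preferences — the behavioural signature of hedonic forecasting rather than
trial-and-error learning.

## Study design assumed by the pipeline

Four ingredients (`C`, `R`, `L`, `V`; cherry, rhubarb, lemon, vinegar in the
motivating design) yield the C(4,2) = 6 pairwise mixes, identified by the
sorted concatenation of their component ids (`CL`, `CR`, `CV`, `LR`, `LV`,
`RV`). Phases:

1. **Familiarisation** — 30 blocked + 24 randomised ingredient-pair trials.
2. **AF test** — the 4 × 6 = 24 unique ingredient-mix pairs, four times each
   (96 trials): encounters 1–2 under visual access (*transparent*, trials
   1–48), encounters 3–4 without (*concealed*, trials 49–96). In these trials
   the ingredient is a 10-ml portion and the mix a 20-ml portion. Left/right
   placement is counterbalanced 2–2 within each pair.
3. **Colour control** — 36 ingredient-pair trials under a reversed colour
   scheme (sweet liquids re-dyed green, sour ones red).
4. **Post-experimental preferences** — either blocked pairwise trials over
   all C(10,2) = 45 liquid pairs (5 per block, 225 trials; "orangutan-style")
   or a 1–10 self-reported ranking ("human-style").

The *encounter index* of a trial is its 1-based position among the trials of
the same phase presenting the same unordered pair; all consistency and
model-fitting scopes key on it.

## Statistics

**Preference scores.** For any trial scope, an item's score is
chosen/offered — the proportion of occasions on which it was chosen when
present. Rankings use average ranks for ties, deliberately, because the
downstream tau-b correlation uses the tie structure. The three standard
scopes (encounters 1–2; concealed trials; all 96 test trials) share one code
path via scope predicates.

**Choice consistency.** A pair is *consistent* for a comparison if the same
option was chosen on both of the comparison's encounters: (1, 2) for
first-two-encounters, (2, 3) for across-conditions (last transparent vs
first concealed), (3, 4) for within-concealed. The consistent count over the
24 pairs is tested against chance 0.5 with the exact two-sided binomial test.
Pairs missing a required encounter are excluded *and reported*; denominators
are always printed because ambiguous denominators are the main obstacle to
reproducing this kind of analysis.

**Exact tests.** Both the binomial test and Fisher's exact test use the
minimum-likelihood two-sided convention: the p-value sums null probabilities
of all outcomes whose point probability does not exceed the observed one
(with the customary 1e-7 relative tolerance for floating-point ties). The
binomial version is computed by direct enumeration of the n+1 outcomes; the
Fisher version wraps `scipy.stats.fisher_exact`, and both are checked against
independent full-enumeration oracles in the tests. Sums within 1e-9 of 1 are
clamped to exactly 1 (the full-mass case accumulates rounding slightly below
1). No mid-p or asymptotic variants are offered.

**Rank association.** Kendall tau-b (tie-corrected) relates test-derived
scores to the post-experimental measure. Test-derived values are the raw
score proportions, not derived ranks, so ties enter tau-b as they arise.
Self-report ranks (1 = best) are harmonised to higher-is-better values via
`n + 1 − rank`. Significance uses a permutation test on relabellings of one
vector: full enumeration of the n! orderings for n ≤ 8, and a seeded
100,000-draw Monte-Carlo permutation scheme above (the study's n = 10 would
need 10! tau evaluations); because tie counts are invariant under
relabelling, only the concordance sum is recomputed per permutation. The
Monte-Carlo p uses the (hits + 1)/(draws + 1) correction so it is never 0. A
tie-corrected normal approximation is available but not the default: the data
are small, discrete and tied.

**Bradley–Terry models.** Choices are modelled as
Pr(i over j) = w_i / (w_i + w_j) = logistic(λ_i − λ_j) with log-worths λ.
One item's λ is fixed at 0 for identifiability (default: the alphabetically
first ingredient). Two nested structures are compared on the fit scope =
AF-test encounters 1–2 plus all post-experimental trials:

* **Model A** (constant): one worth per liquid, k = 9 free parameters for 10
  items. True if early choices among novel mixes already reflect the same
  stable values that post-experimental choices reveal — i.e. forecasting.
* **Model B** (split): the six mixes additionally get separate worths for
  the AF-test first-two-encounter trials, k = 15. True if early choices were
  driven by something other than the eventual taste values.

Comparison uses ΔAIC, ΔBIC (with n = the number of binary choices in the
fit, the exchangeable observation unit) and the likelihood-ratio test with
df = 6 (the six extra mix worths), p from the χ² survival function.

*Numerics.* The negative log-likelihood Σ log(1 + exp(−(λ_chosen −
λ_other))) and its analytic gradient are minimised with L-BFGS-B from a
deterministic all-zero start (the problem is convex in worth differences, so
the optimum is unique given the reference constraint), `ftol` 1e-12, `gtol`
1e-10, and box bounds ±20 on every log-worth: an item chosen always (or
never) has no finite MLE and saturates at the cap with an explicit
perfect-separation warning. Convergence is flagged from the optimiser status
or an off-bound gradient sup-norm below 1e-8.

## The synthetic-subject generator

Because raw data of this design are typically unpublished, every stage is
exercised against simulated subjects whose generative process matches the
analysis assumptions.

An agent holds latent log-worths for the four ingredients. A mix's
*forecast* worth is the arithmetic mean of its components' worths plus a
fixed per-mix Gaussian interaction term (sd `mix_interaction_sd`), allowing
non-additive tastes; the interaction draw is keyed by (seed, mix id) so it
never changes when the schedule does. Two valuation rules:

* **forecaster** — holds the forecast worth from the very first encounter;
* **trial_and_error** — has no pre-taste access to mix values: during AF
  encounters 1–2 (the pre-taste window, defined structurally rather than via
  a stateful choice history) every mix carries a flat prior equal to the
  median ingredient worth; afterwards the forecast (post-taste) worth
  applies. The flat prior, rather than uniform choice, keeps novelty/volume
  biases operative; pure inattention is a separate lapse rate λ ∈ [0, 1]
  (uniform choice with probability λ).

Per trial the left-over-right logit is the effective worth difference plus
`novelty_bias` (mix option), `volume_bias` (20-ml option) and per-colour
bias terms (ingredient colours follow the original scheme everywhere except
the colour-control phase, which uses the reversed scheme). `phase_shift`
displaces mix worths during the pre-taste window only — data generated with
phase_shift ≠ 0 are exactly model B's world, with phase_shift = 0 exactly
model A's. Self-reports rank the true post-taste worths perturbed by
Gaussian noise. All randomness flows from one integer seed through keyed
`numpy` generator streams (schedule, choices, interactions, self-report), so
a study is byte-reproducible and each component is independently stable.

Default ingredient worths are C = 2.0, R = 1.2, L = 0.4, V = 0.0 — a
moderate sweet-over-sour preference ordering. These are package defaults for
a plausible subject, not estimates from any dataset; a strongly deterministic
subject corresponds to a wider spread. What the simulator deliberately omits:
satiation/thirst dynamics, side biases, session breaks, and any interleaving
of extra familiarisation trials into the test phase — so passing tests show
the *pipeline* is correct under its own assumptions, not that real subjects
satisfy them.

## Validation experiments and problem sizes

* **Worth recovery** (`recovery_experiment`): generic BT choices over the
  four-ingredient catalogue with true worths equally spaced on [0, 2] (the
  pairwise gaps span the full ±2 range where choice probabilities reach
  ~0.88), uniformly random pairs, 20 replicates per n ∈ {200, 1000, 5000};
  reports per-item bias and RMSE. The four-item design is used because its
  information content at n = 5000 puts every worth's sampling error
  comfortably below 0.1; a ten-item catalogue at the same n sits at the
  0.1 boundary by the Fisher-information bound alone, which would test the
  design rather than the estimator.
* **Model selection** (`model_selection_experiment`): 200 full study-sized
  replicates (48 + 225 fitted choices each), forecaster agents with default
  worths; truth either constant (phase_shift 0) or early-shifted by 1.5
  log-units. Reports the rate at which AIC picks each model.
* **End-to-end contrast**: forecaster vs trial-and-error agents differing in
  nothing else, with *equal* ingredient worths (all 0) and interaction sd
  1.5. Equal ingredient worths isolate the dichotomy: a trial-and-error
  agent then chooses exactly at chance in the pre-taste window (consistency
  proportion 0.5 by construction) while a forecaster is driven by the mix
  interaction spread; and the early/late worth change appears only under
  trial-and-error, so AIC's model choice flips between the two agents.

## Known limitations

* The across-conditions and within-concealed comparisons assume the
  schedule's 2 + 2 condition split; irregular schedules reduce eligible
  pairs, which are reported rather than silently dropped.
* Exact permutation significance for tau-b is genuinely exact only for
  n ≤ 8; at the study's n = 10 it is a seeded Monte-Carlo estimate with
  ~0.15 % standard error at p ≈ 0.01.
* BIC's n is the number of choices; with blocked trials the effective
  information per choice may be smaller if choices within a block are
  dependent, a dependence neither the models nor the simulator include.
* The BT worth cap of ±20 makes separated items' AIC/BIC finite but
  arbitrary to the cap's value; comparisons involving separated slots should
  lean on the reported warnings.
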