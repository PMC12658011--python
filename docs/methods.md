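# Methods

## Task structure and indifference extraction

The task is fixed: seven social distances N ∈ {1, 2, 5, 10, 20, 50, 100},
nine trials per distance, selfish amounts \$155 → \$75 in \$10 steps, and a
constant generous option (both parties receive \$75). The indifference
point of a block is the selfish amount offered on the first trial with a
generous choice; all-selfish blocks are censored at \$75 and all-generous
blocks at \$155, and v = indifference − 75.

Non-monotone blocks (a selfish choice after the first generous one) have no
canonical indifference point. We use the first switch and set a violation
flag; flagged participants are counted in the run log but retained, since
excluding them is an analysis decision the pipeline should surface, not
make silently. Trials are assumed presented in fixed descending order;
only display, not extraction, would change under randomization. For
monotone blocks the rule reduces to the closed form
indifference = max(75, 65 + 10·g) with g the number of generous choices,
which the test suite verifies against an exhaustive scan of all 2⁹ choice
vectors.

## Discount model fitting

Per participant, v is regressed on N by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) under one of
three families: hyperbolic V0/(1+kN), exponential V0·e^(−kN), linear
max(V0 − kN, 0).

* **V0** is a free parameter in (0, 160] by default, jointly estimated with
  k; a config switch fixes it (e.g. at 85) for studies that treat the
  undiscounted value as known. Both modes are provided because published
  analyses rarely state which convention was used.
* **k floor = 10⁻⁶** keeps logk finite for non-discounters (flat v = 80
  profiles); floored fits are flagged and counted. k is bounded above at
  10⁴ (hyperbolic/exponential); all-zero profiles pin k there and raise a
  degenerate-profile flag.
* **Multistart**: five k starting values log-spaced in [10⁻⁴, 1] (linear
  slopes start on their own dollar scale); lowest RSS wins, ties broken
  toward smaller k.
* **AIC** uses the Gaussian profile-likelihood form n·ln(RSS/n) + 2p with
  shared additive constants dropped — valid for comparing families fit to
  identical observations; RSS is floored at 10⁻¹² so exact fits keep AIC
  finite. AICc is available by config. Akaike weights are
  exp(−Δᵢ/2)/Σ exp(−Δⱼ/2).
* **AUC** is the trapezoidal area of v over the seven observed distances,
  normalized by (N span) × (maximum v = 80). No synthetic N = 0 anchor is
  added: the statistic summarizes exactly the observed curve, so the
  all-generous profile scores 1 and the all-selfish profile 0.

## Synthetic cohort generator

The generator emulates the statistical structure of a two-group
(control vs. very-high-psychopathy) community study:

* TriPM totals: Normal(55.86, 19.90) controls, Normal(122.25, 16.92) high,
  clipped to the instrument's 0–174 range; subscales are the total/3 plus
  correlated, sum-zero residuals, so they add exactly to the total.
* Latent logk: Normal(−4.0, 1.65) controls, Normal(−2.5, 1.65) high — a
  standardized group difference of 0.909, centered inside the window the
  task can measure (roughly logk ∈ [−7.3, 2]).
* STAB antisocial behavior: 62.8 + 35·[high] + 1.0·logk + N(0, 18), which
  plants a nonzero indirect group→logk→STAB path (planted ACME = 1.5,
  proportion mediated ≈ 0.04) while matching group means near 59/95.
* Covariates: age (group-specific Normals clipped to 18–79), gender
  (44/52/4% male/female/other), ordinal household income 1–8 with a 3%
  "don't know" mass, fluid intelligence 0–13, attention-check failures
  (≈ 1.7% fail ≥ 2 of 4), and a lifetime-crime flag with logit
  −0.336 + 2.16·[high] (unadjusted OR ≈ 8.7).
* Choices: P(generous) = logistic((v_N − forgone)/τ) with v_N from the
  hyperbolic curve at V0 = 80 and temperature τ = \$2 by default;
  τ = 0 is the deterministic threshold rule. The \$0-sacrifice final trial
  is generous whenever v_N > 0 — costless sharing — so extreme discounters
  produce v = 0 profiles rather than literally all-selfish blocks.

Group labels are assigned by construction (sizes exactly as configured);
`assign_group` separately implements cutoff-based assignment
(high iff TriPM ≥ the gender-specific cutoff, default 105 male / 91
female-or-other, with the boundary score assigned high).

What the generator does **not** emulate: item-level questionnaire
responses, recruitment heterogeneity, non-monotone response styles beyond
softmax noise, missing data other than "don't know" income, or
heteroscedastic outcome noise. Passing tests therefore demonstrate that
the pipeline recovers known structure under clean parametric conditions,
not that it is robust to every pathology of real survey data.

A fundamental limit of the design: the nine-trial grid quantizes v to \$10
steps, and no nondegenerate (V0, k) places v on that grid at all seven
distances, so exact round-trip recovery of an arbitrary latent k is
impossible even at temperature 0. The closed-loop tests assert the
attainable version — the fitted hyperbola tracks the latent one within
1.25 grid steps at every N, boundary profiles are recovered exactly, and
noisy recovery at σ = \$5 keeps the latent/estimated logk correlation
above 0.9.

## Inference conventions

* Two-tailed tests everywhere; Welch t-tests (Satterthwaite df) for
  continuous group comparisons; Pearson chi-squared without continuity
  correction for categorical ones.
* Cohen's d uses the pooled SD even alongside the Welch statistic, with a
  normal-approximation 95% CI — the common reporting convention when the
  original CI method is unstated.
* "Std. B" z-scores **all** variables, including the binary group and
  gender indicators, before refitting; this is the convention consistent
  with published tables in which a ~1.56-unit raw group coefficient maps
  to ≈ 0.38 standardized. Product terms are formed from the z-scored
  factors and not re-standardized.
* Gender enters as a male indicator with female/other as reference; income
  is ordinal numeric 1–8 after "don't know" entries are recoded to the
  round-half-up mean bracket of the full sample.
* Logistic odds ratios are ML estimates with Wald 95% CIs; near-complete
  separation raises an error suggesting penalized estimation rather than
  returning a divergent estimate.

## Mediation

Mediator and outcome models are linear OLS with no treatment–mediator
interaction, so per parameter draw ACME = a·b·Δt, ADE = c′·Δt and
total = ACME + ADE identically. Default inference is quasi-Bayesian
(1000 draws from each model's asymptotic multivariate normal); a row
bootstrap is available. CIs are 2.5/97.5 percentiles; p-values are
2·min(P(draw ≤ 0), P(draw ≥ 0)) floored at 2/sims; the proportion mediated
is summarized by the median across draws because the ratio distribution is
heavy-tailed. The treatment contrast is 0→1 for the binary group and
±1 SD for continuous exposures. Sims count and CI method are surfaced in
the output metadata as package defaults, since source analyses typically
leave them unreported.

## Reliability and robustness

* Cronbach's α from the standard variance decomposition. The pipeline
  applies it to the three TriPM subscale components (item-level data are
  out of scope), labelled as such in the output.
* ICC(1,1): one-way random-effects, single rater, absolute agreement, with
  F-distribution 95% bounds. The pipeline exercises it on a synthetic
  two-rater table (latent severity rescaled from TriPM plus rater noise)
  for a 44-participant high-group subsample, mirroring a double-rated
  follow-up interview; the table is synthetic and marked so in the output.
* k-fold CV: seeded permutation, fold sizes within 1, per-fold OLS refits,
  pooled out-of-fold R².
* Propensity matching: logistic PS on the covariates, greedy 1:1
  nearest-neighbor on the logit PS without replacement, caliper 0.2 logit
  SDs, treated units matched hardest-first (descending PS, id tie-break) —
  the most common convention where the original specification is
  unpublished. Standardized mean differences are reported before and
  after, and the group→logk model is refit on the matched subsample.

## Problem sizes and numerical choices

The default synthetic cohort is 427 + 288 (the study-scale configuration);
test-suite simulations use smaller cohorts (tens to hundreds of
participants, 100-replicate model-selection sweeps, 200-replicate mediation
coverage runs) chosen so each property is measured with comfortable
Monte-Carlo margin while the whole suite stays quick to run. The
family-selection sweep draws generating parameters from ranges where the
three families are identifiable on the seven-distance grid at \$5 noise
(e.g. exponential k ∈ 10^[−1.2, −0.8]); outside such ranges exponential
and hyperbolic curves genuinely coincide to within the noise, and no
selector could separate them. Determinism is a contract: one integer seed
drives cohort generation, choice noise, mediation draws, CV partitions and
the synthetic rater table, and byte-identical outputs (timestamps isolated
to the run log) are enforced by test.
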