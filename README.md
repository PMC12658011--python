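# socdisc

Analysis toolkit for **social discounting** studies: experiments in which a
participant repeatedly chooses between keeping an amount of money and
splitting it with another person at social distance *N* (1 = closest other,
100 = a stranger). The package turns raw binary choices into
per-participant discounting parameters and carries them through group
inference, mediation of antisocial behavior, reliability statistics and
robustness checks. It is aimed at researchers in behavioral economics and
psychopathology who run this seven-distance, nine-trial task design.

## The model

For each social distance *N* the nine choices (keep \$155…\$75 vs. split so
both get \$75) yield an **indifference point** — the selfish amount at the
first selfish→generous switch, censored at \$75 (never shares) and \$155
(always shares). The **amount willing to forgo** is
*v* = indifference − 75 ∈ [0, 80]. Generosity declines hyperbolically with
social distance:

```
v(N) = V0 / (1 + k·N)
```

where *V0* is the undiscounted value and *k* > 0 the social discount rate;
participants are summarized by **logk** = ln *k* (higher = steeper
devaluation of distant others) and by the model-agnostic normalized
trapezoidal **AUC** ∈ [0, 1] (higher = more overall generosity).
Hyperbolic, exponential (V0·e^(−kN)) and linear (V0 − kN) families are
compared by AIC with Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2).

Downstream, the package provides Welch *t*-tests with Cohen's *d*,
chi-squared tests, OLS with fully standardized coefficients (every
variable, binary indicators included, z-scored), moderation (product
terms), logistic odds ratios, Bonferroni thresholds, quasi-Bayesian and
bootstrap **mediation** (ACME / ADE / total effect / proportion mediated),
Cronbach's α, one-way random-effects ICC(1,1), 10-fold cross-validation,
and greedy caliper propensity-score matching.

A fully parameterized **synthetic cohort generator** emulates the
statistical structure such studies assume — group-separated psychopathy
(TriPM) scores, a latent per-participant logk with a standardized group
difference ≈ 0.9, an antisocial-behavior (STAB) outcome partially mediated
by logk, demographic covariates, and softmax choice behavior — so the whole
pipeline is testable without any data download.

## Worked example

```
python -m socdisc all --seed 42 --out run_out
```

generates the default synthetic cohort (427 controls, 288 high-psychopathy)
and runs every stage. `run_out/summary.txt` starts:

```
n analyzed: 699 (high: 279, control: 420)
social distances: 1, 2, 5, 10, 20, 50, 100
best-fitting family (pooled AIC): hyperbolic
Akaike weights: hyperbolic=1.000, exponential=0.000, linear=0.000
group -> logk: b=1.999 (se 0.168), Std. B=0.447, p=9.03e-30
TriPM -> logk: b=0.0208, Std. B=0.366, p=9.76e-21
mediation (group -> logk -> STAB): ACME=3.079 [1.644, 4.584], p=0.002
```

Reading this: 16 of 715 generated participants were excluded for failing
two or more attention checks; the pooled AIC comparison puts essentially
all Akaike weight on the hyperbolic family; the high-psychopathy group's
logk is about 2 natural-log units higher than controls' (steeper
discounting) after adjusting for age, gender, income and fluid
intelligence; and roughly 3 STAB points of the 36-point group difference in
antisocial behavior flow through discounting (the indirect ACME path), the
rest being direct. Full tables (`table1.csv`, `table3.csv`, `table4.csv`,
the AUC multiverse twins, moderation, matching and CV outputs) and
`discounting_curves.png` land in the same directory, all stamped with the
configuration hash and seed.

The same stages are available as a library:

```python
import socdisc as sd

records = sd.generate_cohort(sd.CohortConfig(n_control=100, n_high=80, seed=7))
profile = sd.build_profile(records[0].choice_blocks)
fit = sd.fit_participant(profile)          # hyperbolic k, logk, AIC
auc = sd.compute_auc(profile).auc
```

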