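# Methods notes

This note records the statistical conventions, parameter defaults and
numerical choices implemented in `jaderpv`, and the limits of the synthetic
data generator.

## Report database

Analyses run over a four-table, case-ID-keyed database in the JADER layout
(see README). Invariants enforced at read time: unique case IDs in DEMO;
every DRUG/REAC/HIST row references a DEMO case. Duplicate DEMO IDs are
always an error (the layout gives no safe deduplication rule); orphan child
rows either raise (strict mode, default) or are dropped and enumerated in a
validation report. Dates that do not parse under the active dialect —
including partial year–month values — become missing. The unit of counting
throughout is the *report*: a case contributes at most once to any cell of
any contingency table, regardless of how many DRUG or REAC rows it carries.

## Outcome and exposure definitions

* **AKI outcome** — 19 MedDRA preferred terms, matched against REAC only.
* **Sepsis covariate** — 22 preferred terms, matched against REAC ∪ HIST.
* **Drug exposure** — any role code (suspected, concomitant, interacting).
  Names are normalized (case folding, whitespace collapse) and resolved
  through an explicit alias table; there is no fuzzy matching, so unmapped
  names stay out of the anti-infective counts rather than being guessed.
* **Anti-infective count** — number of *distinct canonical substances*
  flagged anti-infective on the report. Duplicated rows and spelling
  aliases of one substance count once; a combination product contributes to
  each of its mapped ATC classes but counts as one substance.

## Reporting odds ratio

`ROR = (a/b)/(c/d)` with the Woolf interval
`exp(ln ROR ± z·sqrt(1/a+1/b+1/c+1/d))`, z = 1.96 for every 95% interval in
the package. No continuity (Haldane–Anscombe) correction is applied.
The estimate is suppressed — `defined=False`, NaN, rendered "–" — when any
cell is zero **or** fewer than `min_cases` (default 2) exposed cases carry
the outcome; this is the reporting convention of published
disproportionality tables. A *signal* is a defined ROR with lower CI bound
> 1. Published summary tables can be reproduced by rebuilding each 2×2
table from its margins (`ContingencyTable.from_margins`). The ROR measures
reporting disproportionality, not incidence or relative risk.

Stratified tables treat stratum membership as the exposure (stratum vs all
other reports). Age strata are decades, with the youngest (≤19) and oldest
(≥90) strata each pooling two decade bands of the raw data.

## Propensity-score matching

* Treatment: combination therapy (≥2 distinct anti-infectives); control:
  monotherapy (exactly 1). Reports with zero anti-infectives are outside
  both arms.
* Model: maximum-likelihood logistic regression of treatment on age,
  weight, height (10-unit band midpoints used as continuous values; the
  midpoint of band "a–b" is (a+b+1)/2, of "≥x" is x+5) and sepsis. Sex is
  deliberately excluded from the model but always reported in the balance
  table. Complete-case analysis: reports with any unknown model covariate
  are excluded and the count recorded.
* Matching: greedy nearest-neighbour 1:1 without replacement on logit(PS),
  caliper = 0.2 × sample SD (ddof = 1) of the pooled logit-PS values.
  Treated cases are processed in a seeded random order applied to the
  *sorted* ID list, so results are independent of input row order and fully
  reproducible given the seed. Distance ties break toward the lower-logit
  control.
* Balance: SMD `|p1−p2|/sqrt((p1(1−p1)+p2(1−p2))/2)` for binary covariates
  and `|m1−m2|/sqrt((s1²+s2²)/2)` (sample variances) for binned numeric
  covariates; < 0.1 is considered adequate. Multi-level factors other than
  the reported covariates are not summarized.
* Post-matching effect: each matched arm is compared against the remainder
  of the database with the same crude-ROR machinery ("adjusted ROR"). This
  is a pragmatic disproportionality contrast between balanced arms, not a
  causal effect estimate.

## Time to onset

* Observation: one per (report, drug-in-class, route) with a complete start
  date and outcome onset date, using the earliest start per drug and the
  earliest outcome onset per report; t = onset − start in whole days,
  restricted to [0, 90]. Negative differences (onset before start) are
  excluded.
* Summaries (median, Q1, Q3) use the raw integer days with
  linear-interpolation (type-7) quantiles.
* Weibull fit: two-parameter MLE over (log α, log β), Nelder–Mead followed
  by BFGS; Wald CIs from the observed information matrix on the log scale,
  exponentiated. Day-0 events lie outside the Weibull support; by default
  0.5 is added to every onset time *for fitting only* (`shift0.5`);
  alternatives are `exclude` (drop zeros — appropriate for
  continuous-valued samples) and `add1`. Fits require ≥ `min_n` (default
  10) usable observations and non-degenerate spread; smaller cells report
  the median summary only. No censoring model: only complete in-window
  events enter the likelihood.
* Hazard classification from the β CI: lower bound > 1 → increasing hazard
  (wear-out failure); upper bound < 1 → decreasing hazard (initial
  failure); otherwise constant hazard (random failure).

## Synthetic generator

Generation is a pure function of (config, seed): independent named random
sub-streams (demographics, sepsis, exposure, outcome, dates, onset,
missingness, events) keep draws stable when unrelated features change.
The model, in order:

1. demographics (decade age bands, sex, latent-normal height/weight binned
   to 10-unit bands and scaled for juveniles);
2. sepsis flag (Bernoulli);
3. drug exposure per catalog drug: marginal prevalence, optionally shifted
   on the logit scale for anti-infectives by allocation coefficients
   (sepsis, age, sex) and by a two-component polypharmacy mixture
   (`heavy_fraction`, `heavy_multiplier`); an `exclusive_drugs` mode for
   onset demos assigns at most one drug per report;
4. adverse-event outcome from a logistic model: baseline + per-drug
   log-odds + pairwise interaction terms + combination-therapy term +
   sepsis and age effects;
5. a culprit drug per event (uniform over its anti-infectives when any)
   whose Weibull(α, β) delay, floored to whole days, sets the onset date;
   configurable fractions of missing start/onset dates.

The ground-truth sidecar records realized outcome/exposure/sepsis vectors,
the culprit assignment and the true parameters. The `jader-like` preset is
numerically anchored to the marginal structure of a national reporting
database (≈4–5% event rate, ≈5.6% of reports with exactly one
anti-infective, ≈1.8% with two or more). Limits: exposures are independent
across drugs given the mixture component and allocation shift; one primary
event per report; no reporting-delay or under-reporting model; onset dates
exist only for the culprit drug's timeline.

## Problem sizes and statistical checks

Defaults used by the test suite and the acceptance script, chosen so Monte
Carlo noise is far below the tolerances being asserted:

* Weibull recovery: 10,000 draws (relative SE of both parameters < 1.3%,
  asserted within 2%).
* Null-interval coverage: 500–1,000 replicate databases of 5,000 reports
  (binomial SE of the coverage estimate ≤ 1%, asserted within 93–97%).
* Balance recovery: 200 replicates of 10,000 reports; planted confounding
  yields pre-matching max SMD > 0.1 in every replicate, and matching must
  bring all SMDs below 0.1 in ≥ 95% of replicates.
* Oracle equivalence: the vectorized 2×2 builder vs a per-case double loop
  (exact), the Weibull MLE vs an iterated grid search (1e-4) and an
  independent survival library (1e-4 relative), and the logistic fit vs a
  generic gradient-based optimizer of the Bernoulli likelihood (1e-6).
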