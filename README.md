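# jaderpv

Pharmacovigilance signal analysis for JADER-format spontaneous adverse-event
reports, focused on anti-infective drugs and acute kidney injury (AKI):

* **Disproportionality analysis** — crude reporting odds ratios (ROR) with
  Woolf 95% confidence intervals per drug, ATC class, drug pair and
  demographic stratum;
* **Propensity-score matching** — logistic treatment-allocation model and
  greedy 1:1 caliper matching to compare anti-infective monotherapy against
  combination therapy with covariate balance (standardized mean difference)
  diagnostics;
* **Time-to-onset profiling** — median/IQR onset days and maximum-likelihood
  Weibull fits whose shape parameter classifies the hazard over time;
* **Synthetic data generator** — a seeded, fully reproducible generator of
  JADER-layout databases with known ground truth, so every stage of the
  pipeline is testable without downloading any external data.

## Data model

A database is four delimited tables keyed by an opaque case (report) ID:

| table | one row per | columns |
|-------|-------------|---------|
| DEMO | report | sex, age band (decades), height/weight bands (10-unit bins), reporting quarter |
| DRUG | drug × report | drug name, role code (suspected/concomitant/interacting), route (po/iv/…), start date |
| REAC | adverse event × report | MedDRA preferred-term (PT) code and name, onset date |
| HIST | primary disease × report | PT code |

The AKI outcome is a fixed set of 19 MedDRA preferred terms read from REAC;
the sepsis covariate is a set of 22 terms read from REAC or HIST. Drug names
map to ATC codes and an anti-infective flag through a bundled, extensible
CSV map (36 anti-infective ATC classes); the per-report anti-infective count
is the number of *distinct* substances after alias normalization.

## Statistics

For an exposure E and outcome O counted over reports,

```
              outcome   no outcome
exposed          a          b
non-exposed      c          d

ROR = (a/b) / (c/d),   95% CI = exp( ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d) )
```

The ROR is suppressed ("–") when any cell is empty or fewer than two exposed
cases carry the outcome; a *signal* is a defined ROR whose lower CI bound
exceeds 1. Matching runs on the logit of the propensity score with a caliper
of 0.2 × SD of the pooled logits; balance is adequate when every SMD is
below 0.1. Onset times t = onset − first start date (days, 0–90 window) are
fitted with the Weibull density `f(t) = (β/α)(t/α)^(β−1) exp(−(t/α)^β)`;
the 95% CI of the shape β classifies the hazard: entirely below 1 →
decreasing ("initial failure"), containing 1 → constant ("random failure"),
entirely above 1 → increasing ("wear-out failure").

## Worked example

The `run-all` command generates (or reads) a database and runs every stage.
With the bundled `jader-like` preset — 50,000 synthetic reports whose
marginal structure mimics a national spontaneous-reporting extract:

```
$ jaderpv run-all --seed 1 --out-dir results/run
pipeline complete; manifest at results/run/manifest.json
stage rows: {'reports': 50000, 'aki_cases': 2573, 'class_ror': 36,
 'combination_ror': 3, 'stratified_ror': 14, 'matched_pairs': 950,
 'onset_profile': 22, 'onset_events': 462}
```

Top signalled ATC classes in `results/run/class_ror.csv`:

```
label                                                  class_label  total_n  case_n  ror  ci_low  ci_high
J01CR Combinations of penicillins, incl. beta-lactamase inhibitors      528     146 7.41    6.10     9.00
J01XA                                  Glycopeptide antibacterials      555     132 6.01    4.92     7.34
J02AX                          Other antimycotics for systemic use      551     119 5.28    4.29     6.49
J01DH                                                  Carbapenems      518     105 4.84    3.89     6.02
```

The vancomycin + tazobactam/piperacillin pair (`combination_ror.csv`) shows
the planted supra-additive combination risk:

```
                               label  total_n  case_n   ror  ci_low  ci_high  signal
                          vancomycin      555     132  6.01    4.92     7.34    True
             tazobactam/piperacillin      528     146  7.41    6.10     9.00    True
vancomycin + tazobactam/piperacillin       51      31 28.91   16.45    50.79    True
```

Propensity-matched mono- vs combination-therapy arms (`adjusted_ror.csv`,
950 matched pairs, all post-matching SMDs < 0.1):

```
        arm  ror  ci_low  ci_high  case_n
monotherapy 1.77    1.40     2.22      82
combination 6.73    5.78     7.84     239
```

Pooled time-to-onset profile (`onset_profile.csv`):

```
atc_class route   n  median   q1    q3  alpha  beta  beta_lo  beta_hi          hazard
    Total    po 158     6.0 2.00 11.00   9.08  1.06     0.94     1.20  random_failure
    Total    iv 304     6.0 3.00 11.25   9.50  1.13     1.04     1.24 wearout_failure
```

The same stages are available individually (`jaderpv simulate`, `jaderpv
ror`, `jaderpv match`, `jaderpv tto`) and as a Python API:

```python
from jaderpv import (ContingencyTable, crude_ror, generate, preset,
                     match_therapy_arms, weibull_mle)

res = crude_ror(ContingencyTable.from_margins(
    n_total=534_688, n_outcome=21_727, n_exposed=5101, n_exposed_outcome=723))
res.rounded()          # (4.0, 3.69, 4.33)
res.signal             # True
```

Given the same inputs and `--seed`, every output file is byte-identical
between runs; `manifest.json` records the configuration hash, seed, input
digests and per-stage row counts.

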