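# rossercea

Cost-utility analysis of internet-based depression-prevention trials using
Rosser Index QALY valuation.

## The problem

Internet-delivered self-help programs for depression (automated CBT plus
psychoeducation) are cheap to run but costly to develop, and translating an
existing program into another language is a candidate shortcut.  Deciding
whether translation is worth it requires converting trial outcomes measured
on symptom scales into a common health-economic currency — quality-adjusted
life years (QALYs) — and setting the gain against the project's costs.

`rossercea` implements that full chain for a two-arm pre/post trial whose
outcomes are CES-D (depression symptoms, 0–60) and K10 (psychological
distress, 10–50) totals:

1. **Health-state classification.** CES-D scores map to Rosser disability
   categories I–VI and K10 scores to Rosser distress categories A–D, giving
   each participant a health state in a 6 × 4 matrix.  Category bands are
   half-open real intervals, so subgroup *means* classify the same way as
   raw integer scores.
2. **Utility valuation.** Each state carries a fixed utility weight
   *w* ∈ [0, 1] from the Rosser valuation matrix (1 = healthy, 0 = dead).
   A group's total QOL at a timepoint is Σ<sub>s</sub> n<sub>s</sub> w<sub>s</sub>;
   the mean utility change is ΔH = (QOL<sub>post</sub> − QOL<sub>pre</sub>)/n,
   and the treatment effect is the between-arm contrast
   ΔH<sub>int</sub> − ΔH<sub>ctl</sub>.
3. **12-month extrapolation.** An 8-week ΔH is scaled to one year with a
   *change factor* — the ratio of posttest to 12-month CES-D means from a
   reference trial of the same programs (gains are multiplied by the factor,
   losses by its reciprocal).  QALY gain = ΔH × T, and
   persons-per-QALY = ⌈1 / QALY gain⌉.
4. **Costs and cost-effectiveness.** Development/maintenance schedules are
   amortized over an operating period; the cost-effectiveness ratio is
   CER = annual cost / QALYs gained, with break-even treatment numbers and
   return-on-investment multiples.
5. **Sensitivity analysis.** Five deterministic scenarios vary the
   classification granularity (per participant, per severity subgroup, per
   arm) and the assumptions about the control group (frozen, or improving
   at 12 months).

A synthetic-trial generator (`generate_trial`) draws participant records
from configurable moments, and `generate_from_matrix` regenerates exact
participant-level fixtures from published health-state count matrices.

## Worked example

The packaged defaults reproduce the published Norwegian translated-program
trial analysis from its printed summary tables (intervention n=43, control
n=59 completers):

```sh
$ rossercea qol
intervention pre: total 40.82 (mean 0.95, n=43)
intervention post: total 41.02 (mean 0.95, n=43)
intervention ΔH: 0.0048
control pre: total 56.86 (mean 0.96, n=59)
control post: total 56.06 (mean 0.95, n=59)
control ΔH: -0.0135
between-groups ΔH: 0.0183
```

The intervention arm's mean utility rises by 0.0048 over 8 weeks while the
control arm deteriorates, for a between-group gain of ≈0.018 — about 1.8%
of a full-health year per treated completer.  The same numbers are available
programmatically:

```python
from rossercea import (build_descriptive_matrix, default_valuation_matrix,
                       total_qol, delta_h)
from rossercea.reference import reference_records

records = reference_records()          # rebuilt from the published counts
valuation = default_valuation_matrix()
pre = total_qol(build_descriptive_matrix(records, "intervention", "pre"), valuation)
post = total_qol(build_descriptive_matrix(records, "intervention", "post"), valuation)
print(delta_h(pre, post).value)        # 0.004790697674418676
```

Cost side and sensitivity:

```sh
$ rossercea costs
translation_norway: per-year [118.9, 23.0, 23.0] mean 55.0 (€1000)
development_australia: per-year [524.1, 44.7, 44.7] mean 204.5 (€1000)

$ rossercea sensitivity --scenarios 1,2,3
 scenario                     description  ...  dh_between_display
        1 main analysis (per participant)  ...               0.018
        2                  subgroup means  ...               0.012
        3                 condition means  ...               0.040
```

Translating the program costs €55,000/year amortized — about 27% of
developing it from scratch — and at the UK £30,000-per-QALY valuation,
treating 1000 persons per year saves €481,000, gains 16 QALYs and yields a
CER of €3432 per QALY (`rossercea cea`).

`rossercea run` executes the whole pipeline and writes `report.json` with
every rounded display value next to its unrounded counterpart, plus the
per-arm health-state matrices as CSV.  `rossercea simulate` writes a
synthetic trial CSV at the study's default conditions for use as pipeline
input.

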