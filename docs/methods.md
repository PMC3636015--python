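# Methods

## Model

The package estimates the health-economic value of a two-arm (intervention
vs waiting-list control) pre/post trial of an internet-based
depression-prevention program.  The causal quantity is the between-arm
difference in mean utility change (ΔH), obtained by classifying every
completer into a Rosser health state at both assessments and valuing states
with the Rosser utility matrix.

**Classification.**  The disability dimension (I–VI) is driven by the CES-D
total score, the distress dimension (A–D) by the K10 total score.  Default
bands (lower-inclusive, upper-exclusive; topmost band closed at the
instrument maximum):

| CES-D | disability | | K10 | distress |
|---|---|---|---|---|
| [0, 16) | I | | [10, 20) | A |
| [16, 24) | II | | [20, 25) | B |
| [24, 34) | III | | [25, 30) | C |
| [34, 43) | IV | | [30, 50] | D |
| [43, 53) | V | | | |
| [53, 60] | VI | | | |

Half-open *real* intervals extend the published integer bands so that
non-integer subgroup means (CES-D 32.7, K10 24.5, …) classify with the same
rule as raw scores — no per-case special handling.  Rosser disability
categories VII–VIII (confined to bed, unconscious) are not meaningful for a
symptom-scale mapping and are rejected at construction.  Bands are
configurable (`CategoryScheme`).

**Distress at posttest.**  Whether the posttest distress category should
come from a posttest K10 or always from baseline is genuinely ambiguous in
the source analysis (its state matrices show distress moving between
timepoints, while the measure description mentions only pre-assessment
K10).  Both behaviours are implemented behind
`distress_source = per_timepoint | baseline_only`; `per_timepoint` (with
baseline fallback when the posttest K10 is missing) is the default because
it is the only behaviour consistent with the published matrices.

**Valuation and ΔH.**  Total QOL = Σ counts × weights (compensated
summation); ΔH = (post − pre)/n from *unrounded* totals — the published
intervention value 0.0048 is only obtainable as 0.206/43, not from the
2-decimal displayed totals.  Stored values are never rounded; display
rounding is half-up at the printed precision, with a 4-guard-digit snap to
absorb binary-float noise at exact halves (e.g. the pretest total 40.815).

**Extrapolation.**  Change factors are posttest/12-month CES-D means from a
12-month reference trial of the same programs: 15.9/14.1 ≈ 1.128
(intervention), 19.5/16.4 ≈ 1.189 (control), shipped as the
`mackinnon_12m` defaults and kept at full precision (published 1.127/1.19
are display truncations).  A non-negative ΔH is multiplied by the factor; a
negative ΔH by its reciprocal, encoding the expectation that an untreated,
deteriorated group recovers over a year, which shrinks the between-group
gap.  QALY gain = ΔH × T (default horizon T = 1 year, no discounting
beyond the single factor).  Persons-per-QALY and break-even counts use
ceilings (people are indivisible); return multiples round half-up.

**Costs.**  All monetary arithmetic is in €1000 at full precision.
Amortization assigns the one-off development cost to year 1 and recurring
maintenance/service fees to every operating year (default 3 years); the
mean annual cost is the grand total divided by operating years.  The
packaged schedules are the published € figures (translation 95.9 + 14.0 +
9.0; development 479.4 + 44.7).  The generic inflation
(amount × (1+r)^years) and currency-conversion operations (round *up* to a
configurable granularity — conservative costing) exist for new analyses;
the raw NOK/AUD amounts behind the packaged € figures were never published,
so these operations are verified by property tests and direct evaluation
rather than against published figures.  Two distinct "translation vs
development" ratios exist and are exposed separately: mean-annual costs
(55.0/204.5 ≈ 27%) and raw development outlays (95.9/479.4 ≈ 20%).

**Cost-effectiveness.**  With v = savings per QALY (€1000), m =
persons-per-QALY, c = mean annual cost (€1000), N = persons treated/year:
savings per person = v/m − c/N; total savings = that × N; QALYs gained =
total/v; CER = c/QALYs (reported in €).  Nothing is rounded inside the
chain.  The CE grid enters annual costs as whole €1000 (204, 55 — Python's
round, half-even at the .5): the published grid figures only reproduce from
these whole-number inputs.  Dominated rows (no QALYs gained) carry a null
CER rather than an error inside the grid; the scalar `cer()` raises.

## Sensitivity scenarios

1. **Per participant** — the main analysis.
2. **Subgroup means** — each CES-D severity subgroup (subclinical,
   mild/moderate, moderate/severe) occupies one state per timepoint.
   Disability is fixed by the *baseline* subgroup label (I, II, and from
   the baseline CES-D mean for moderate/severe); distress follows the
   timepoint's K10 subgroup mean.  Arm totals weight states by the
   timepoint's own subgroup sizes, and the ΔH denominator is the whole-arm
   n — the only weighting that reproduces the published 0.008 / −0.004.
3. **Condition means** — one state per arm.  When the state does not move
   between timepoints, the utility change is half the C→D weight gap at the
   arm's disability level, signed by the CES-D change direction.  The
   half-gap is rounded to 2 decimals before use (0.02 at disability II),
   the granularity at which this judgment-based adjustment was defined;
   this reproduces all three published values (±0.020, 0.040), which the
   unrounded 0.0205 cannot (it would display 0.041 between groups).
   `exact_half_step=True` keeps the unrounded variant.
4. **Frozen control** — the control arm's change is forced to zero, so the
   between-group gain equals the intervention-only gain.
5. **Control gain** — each participant's 12-month CES-D is predicted as
   pretest/factor (defaults 1.546 intervention, 1.317 control) and
   re-classified; distress keeps the baseline K10 category because no
   12-month distress prediction rule exists.  Results are 12-month values
   by construction.  A `mode="posttest"` option applies the factor to
   posttest scores instead.

Extrapolated scenario-2/3 cells are computed by the standard rule but the
source's exact rounding path for those cells is unrecoverable, so they are
reported, not asserted.

## Effect sizes

Pre–post change contrasts (positive = improvement) are summarized per arm;
the between-group effect is Hedges' g = J·(Δ̄ₐ − Δ̄ᵦ)/s_pooled with
J = 1 − 3/(4N − 9) (one common small-sample convention; inert at 2-decimal
display for these sample sizes) and SE ≈ √(N/(nₐnᵦ) + g²/2N).  Descriptive
only — the economics consume ΔH, not significance tests.

## Synthetic data

`generate_trial` emulates the study conditions: enrolment 81/82 per arm,
completer retention 43/81 and 59/82, baseline CES-D 22.6 (SD 10.9) / 18.5
(SD 9.6), K10 33.2 (SD 5.5/5.0), change scores +4.1 (SD 10.4) / −3.0
(SD 9.1).  Baselines are truncated normals within the instrument ranges,
coupled by a Gaussian copula at correlation 0.6 (a typical
depression–distress association in community samples; neither scale's
cross-correlation was published).  The posttest is baseline minus a normal
change draw, clipped to range; the posttest K10 tracks the CES-D change
through the correlation slope plus independent noise.  One integer seed
drives a single `numpy` Generator.

What it does *not* emulate: help-seeking behaviour, adherence/module
completion, recruitment, or non-normal score distributions (floor effects
are produced only by truncation).  Consequently, passing moment-recovery
tests shows internal consistency of the generator, not realism of real
trial data; moment checks are run at configurations away from the
instrument bounds, since clipping near a bound shifts moments by
construction.

`generate_from_matrix` inverts the descriptive cross-tabulation using
category-interval midpoints, so matrix → records → matrix is the identity.
Because only per-timepoint marginals were published, the pre→post pairing
of states is a greedy convention; every quantity the package asserts
(totals, ΔH, scenario results) depends on the marginals alone, so the
pairing is inert.  The regenerated dataset is *synthetic* at the
participant level: per-participant quantities that depend on joint pre/post
scores (e.g. change-score SDs, Hedges' g) do not reproduce the original
raw-data values and are not asserted against them.

## Numerical choices

- Compensated (`math.fsum`) summation for all totals.
- Display rounding: decimal half-up with a half-even snap at 4 guard
  digits; ceilings guarded against float noise at 1e-9.
- Valuation matrices validate range, the 1.000/0.000 anchor states, and
  monotonicity (non-increasing along distress and disability); descriptive
  matrices validate non-negative integer counts and n ≥ 1.
- Degenerate inputs raise: empty record sets, mismatched pre/post n,
  non-positive factors/horizons/costs, zero pooled SD.

## Known limitations

- The control arm's posttest state counts imply a total QOL of 56.06; the
  source prints 55.96 (and a control ΔH of −0.015 where the counts imply
  −0.0135) — a probable misprint in one published cell.  The package
  reproduces what the printed counts imply, and its main-analysis
  between-group ΔH is accordingly 0.018 unextrapolated.
- Average (not incremental) CERs only; no probabilistic sensitivity
  analysis or CEAC curves.
- Completers-only: no imputation or MMRM-style missing-data modelling.
- The Rosser Index is one of several utility instruments; EQ-5D/SF-6D
  valuations are not shipped, though structurally a substitute matrix can
  be configured.
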