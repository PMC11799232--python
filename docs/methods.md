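# Methods

## The analysis model

`pvsignal` implements case–non-case disproportionality analysis for
spontaneous-reporting data. The unit of analysis is the *case* (a
deduplicated report), not the row: extracts arrive as one row per
report × drug × event, and all counting collapses to case level first, so a
drug listed twice or a PT coded on several rows contributes once.

For a target drug and target event the deduplicated extract is partitioned
into the 2×2 table (a, b, c, d): exposure is "the drug appears with role
Primary Suspect (PS)" — a drug present only as Secondary Suspect,
Concomitant or Interacting belongs to the comparator — and the event is
"the PT appears at least once in the case". The comparator is all other
cases *of the supplied extract*; the package makes no assumption about
whether that extract is a whole-database download or a query result, which
is why absolute signal counts depend entirely on the background the user
feeds in.

Estimators (z = 1.96 verbatim, the convention in this literature, rather
than the exact 0.975 normal quantile):

- ROR = ad/bc, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` (Woolf);
- PRR = [a/(a+b)]/[c/(c+d)], 95% CI
  `exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`;
- χ²: Pearson `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` by default; the Yates
  variant (numerator `(|ad−bc|−N/2)²`, floored at 0) behind a flag. Both are
  exposed because published tables rarely say which was used; neither enters
  the signal rule.

**Signal rule.** A pair is a signal iff a ≥ 3 (inclusive), ROR CI lower
bound > 1 (strict) and PRR > 2 (strict). The strict/inclusive reading is
deliberate and tested (`PRR = 2.0` exactly is not a signal). Signals are
ranked by a (desc), ties by ROR (desc) then PT name.

**Zero cells.** No silent continuity correction: with any empty cell the
estimates are NaN, the pair is excluded from signals with reason
`undefined`, and the Haldane +0.5-to-every-cell correction is available only
behind an explicit flag. A silent correction would change signal counts
invisibly.

**Useful identities** (implemented, property-tested, and used to vet
published rows):

1. *Same side of 1*: ROR > PRR ⟺ ROR > 1 and ROR = PRR ⟺ ROR = 1, because
   ROR/PRR = [d(a+b)]/[b(c+d)] sits on the same side of 1 as ROR itself.
2. *CI symmetry*: both CIs are symmetric on the log scale, so
   √(low·high) equals the point estimate exactly (to rounding).

## Deduplication and demographics

FAERS cases are resubmitted as new versions; `deduplicate` keeps, per case
id, only rows of the highest report version (exposed as a switchable step,
since some front ends pre-deduplicate). Demographics count distinct PS
cases per drug: sex in {female, male, unknown}, age binned <18 / 18–44 /
45–64 / ≥65 / unknown with integer printed boundaries read as
[18,45), [45,65) etc., top-5 reporting countries (ties alphabetical).
Ages in non-year units (MON/WK/DY/DEC/HR) are converted to years by the
reader; unconvertible or implausible (≥150 y) ages become missing with a
logged, line-numbered warning. Percentages are count/total·100, rounded to
2 decimals only at display.

## SOC aggregation

MedDRA is licensed, so the PT → SOC mapping arrives as a plain file
(`pt, soc[, is_primary]`). Only the primary axis is used — each signal is
counted once under its PT's primary SOC so per-drug shares sum to 100% —
and percentages are shares of the drug's *signal count*, not of reports.
PTs missing from the map fall into an explicit `Unmapped` bucket with a
warning rather than being dropped. SOC-level RORs treat "case carries ≥ 1
member PT" as the event, so the SOC-level a is the size of the union of the
member-PT case sets (≤ the sum of PT-level a's, with equality iff no case
carries two member PTs — a tested invariant).

## The synthetic extract generator

The generator produces the statistical structure the estimators assume,
with closed-form ground truth:

- one PS drug per case, multinomial over the catalogue; optionally one
  concomitant drug (SS/C/I) that never affects the statistics (by the PS
  extraction contract) but exercises the role handling;
- events: one "primary" PT per case from a Zipf(1) multinomial π (so every
  case has ≥ 1 event, as in real extracts), plus independent extra-event
  Bernoullis with rates r_e = λ·π_e, λ = `mean_extra_events` (default 1.5,
  i.e. ≈ 2.5 PTs/case). The marginal occurrence probability is then exactly
  q_e = 1 − (1−π_e)(1−r_e). An explicit events-per-report distribution was
  rejected because sampling without replacement from a multinomial makes
  the per-event marginals — and hence exact ROR control — intractable;
- planting: for a planted (drug g, PT e, target ρ), the occurrence odds of
  e among g's PS cases are scaled by ρ (q' = ρq/(1−q+ρq)), realised by
  adjusting only the extra-event rate for that column
  (r' = 1 − (1−q')/(1−π_e)), leaving the primary multinomial and all other
  events untouched. The expected 2×2 table therefore has ROR exactly ρ;
  ρ < 1 targets below the primary-event floor are rejected as infeasible
  rather than silently clipped. ROR is the exactly controlled quantity (PRR
  converges to it for rare events) — controlling both simultaneously is
  impossible, since they are deterministically linked given the margins;
- demographics emulate a large antifungal safety extract: sex
  (32.1/50.3/17.6% f/m/unknown), ~29.6% missing age with the observed mass
  split 9.4/15.7/33.0/41.9% over the four bins, US-dominated country mix
  with ~22% missing, receipt dates uniform 2005–2023Q3;
- 5% of cases are emitted twice with an incremented version (identical
  content), so deduplication is exercised on every simulated run;
- the default catalogue: 12 drugs (three triazoles with PS shares 0.200 /
  0.044 / 0.021, proportional to their real report volumes, plus nine
  Zipf-weighted background drugs) and 120 PTs. The default planted pair is
  (voriconazole, event_030, ROR 5) — a mid-tail PT with baseline occurrence
  ≈ 1.5%, giving a ≈ 290 at the default 20,000 cases.

**What it does not emulate:** reporting dynamics over time, drug–drug
interaction signals, correlated event co-reporting beyond the shared
primary draw, notoriety/stimulated-reporting waves, duplicated cases with
*conflicting* content, and free-text coding noise. Passing the calibration
studies therefore shows the estimators and pipeline are correct under the
assumed sampling model, not that real FAERS signals are unbiased.

**Validation studies** (all seeded, run by the acceptance script and the
test suite): (i) CI coverage — 500 extracts of 20,000 cases with ρ = 5
planted; the Woolf 95% CI covers ρ in 96.2% of replicates at the reference
seed (93–97% expected at nominal 95% with this replicate count);
(ii) null rates — on a 50,000-case extract with nothing planted, the ROR CI
lower bound exceeds 1 for ≈ 2.5–3% of the ~1,430 pairs with a ≥ 3 (the
nominal one-tail 2.5% of a two-sided 95% CI), and the full joint rule flags
≈ 0.3% — the study evaluates *all* eligible pairs rather than a small
subsample because at ~2.5% true rate a 100-pair estimate is mostly noise;
(iii) recovery — median estimated ROR across 11 extracts of 50,000 cases is
within 10% of planted strengths 2, 5 and 20. Study sizes were chosen so the
whole validation battery completes in about two minutes on one CPU.

## Inversion of published summary rows

Published tables print (a, PRR, ROR, ROR 95% CI) but not b, c, d. Those are
identified by three relations: the two estimator definitions and the CI
width `1/a + 1/b + 1/c + 1/d = (ln(hi/lo)/(2·1.96))²`. The system solves in
closed form — dividing the ROR by the PRR relation gives
`b = a(PRR−1)/(ROR−PRR)`; substituting `d = ROR·b·c/a` into the width
relation leaves a linear equation in 1/c — so no iterative root finding is
needed and the continuous solution reproduces the inputs to machine
precision. Reported residuals are therefore the *rounding* residuals of the
nearest-integer table.

Three consistency gates precede the solve, each raising a named error:
positivity, the geometric-mean identity |√(lo·hi)/ROR − 1| < 0.005, and the
same-side-of-1 ordering (a printed row with PRR > ROR > 1 cannot come from
any positive table). A fourth emerges from the solve itself: if
`1/a + 1/b` already exceeds the squared log-CI half-width the printed CI is
too narrow for the printed count and no positive c, d exist. Of the bundled
60 published rows, all 20 voriconazole rows invert (rounding residuals
≤ 0.02%, implied backgrounds clustering near 11.1–11.5 M comparator
reports), while 15 posaconazole/isavuconazole rows fail the width gate and
one fails the ordering gate — the tool is designed exactly to surface such
transcription artefacts, and the bundled data keeps them verbatim as
negative examples.

## Numerical and interface choices

- Display rounding is 3 decimals for statistics tables and 2 for
  percentages; nothing is rounded internally.
- All tabular outputs are UTF-8 delimited text with headers, written with
  fixed float formats so reruns are byte-identical; every source of
  randomness flows from an explicit integer seed (per-replicate seeds are
  derived through `numpy.random.SeedSequence`).
- The Model/Results split follows the statsmodels convention:
  `DisproportionalityModel` holds data + configuration, `fit()` returns a
  results object carrying the per-pair statistics, the filter funnel
  (rows → cases → pairs → signals), demographics/SOC views, `summary()`,
  and simple bar/forest plots. The CLI is a thin layer over it.

## Known limitations

- No Bayesian disproportionality (BCPNN/EBGM), no stratified or
  time-partitioned tables, and no multiple-testing adjustment — the joint
  a/CI/PRR rule is applied as-is, so family-wise false-positive behaviour
  is only *measured* (by the null study), not controlled.
- Absolute signal counts are not comparable across backgrounds; an extract
  restricted to a therapeutic area will yield different counts than a
  whole-database background.
- The inversion assumes the published CI was computed with the same Woolf
  formula and z = 1.96; rows produced by other CI methods would be flagged
  inconsistent rather than inverted.
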