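# Methods

This note documents the statistical procedures the package implements, the
model behind the synthetic-data generator, the parameter choices that matter,
and what passing tests do and do not establish.

## Instruments and scoring

The reference instrument has 34 past-year victimization items on a
four-category frequency scale ("0 times", "1–3 times", "4–10 times", "more
than 10 times"). The numeric coding 0/1/2/3 is a package convention: the
published scale does not state a coding, and 0–3 is the simplest one under
which the reference rule "sum score ≥ 6" is expressible with a scale minimum
of 0. (The published description of the rule — that a score of 6 corresponds
to a minimum of five acts — is not consistent with any simple coding of the
four categories, under which the minimum is six acts; the package adopts 0–3
and documents the discrepancy rather than resolving it.)

Skipped items score 0 by default (`treat_as_zero`), because respondents were
free to skip questions and records skipping more than 10 are removed
upstream by QC; a `reject_if_over_k` policy is available when the QC stage
is not in play.

The screener is the fixed three-item subset (`int_yelled`,
`sex_pressured_photo`, `soc_trapped`), scored as the count of items endorsed
at any nonzero frequency. The item-selection rule (`select_screener_items`)
ranks items by endorsement prevalence after removing excluded ids, with
deterministic lexicographic tie-breaking; the `soc_stopped_talking` item is
excluded despite being the most endorsed because ceasing contact can be a
healthy behavior.

## Diagnostic accuracy

All proportions carry exact Clopper–Pearson intervals (beta-quantile form,
via statsmodels), chosen because the published CI cells — in particular the
one-sided 96.6% lower bound at 107/107 — are reproduced by the exact method
and not by Wald or Wilson intervals. Zero-denominator metrics are reported
as explicit `NA (zero denominator)` markers, never as 0 or 1.

Two "ROC area" quantities are deliberately distinguished:

- `roc_area_single` = (sensitivity + specificity)/2, the area of the ROC
  polygon through a single operating point — this is the quantity published
  accuracy tables of this kind label "ROC area" (0.872 for the full sample);
- `auc_empirical`, the trapezoidal area through all cutpoint operating
  points anchored at (0,0) and (1,1) (0.892 on the reconstructed data).

Cutpoint selection offers `closest_to_corner` (minimum Euclidean distance to
FPR 0, sensitivity 1) and `youden` (maximum sens + spec − 1); ties go to the
smaller cutpoint. On the reconstructed study data both select cutpoint 1
(distances 0.187 / 0.564 / 0.812; J = 0.744 / 0.436 / 0.188).

Report rendering rounds percentages to one decimal and areas to three, using
half-up rounding to match published tables (0.8715 → 0.872, not banker's
0.871).

### Reconstruction of the published 2×2 table

The study's record-level data are unavailable, but with n = 224 and 117
reference-positives fixed, the five published rounded metrics over-determine
the two free integers of the 2×2 table. `reconstruct_confusion_table`
searches all admissible tables and returns the minimizer of the maximum
absolute deviation from the published values, requiring the runner-up to be
clearly worse; the search returns (tp, fn, fp, tn) = (98, 19, 10, 97)
uniquely (deviation 4.6×10⁻⁴ vs 8.2×10⁻³ for the runner-up). Subgroup 2×2
tables are *not* uniquely recoverable from their published rounded rows, so
subgroup behavior is checked as a homogeneity property on synthetic cohorts
instead (demographics independent of severity ⇒ subgroup sensitivities equal
up to sampling noise).

## Survey QC

Eligibility failures are labeled with the first failing rule in the fixed
order (prior completion, no past-year dating, age outside 11–21, more than
10 skips, non-US, timeout), making the per-reason counts a partition; the
published source does not state an assessment order, so this order is a
convention chosen to reproduce the published per-reason counts exactly when
each record fails one rule.

The fraud rules requiring choices the source leaves open:

- *nonsense text*: a field is blank/nonsense when trimmed text is empty,
  shorter than 2 characters, vowel-free, or a single repeated character; the
  rule fires only when **all five** open-text fields are blank/nonsense.
- *duplicate*: records sharing a respondent key (cohort-level count > 1);
  the key column is configurable.
- *geolocation*: great-circle distance between IP coordinates and the
  reported zip's centroid above 400 km (generous, since both coordinates are
  coarse). Zip/state checks use an injected lookup table; the packaged
  miniature table covers one or two zips per state and is intended for tests
  and synthetic data, not production QC.
- an unverifiable (unknown) zip counts as a zip/state mismatch; an unknown
  *state code* raises an error naming the record, since it indicates
  malformed input rather than fraud.

## The synthetic-data generator

A single-factor probit latent-trait model: respondent severity z ~ N(0,1);
item i endorsed iff a_i·z + e_i > τ_i with e_i ~ N(0,1), giving the marginal
closed form 1 − Φ(τ_i/√(1+a_i²)). Endorsed items receive frequency category
1–3 by ordered thresholds on the same linear predictor. A single factor is
the simplest structure consistent with the instrument's high internal
consistency (the simulated 34-item scale has Cronbach's α ≈ 0.92, against a
published 0.90) and with a three-item subset predicting the full scale well.

Calibration is by monotone root-finding: per-item thresholds against the
closed-form marginal, and per reporting category a single shared shift on
the unpinned items' thresholds against the Gauss–Hermite evaluation of
P(≥ 1 item endorsed in the category). Published values are *pins* that
calibration never moves: screener marginals 28/28/25%, the excluded item at
38%, the two monitoring items at 22%, category prevalences 17/25/35/43%,
and the screener loading solved so the screener-endorsement union equals the
published 48.2% screen-positive rate.

Choices where the source gives no value:

- **Reporting categories vs subscales.** The published abuse-type
  prevalences (physical, sexual, emotional, technology-facilitated) do not
  coincide with the instrument's five subscales, so the schema carries both
  labels per item. The "could not break up" and "stopped talking" items are
  treated as social control, *outside* the four categories: with them inside
  the emotional category its 35% target would be arithmetically unreachable
  (the screener pins alone would exceed it under any positive loading).
- **Unpublished item marginals** decrease smoothly within subscale, capped
  at 0.22 so the screener items remain the most-endorsed items after the
  excluded one, as published; loading 1.3 for unpinned items, 1.0–1.5 for
  non-screener pins.
- **Frequency-category split.** The conditional split of endorsed mass is
  (0.045, 0.055, 0.90) toward "more than 10 times". Equal thirds cap the
  dichotomized reference prevalence near 0.30, far below the published
  52.2%; the published facts that a full-scale cutpoint of 2 would classify
  72% of the sample positive versus 52% at cutpoint 6 imply heavy score mass
  among endorsers, which this split encodes. It is configurable.

### The attainable operating point

With the marginal pins in place, the identity
screen-positive rate = sens·π + (1−spec)(1−π) holds by construction, so the
generator has effectively two free accuracy coordinates. A single-factor
model with all pins active saturates near sensitivity 0.82 / specificity
0.86 at reference prevalence ≈ 0.50 — close to, but below, the published
0.838/0.907 at 0.522. The gap is informative: in real data the three
screener items are embedded in the reference scale and share method and
content with neighboring items, giving a stronger screener–scale coupling
than a single common factor can express once the 48.2% union is pinned.

`study_config` therefore keeps the published *inputs* (prevalences, margins,
flow composition) and accepts the implied operating point, while
`operating_point_config` reproduces the published *outputs* (sens ≈ 0.84,
spec ≈ 0.91, prevalence ≈ 0.52) by raising the screener marginals to 0.34
at loading 2.0 and relaxing the marginal pins. Analyses that need the
published accuracy geometry (e.g. stochastic cutpoint-selection rates) use
the second configuration; analyses of the pipeline mechanics use the first.

A related part–whole effect: because the screener items contribute to the
reference sum score, even a zero-loading screener discriminates above chance
against the full scale; chance-level behavior holds only against a reference
built from the 31 non-screener items, and the tests assert exactly that.

### Demographics and contamination

Demographics are drawn independently of severity from the published sample
margins (the study found no significant survivor/non-survivor demographic
differences); `demo_severity_shift` provides an additive hook on z for
sensitivity analyses. Ages are uniform within the drawn age band, zip/state
metadata are consistent with the drawn census region, and QC metadata are
clean by construction. `inject_contamination` appends records that each
violate exactly one eligibility or fraud rule; the packaged
`STUDY_CONTAMINATION` reproduces the published recruitment composition
(571 screened → 409 eligible → 401 consented → 224 analytic). The fraud
total of 177 is published but its per-rule split is not; the packaged split
(40/45/40/30/22) is a generator convention.

Reproducibility: one master seed spawns independent per-stage substreams;
identical configuration and seed produce byte-identical cohort files.

## Sample size

`required_cases` rounds Z²p̂(1−p̂)/d² up (48.98 → 49);
`required_total` truncates cases/prevalence by default (49/0.409 = 119.8 →
119), because truncation is the only convention that reproduces the
published total; `ceil` mode is available. Z comes from the normal quantile
(1.96 at α = 0.05).

## Problem sizes and verification

Tests run the generator at n = 10,000 (calibration, margins, subgroup
homogeneity), 20,000–40,000 (operating point, no-signal checks), and 224 ×
100 replicates (cutpoint-selection rate); exact-CI coverage uses 10,000
binomial replicates at n = 117, p = 0.84. These sizes put Monte-Carlo error
well inside the asserted tolerances while keeping the suite fast.
Independent oracles: CI bounds against the beta-quantile closed form,
trapezoidal AUC against both the pairwise-probability interpretation
(brute force) and scikit-learn's `roc_auc_score`, calibrated thresholds
against the probit closed form, and the reconstructed 2×2 table against the
published metric cells.

## Limitations

- The generator is a stand-in, not a fit: no real record-level data
  informed it beyond the published summary statistics, and passing tests
  show internal consistency with those summaries, not fidelity to real
  response behavior (e.g. item-specific response styles, missingness
  patterns, or genuinely multidimensional abuse profiles).
- The single-factor structure understates screener–scale coupling (see
  above); two configurations bracket the published study rather than one
  reproducing it entirely.
- Bot behavior is simulated only insofar as it triggers the five rules;
  the QC module does not attempt behavioral bot detection.
- No IRT machinery: items are simulated from, but never fitted to, a
  latent-trait model.
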