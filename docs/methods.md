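# Methods

## Calling model

A well's measurement is a pair of Ct values (methylation target, ACTB
internal control). `UNDETECTED` is a distinct sentinel, never a numeric
stand-in: the value 45 enters only when ROC analysis explicitly censors
undetected wells to the cycle ceiling. A well is

- **invalid** when the control is undetected or beyond `max_cycles`
  (no assayable DNA reached the reaction);
- **positive** when the target is detected at `Ct <= ct_cutoff`;
- **negative** otherwise.

Ties at the cutoff count as positive: an assay that runs 45 cycles and
names 45 its cutoff treats detection *at* cycle 45 as detection. A
subject is k-of-n positive when at least k of n wells are positive. Any
invalid well invalidates the subject, which is excluded from all
denominators and counted in reports — a conservative, auditable policy
chosen because retest/exclusion handling in field use varies and the
exclusion count lets users audit its impact. The "1/1" rule is not a
per-subject vote: each replicate position is scored as a whole
single-well test and the positions' sensitivities and specificities are
averaged.

## Performance statistics

Proportions carry 95% Wilson score intervals (closed form), preferred
over Wald for the proportions near 0 and 1 this domain produces (e.g.
6/490). Two proportions are compared with the **uncorrected** Pearson χ²
on the 2×2 table, df = 1, p from `erfc(sqrt(x/2))`; no Yates correction
and no multiple-testing adjustment are applied, matching how pairwise
comparisons are conventionally reported in this assay literature (the
shipped fixture comparisons reproduce their published statistics to two
decimals only without the correction). Degenerate tables (zero margin)
are rejected rather than patched.

## Censored-Ct ROC

The scalar score for a k-of-n rule is the k-th smallest target Ct after
censoring undetected wells to `max_cycles`: a subject is k-of-n positive
at threshold t exactly when this order statistic is ≤ t, so the score
generates the rule's full operating curve. Because most disease-free
subjects never amplify, a large point mass sits at the ceiling and
thresholds beyond it are unobservable. The realized curve therefore uses
thresholds at the unique observed sub-ceiling scores and *terminates* at
the last of them (`max_observed_fpr` records where); it is never
extrapolated. The AUC integrates the realized points by trapezoid and
closes the curve to (1, 1) with a single chord, which credits
censored-tied case–control pairs exactly ½ — making the AUC identical to
the tie-corrected Mann–Whitney probability P(case < control) + ½P(tie),
verified pair-by-pair in the tests. `specificity_at_sensitivity`
interpolates linearly between realized points only; targets above the
truncated curve's maximum TPR raise an unreachable-target error instead
of inventing specificity beyond the censoring limit.

Published work comparing AUCs of this kind rarely states its test; this
package deliberately provides a percentile bootstrap on ΔAUC (subjects
resampled with replacement independently within each assay's case and
control arms, as the two assays under comparison were run on different
cohorts) rather than guessing at an unstated parametric procedure. A
DeLong test is intentionally out of scope.

## Design calculators

`required_cases` is floor(z²·p(1−p)/e²); `required_enrollment` divides by
the anticipated case fraction (floor) and inflates by attrition (ceiling).
Floor-floor-ceiling is the unique rounding convention under which the
standard worked chain (z = 1.96, p = 0.68, e = 0.05, 30% case mix, 20%
loss) lands on 334 → 1113 → 1336 whole subjects without under-powering
the final goal.

`predict_performance` implements an equivalence rule, not a model: a
configuration inherits the measured operating point with the same
per-reaction plasma equivalent (2.7 mL → 75.1%/97.1%, 1.8 mL →
76.6%/95.9%, 1.0 mL → 71.3%/92.7%); other volumes map to the nearest
measured equivalent with a logged extrapolation warning. Predicted rows
are labelled `predicted` and carry no accuracy claim. The mechanism that
justifies volume-based reasoning — the Poisson hit probability
1−exp(−c·v) is monotone in v — is a tested property of the simulator.

`mass_to_copies` divides pg/mL by a configurable genome mass, default
6.6 pg (one diploid human genome), placing a 7.8 pg/mL limit of detection
at ≈1.2 copies/mL.

## Synthetic cohort generator

Per subject, concentration c (copies/mL plasma) is zero-inflated
log-normal: with stratum shedder-fraction w, c ~ LogNormal(μ, σ), else
c = 0. Per well, template count m ~ Poisson(c·v) with v the assay's
plasma-equivalent volume (0.9 mL/well triplicate, 1.8 mL single-well). A
templated well amplifies at Ct = 41 − log₂(m) + N(0, 0.5²), clipped to
(0, 45]: one cycle per doubling of input, intercept chosen so
single-molecule events sit in the low-40s cycles, consistent with a
single-digit-copies detection limit. A template-free well false-amplifies
with probability 0.056, uniformly over the last 3 cycles below the
ceiling — late false signal is why widening a cutoff from 41 to 45 costs
specificity. The ACTB control fails independently at 0.005/well
(unreported in source data; set to a plausible lab failure rate). All
draws flow through one seeded generator in a documented stratum and
stream order, so identical parameters give byte-identical cohort files.

Default sizes are the published enrolment table (369 CRC by stage
21/42/105/131/15/55, 113 adenoma, 87 polyps, 27 IBD, 47 other-GI,
490 NED; 1133 total). Per-stratum (w, μ) were fitted once, offline, by
Nelder–Mead on closed-form exchangeable k-of-3 tail probabilities against
the published stage- and group-wise detection fractions, with σ = 1.0
shared and the background rate fitted on the NED group; the result is
frozen as the `table1-calibrated` preset. `calibrate_to_table2` validates
the preset by simulation (default 100 000 subjects, a size chosen to make
Monte-Carlo error ≪ the tolerance while keeping the check to a few
seconds) and raises if any of the six headline operating characteristics
drifts beyond tolerance; it never re-searches.

**What the model does and does not capture.** Replicates are exchangeable
given c: all well-to-well correlation comes from the shared
concentration. Consequently the three k-of-3 operating points of any
stratum are three moments of a two-parameter mixture and cannot all be
matched exactly — the shipped preset's worst CRC-overall residual is
≈0.016, comfortably inside the ±0.05 validation band, and a tolerance of
0.001 provably fails (a tested behaviour). Real cohorts may carry extra
within-subject correlation (pipetting, inhibition), systematic well
effects, bisulfite-conversion losses and fragment-length biology, none of
which are modelled; passing tests therefore certify the analysis code and
the stated mechanism, not biological fidelity of any particular dataset.

## Fixtures and their inconsistencies

The shipped count tables store (positives, total) as ground truth with
the published percentage carried verbatim. Three printed percentages
disagree with their own counts at 1-decimal rounding (82.4% for
303/369 = 82.1%, reprinted across three tables, and 3.4% for
2/47 = 4.3%); these are flagged, not reconciled — the χ² statistics,
which are computed from counts, are self-consistent throughout. One
published χ² (3.26) appears truncated rather than rounded (the
uncorrected statistic is 3.2667); comparisons therefore assert agreement
within 0.01.

## Numerical choices

- Ct values are read/written with two decimals; the undetected token is
  the literal string `ND` (survives spreadsheet round-trips, cannot
  collide with a numeric Ct).
- Cohort files are UTF-8 CSV/TSV (autodetected), one row per subject,
  columns `subject_id,group,stage,sex,age_band,target_ct_1..n,
  control_ct_1..n`; a leading `# provenance:` comment preserves the
  simulation seed across the file boundary.
- Wilson intervals pin the boundary cases (0/n, n/n) to exactly 0 and 1.
- Equidistant plasma volumes in `predict_performance` resolve to the
  smaller measured equivalent (conservative).
- Bootstrap CIs are percentile, seeded, minimum 100 resamples.

## Known limitations

- The exchangeable-replicate assumption above; no S-shaped
  amplification-curve modelling (Ct values are inputs, not computed from
  fluorescence).
- The plasma-equivalent lookup is a nearest-neighbour rule over at most a
  handful of measured points; it does not model the Poisson mechanism it
  is motivated by.
- No prevalence-based PPV/NPV modelling and no multiple-testing
  correction (deliberate, to match reporting conventions; see above).
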