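"""Diagnostic performance statistics for replicate-combination calling.

Covers proportion estimates with Wilson score intervals, uncorrected
Pearson chi-square comparisons of two proportions, stratified positive
detection rates, the averaged single-well (``1/1``) summary, and ROC
analysis for Ct-based scores in the presence of censoring at the cycle
ceiling.

Censored ROC
------------
Most disease-free subjects never amplify, so their Ct is undetected and is
censored to the cycle ceiling (45) for ROC purposes. Thresholds beyond the
ceiling are unobservable: the realized curve therefore *terminates* at the
operating point of the largest observed sub-ceiling score instead of
reaching (1, 1). The AUC integrates the realized curve and closes it to
(1, 1) with a single chord, which credits the censored mass exactly half —
making the AUC identical to the tie-corrected Mann-Whitney probability
P(case score < control score) + 0.5 P(tie).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .calling import AlgorithmSpec, BinaryCall, call_replicate, call_subject
from .cohort_io import (CRC_STAGES, GROUP_ORDER, AssayConfig, Cohort, Group,
                        Stage, SubjectRecord, is_detected)
from .errors import (DegenerateTableError, EstimationError,
                     UnreachableTargetError, ValidationError)

logger = logging.getLogger(__name__)

DEFAULT_CASE_GROUPS = frozenset({Group.CRC})
DEFAULT_CONTROL_GROUPS = frozenset({Group.NED})


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionEstimate:
    """A count-based proportion with a 95% Wilson score interval."""

    positives: int
    total: int
    proportion: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:
        return (f"{100 * self.proportion:.1f}% "
                f"({self.positives}/{self.total})")


def proportion_estimate(positives: int, total: int,
                        z: float = 1.959963984540054) -> ProportionEstimate:
    """Exact fraction plus Wilson score interval (default 95%).

    The Wilson interval inverts the normal test on the score scale; unlike
    the Wald interval it behaves sensibly at proportions near 0 or 1, which
    this domain hits routinely (e.g. 6/490 = 1.2%).
    """
    if total < 1:
        raise EstimationError("total must be >= 1")
    if not 0 <= positives <= total:
        raise EstimationError(
            f"positives={positives} outside [0, total={total}]")
    p = positives / total
    z2 = z * z
    denom = 1 + z2 / total
    center = (p + z2 / (2 * total)) / denom
    half = z * math.sqrt(p * (1 - p) / total
                         + z2 / (4 * total * total)) / denom
    # at the boundaries center == half analytically; pin the limit exactly
    ci_low = 0.0 if positives == 0 else max(0.0, center - half)
    ci_high = 1.0 if positives == total else min(1.0, center + half)
    return ProportionEstimate(positives, total, p, ci_low, ci_high)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Observed counts: row 1 = (a, b), row 2 = (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("grand total must be >= 1")

    @classmethod
    def from_proportions(cls, pos1: int, tot1: int, pos2: int,
                         tot2: int) -> "ContingencyTable2x2":
        return cls(pos1, tot1 - pos1, pos2, tot2 - pos2)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def chi2_survival(statistic: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-square(1) distribution.

    For one degree of freedom this is ``erfc(sqrt(x/2))``; no other df is
    used by the pairwise 2x2 comparisons in scope.
    """
    if df != 1:
        raise ValidationError("only df=1 is supported")
    if statistic < 0:
        raise ValidationError("statistic must be non-negative")
    return float(erfc(math.sqrt(statistic / 2)))


def pearson_chi2(t: ContingencyTable2x2) -> Chi2Result:
    """Uncorrected Pearson chi-square on a 2x2 table.

    chi2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)], df = 1. No Yates
    continuity correction: the uncorrected statistic reproduces every
    published comparison in this domain to two decimals.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        raise DegenerateTableError(
            f"zero row/column margin in table ({a},{b};{c},{d})")
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return Chi2Result(statistic=stat, df=1, p_value=chi2_survival(stat, 1))


# ---------------------------------------------------------------------------
# cohort-level performance
# ---------------------------------------------------------------------------

def _split_valid(cohort: Cohort, assay: AssayConfig, alg: AlgorithmSpec):
    """Subject calls with invalid subjects excluded and counted."""
    calls: dict[str, BinaryCall] = {}
    n_invalid = 0
    for s in cohort.subjects:
        call = call_subject(s, assay, alg)
        if call is BinaryCall.INVALID:
            n_invalid += 1
            continue
        calls[s.subject_id] = call
    if n_invalid:
        logger.warning(
            "%d subject(s) excluded for failed internal control", n_invalid)
    return calls, n_invalid


def _as_groups(groups) -> frozenset[Group]:
    return frozenset(Group(g) for g in groups)


def algorithm_performance(
        cohort: Cohort, assay: AssayConfig, alg: AlgorithmSpec,
        case_groups: Iterable[Group] = DEFAULT_CASE_GROUPS,
        control_groups: Iterable[Group] = DEFAULT_CONTROL_GROUPS,
) -> tuple[ProportionEstimate, ProportionEstimate]:
    """Sensitivity over the case groups and specificity over the controls.

    Subjects with any failed-control well are excluded from both
    denominators (logged). Returns ``(sensitivity, specificity)``.
    """
    case_groups = _as_groups(case_groups)
    control_groups = _as_groups(control_groups)
    if case_groups & control_groups:
        raise ValidationError("case and control groups must be disjoint")
    calls, _ = _split_valid(cohort, assay, alg)
    by_id = {s.subject_id: s for s in cohort.subjects}
    case_calls = [c for sid, c in calls.items()
                  if by_id[sid].group in case_groups]
    ctrl_calls = [c for sid, c in calls.items()
                  if by_id[sid].group in control_groups]
    if not case_calls or not ctrl_calls:
        raise EstimationError(
            "empty case or control set after exclusions")
    sens = proportion_estimate(
        sum(c is BinaryCall.POSITIVE for c in case_calls), len(case_calls))
    spec = proportion_estimate(
        sum(c is BinaryCall.NEGATIVE for c in ctrl_calls), len(ctrl_calls))
    return sens, spec


def averaged_single_replicate_performance(
        cohort: Cohort, assay: AssayConfig,
        case_groups: Iterable[Group] = DEFAULT_CASE_GROUPS,
        control_groups: Iterable[Group] = DEFAULT_CONTROL_GROUPS,
) -> tuple[float, float]:
    """The ``1/1`` summary: treat each replicate position as a whole test
    and average the positions' sensitivities and specificities."""
    case_groups = _as_groups(case_groups)
    control_groups = _as_groups(control_groups)
    sens_r, spec_r = [], []
    for r in range(assay.n_replicates):
        case_pos = case_tot = ctrl_neg = ctrl_tot = 0
        for s in cohort.subjects:
            call = call_replicate(s.replicates[r], assay)
            if call is BinaryCall.INVALID:
                continue
            if s.group in case_groups:
                case_tot += 1
                case_pos += call is BinaryCall.POSITIVE
            elif s.group in control_groups:
                ctrl_tot += 1
                ctrl_neg += call is BinaryCall.NEGATIVE
        if case_tot == 0 or ctrl_tot == 0:
            raise EstimationError(
                f"replicate position {r + 1}: empty case or control set")
        sens_r.append(case_pos / case_tot)
        spec_r.append(ctrl_neg / ctrl_tot)
    return float(np.mean(sens_r)), float(np.mean(spec_r))


def pdr_by_stratum(cohort: Cohort, assay: AssayConfig, alg: AlgorithmSpec,
                   stratify_by: str = "group") -> pd.DataFrame:
    """Positive detection rate per stratum, plus a CRC "Overall" row.

    ``stratify_by="group"`` tabulates every diagnostic group present;
    ``stratify_by="stage"`` tabulates CRC subjects by stage. Returns a
    DataFrame with columns positives/total/proportion/ci_low/ci_high.
    """
    if stratify_by not in ("group", "stage"):
        raise ValidationError(
            f"stratify_by must be 'group' or 'stage', got {stratify_by!r}")
    calls, _ = _split_valid(cohort, assay, alg)
    by_id = {s.subject_id: s for s in cohort.subjects}

    def est(subjects):
        pos = sum(calls[s.subject_id] is BinaryCall.POSITIVE
                  for s in subjects)
        return proportion_estimate(pos, len(subjects))

    valid = [s for s in cohort.subjects if s.subject_id in calls]
    rows, labels = [], []
    if stratify_by == "group":
        strata = [(g.value, [s for s in valid if s.group is g])
                  for g in GROUP_ORDER]
    else:
        crc = [s for s in valid if s.group is Group.CRC]
        strata = [(f"Stage {st.value}" if st is not Stage.NOT_SPECIFIED
                   else "Not specified",
                   [s for s in crc if s.stage is st]) for st in CRC_STAGES]
    for label, members in strata:
        if not members:
            continue
        labels.append(label)
        rows.append(est(members))
    crc_all = [s for s in valid if s.group is Group.CRC]
    if crc_all:
        labels.append("Overall")
        rows.append(est(crc_all))
    if not rows:
        raise EstimationError("no non-empty strata after exclusions")
    return pd.DataFrame(
        {"positives": [r.positives for r in rows],
         "total": [r.total for r in rows],
         "proportion": [r.proportion for r in rows],
         "ci_low": [r.ci_low for r in rows],
         "ci_high": [r.ci_high for r in rows]},
        index=pd.Index(labels, name=stratify_by))


# ---------------------------------------------------------------------------
# ROC with censoring at the cycle ceiling
# ---------------------------------------------------------------------------

def subject_score(s: SubjectRecord, assay: AssayConfig, k: int) -> float:
    """k-th smallest target Ct after censoring undetected wells to the
    ceiling.

    This is the unique scalar score consistent with the k-of-n decision
    rule: the subject is k-of-n positive at cutoff t exactly when this
    score is <= t.
    """
    if not 1 <= k <= assay.n_replicates:
        raise ValidationError(
            f"k={k} out of range [1, {assay.n_replicates}]")
    for m in s.replicates:
        if (not is_detected(m.control_ct)
                or float(m.control_ct) > assay.max_cycles):
            raise ValidationError(
                f"subject {s.subject_id!r} is invalid (failed control)")
    censored = sorted(
        float(m.target_ct) if is_detected(m.target_ct) else assay.max_cycles
        for m in s.replicates)
    return censored[k - 1]


@dataclass(frozen=True)
class RocPoint:
    false_positive_rate: float
    true_positive_rate: float
    threshold_ct: float


@dataclass(frozen=True)
class RocCurve:
    """Censored-Ct ROC: realized operating points and tie-corrected AUC.

    ``points`` stop at the largest observed sub-ceiling threshold;
    ``max_observed_fpr`` is the FPR there — beyond it no specificity data
    exist. ``auc`` includes the chord closing the curve to (1,1), i.e.
    censored ties count half.
    """

    points: tuple[RocPoint, ...]
    auc: float
    censor_ct: float
    max_observed_fpr: float

    @property
    def max_tpr(self) -> float:
        return self.points[-1].true_positive_rate if self.points else 0.0


def roc_curve(scores_cases: Sequence[float], scores_controls: Sequence[float],
              censor_ct: float) -> RocCurve:
    """Build the ROC of a lower-is-more-positive Ct score.

    Operating points arise from thresholds at every unique observed score
    strictly below ``censor_ct`` (positive iff score <= threshold); scores
    at or above the ceiling are treated as censored mass.
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise EstimationError("both case and control scores are required")
    cases = np.minimum(cases, censor_ct)
    controls = np.minimum(controls, censor_ct)

    thresholds = np.unique(np.concatenate([cases, controls]))
    thresholds = thresholds[thresholds < censor_ct]
    points = [RocPoint(0.0, 0.0, 0.0)]
    for t in thresholds:
        points.append(RocPoint(
            float(np.mean(controls <= t)), float(np.mean(cases <= t)),
            float(t)))
    auc = 0.0
    for p1, p2 in zip(points, points[1:]):
        auc += ((p2.false_positive_rate - p1.false_positive_rate)
                * (p1.true_positive_rate + p2.true_positive_rate) / 2)
    last = points[-1]
    # chord to (1,1): the censored tie mass, credited half
    auc += ((1.0 - last.false_positive_rate)
            * (last.true_positive_rate + 1.0) / 2)
    return RocCurve(points=tuple(points), auc=float(auc),
                    censor_ct=float(censor_ct),
                    max_observed_fpr=last.false_positive_rate)


def specificity_at_sensitivity(curve: RocCurve,
                               target_sensitivity: float) -> float:
    """Specificity read off the realized curve at a target sensitivity.

    Linear interpolation between adjacent realized points; a target above
    the truncated curve's maximum TPR is unreachable (a direct consequence
    of censoring at the cycle ceiling).
    """
    if not 0 <= target_sensitivity <= 1:
        raise ValidationError("target sensitivity must be in [0, 1]")
    pts = curve.points
    if target_sensitivity > curve.max_tpr + 1e-12:
        raise UnreachableTargetError(
            f"target sensitivity {target_sensitivity} exceeds the curve's "
            f"maximum {curve.max_tpr:.4f} (censored at "
            f"Ct {curve.censor_ct})")
    for prev, cur in zip(pts, pts[1:]):
        if cur.true_positive_rate >= target_sensitivity:
            dy = cur.true_positive_rate - prev.true_positive_rate
            if dy <= 0:
                fpr = cur.false_positive_rate
            else:
                frac = (target_sensitivity - prev.true_positive_rate) / dy
                fpr = (prev.false_positive_rate
                       + frac * (cur.false_positive_rate
                                 - prev.false_positive_rate))
            return 1.0 - fpr
    return 1.0 - pts[0].false_positive_rate  # target <= 0


@dataclass(frozen=True)
class AucComparison:
    """Bootstrap comparison of two AUCs (A minus B)."""

    delta_auc: float
    ci_low: float
    ci_high: float
    auc_a: float
    auc_b: float
    n_boot: int


def compare_auc_bootstrap(
        cases_a: Sequence[float], controls_a: Sequence[float],
        cases_b: Sequence[float], controls_b: Sequence[float],
        censor_ct: float, n_boot: int = 1000, seed: int = 0,
        ci_level: float = 0.95) -> AucComparison:
    """Percentile bootstrap CI for the AUC difference of two assays.

    Subjects are resampled with replacement independently within each of
    the four arms (the two assays were run on separate cohorts). Fully
    reproducible under a fixed seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(x, dtype=float)
              for x in (cases_a, controls_a, cases_b, controls_b)]

    def auc_of(ca, co):
        return roc_curve(ca, co, censor_ct).auc

    auc_a = auc_of(arrays[0], arrays[1])
    auc_b = auc_of(arrays[2], arrays[3])
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        res = [arr[rng.integers(0, arr.size, arr.size)] for arr in arrays]
        deltas[i] = auc_of(res[0], res[1]) - auc_of(res[2], res[3])
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(deltas, [alpha, 1 - alpha])
    return AucComparison(delta_auc=auc_a - auc_b, ci_low=float(lo),
                         ci_high=float(hi), auc_a=auc_a, auc_b=auc_b,
                         n_boot=n_boot)
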