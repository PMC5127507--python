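"""Proportions, chi-square, averaged single-well summary, and censored ROC."""

import math

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from repcall import (Cohort, ContingencyTable2x2, DegenerateTableError,
                     EstimationError, Group, UnreachableTargetError,
                     ValidationError, AlgorithmSpec,
                     algorithm_performance,
                     averaged_single_replicate_performance, chi2_survival,
                     compare_auc_bootstrap, pdr_by_stratum, pearson_chi2,
                     proportion_estimate, roc_curve,
                     specificity_at_sensitivity, subject_score)
from repcall.printed_tables import PRINTED_CHI2_COMPARISONS

from conftest import make_subject


class TestProportionEstimate:
    @pytest.mark.parametrize("pos,tot,expected", [
        (303, 369, 303 / 369),   # rounds to 82.1%, not the published 82.4%
        (214, 369, 214 / 369),
        (0, 100, 0.0),
    ])
    def test_exact_fraction(self, pos, tot, expected):
        est = proportion_estimate(pos, tot)
        assert est.proportion == pytest.approx(expected)
        assert est.ci_low <= est.proportion <= est.ci_high

    def test_boundary_zero_positives(self):
        est = proportion_estimate(0, 100)
        assert est.ci_low == 0.0 and est.ci_high > 0

    def test_zero_total_rejected(self):
        with pytest.raises(EstimationError):
            proportion_estimate(0, 0)

    @pytest.mark.parametrize("pos,tot", [
        (303, 369), (6, 490), (0, 10), (10, 10), (1, 2), (214, 369)])
    def test_wilson_interval_matches_statsmodels(self, pos, tot):
        est = proportion_estimate(pos, tot)
        lo, hi = proportion_confint(pos, tot, alpha=0.05, method="wilson")
        assert est.ci_low == pytest.approx(lo, abs=1e-10)
        assert est.ci_high == pytest.approx(hi, abs=1e-10)


class TestPearsonChi2:
    def test_published_example(self):
        res = pearson_chi2(ContingencyTable2x2(303, 66, 277, 92))
        assert res.statistic == pytest.approx(5.44, abs=0.005)
        assert res.p_value < 0.05

    def test_identical_proportions_give_zero(self):
        res = pearson_chi2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_adenoma_vs_ned(self):
        res = pearson_chi2(ContingencyTable2x2(42, 71, 88, 402))
        assert res.statistic == pytest.approx(20.04, abs=0.005)
        assert res.p_value < 0.001

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2(ContingencyTable2x2(0, 0, 5, 5))

    def test_matches_scipy_uncorrected_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 400, 4)
            ours = pearson_chi2(ContingencyTable2x2(a, b, c, d))
            ref_stat, ref_p, _, _ = stats.chi2_contingency(
                [[a, b], [c, d]], correction=False)
            assert ours.statistic == pytest.approx(ref_stat, rel=1e-12)
            assert ours.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_p_decreases_with_statistic(self):
        ps = [chi2_survival(x) for x in (0.5, 1, 2, 4, 8, 16)]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))


class TestChi2Survival:
    def test_published_borderline_value(self):
        assert round(chi2_survival(3.26), 2) == 0.07

    def test_zero_statistic(self):
        assert chi2_survival(0.0) == 1.0

    def test_95th_percentile(self):
        """chi2(1) upper 5% point, checked against numeric integration
        of the density."""
        x = 3.841459
        grid = np.linspace(x, 200, 400001)
        dens = np.exp(-grid / 2) / np.sqrt(2 * np.pi * grid)
        oracle = np.trapezoid(dens, grid)
        assert chi2_survival(x) == pytest.approx(0.05, abs=1e-4)
        assert chi2_survival(x) == pytest.approx(oracle, abs=1e-6)

    def test_unsupported_df(self):
        with pytest.raises(ValidationError):
            chi2_survival(1.0, df=2)


class TestAlgorithmPerformance:
    def test_separable_cohort_perfect_under_1of3(self, epi):
        subjects = (
            [make_subject(f"C{i}", "CRC", [38.0, None, None])
             for i in range(20)]
            + [make_subject(f"N{i}", "NED", [None, None, None])
               for i in range(20)])
        cohort = Cohort(subjects=subjects, assay=epi)
        sens, spec = algorithm_performance(
            cohort, epi, AlgorithmSpec.from_name("1/3"))
        assert (sens.proportion, spec.proportion) == (1.0, 1.0)
        # one positive well fails the 3/3 quorum
        sens3, _ = algorithm_performance(
            cohort, epi, AlgorithmSpec.from_name("3/3"))
        assert sens3.proportion == 0.0

    def test_binomial_tail_recovered(self, epi):
        """Wells positive independently at p=0.6: the 2-of-3 sensitivity
        is the binomial tail 3 p^2 (1-p) + p^3 = 0.648."""
        rng = np.random.default_rng(11)
        p = 0.6
        n = 10_000
        subjects = [
            make_subject(f"C{i}", "CRC",
                         [38.0 if rng.random() < p else None
                          for _ in range(3)])
            for i in range(n)]
        subjects += [make_subject("N0", "NED", [None, None, None])]
        cohort = Cohort(subjects=subjects, assay=epi)
        sens, _ = algorithm_performance(
            cohort, epi, AlgorithmSpec.from_name("2/3"))
        expected = 3 * p ** 2 * (1 - p) + p ** 3
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(sens.proportion - expected) < 3 * se

    def test_invalid_subjects_excluded_from_denominator(self, epi):
        subjects = (
            [make_subject(f"C{i}", "CRC", [38.0, 38.0, 38.0])
             for i in range(10)]
            + [make_subject("CX", "CRC", [38.0, 38.0, 38.0],
                            control_ct=None)]
            + [make_subject(f"N{i}", "NED", [None, None, None])
               for i in range(10)])
        sens, _ = algorithm_performance(
            Cohort(subjects=subjects, assay=epi), epi,
            AlgorithmSpec.from_name("2/3"))
        assert sens.total == 10

    def test_overlapping_groups_rejected(self, epi, toy_cohort):
        with pytest.raises(ValidationError):
            algorithm_performance(toy_cohort, epi,
                                  AlgorithmSpec.from_name("1/3"),
                                  case_groups={Group.CRC},
                                  control_groups={Group.CRC})


class TestAveragedSingleReplicate:
    def test_mean_of_position_sensitivities(self, epi):
        """Positions engineered to sensitivities 0.70/0.71/0.73 average
        to 0.7133..."""
        targets = [70, 71, 73]
        subjects = []
        for i in range(100):
            cts = [38.0 if i < targets[r] else None for r in range(3)]
            subjects.append(make_subject(f"C{i}", "CRC", cts))
        subjects += [make_subject(f"N{i}", "NED", [None, None, None])
                     for i in range(10)]
        sens, spec = averaged_single_replicate_performance(
            Cohort(subjects=subjects, assay=epi), epi)
        assert sens == pytest.approx((0.70 + 0.71 + 0.73) / 3)
        assert spec == 1.0

    def test_single_well_assay_degenerates_to_plain_performance(
            self, sensi):
        subjects = ([make_subject(f"C{i}", "CRC", [38.0 if i < 7 else None])
                     for i in range(10)]
                    + [make_subject(f"N{i}", "NED", [None])
                       for i in range(10)])
        cohort = Cohort(subjects=subjects, assay=sensi)
        sens, spec = averaged_single_replicate_performance(
            cohort, sensi)
        s_est, sp_est = algorithm_performance(
            cohort, sensi, AlgorithmSpec.from_name("1/3"))
        assert sens == pytest.approx(s_est.proportion)
        assert spec == pytest.approx(sp_est.proportion)


class TestPdrByStratum:
    def test_stage_table_with_overall_row(self, epi):
        subjects = (
            [make_subject(f"A{i}", "CRC", [38.0, 38.0, 38.0], stage="I")
             for i in range(4)]
            + [make_subject(f"B{i}", "CRC", [None, None, None],
                            stage="II") for i in range(6)])
        table = pdr_by_stratum(Cohort(subjects=subjects, assay=epi), epi,
                               AlgorithmSpec.from_name("2/3"), "stage")
        assert list(table.index) == ["Stage I", "Stage II", "Overall"]
        assert table.loc["Overall", "positives"] == 4
        assert table.loc["Overall", "total"] == 10

    def test_group_table(self, epi, toy_cohort):
        table = pdr_by_stratum(toy_cohort, epi,
                               AlgorithmSpec.from_name("1/3"), "group")
        assert table.loc["CRC", "proportion"] == 1.0
        assert table.loc["NED", "proportion"] == 0.0

    def test_unknown_stratifier(self, epi, toy_cohort):
        with pytest.raises(ValidationError):
            pdr_by_stratum(toy_cohort, epi,
                           AlgorithmSpec.from_name("1/3"), "sex")


class TestSubjectScore:
    def test_kth_order_statistic_with_censoring(self, epi):
        s = make_subject("S", "CRC", [38.0, 41.0, None])
        assert subject_score(s, epi, 2) == 41.0
        assert subject_score(s, epi, 3) == 45.0  # censored well

    def test_all_undetected_scores_at_ceiling(self, epi):
        s = make_subject("S", "NED", [None, None, None])
        for k in (1, 2, 3):
            assert subject_score(s, epi, k) == 45.0

    def test_single_well_identity(self, sensi):
        s = make_subject("S", "NED", [39.5])
        assert subject_score(s, sensi, 1) == 39.5

    def test_invalid_subject_rejected(self, epi):
        s = make_subject("S", "CRC", [38.0, 39.0, 40.0], control_ct=None)
        with pytest.raises(ValidationError):
            subject_score(s, epi, 1)


def mann_whitney_auc(cases, controls):
    """All-pairs oracle: P(case < control) + 0.5 P(tie)."""
    wins = ties = 0
    for x in cases:
        for y in controls:
            wins += x < y
            ties += x == y
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([30.0] * 5, [45.0] * 5, censor_ct=45.0)
        assert curve.auc == pytest.approx(1.0)
        assert curve.max_observed_fpr == 0.0

    def test_identical_distributions_chance(self):
        scores = [31.0, 35.0, 40.0, 45.0, 45.0]
        curve = roc_curve(scores, list(scores), censor_ct=45.0)
        assert curve.auc == pytest.approx(0.5)

    def test_worked_example_equals_rank_sum(self):
        cases = [30.0, 32.0, 34.0, 45.0, 45.0]
        controls = [45.0, 45.0, 45.0, 45.0, 40.0]
        curve = roc_curve(cases, controls, censor_ct=45.0)
        assert curve.auc == pytest.approx(19 / 25)
        assert curve.auc == pytest.approx(
            mann_whitney_auc(cases, controls))

    def test_auc_equals_rank_sum_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n1, n2 = rng.integers(1, 50, 2)
            cases = np.minimum(
                np.round(rng.uniform(30, 47, n1), 1), 45.0)
            controls = np.minimum(
                np.round(rng.uniform(30, 47, n2), 1), 45.0)
            curve = roc_curve(cases, controls, censor_ct=45.0)
            assert curve.auc == pytest.approx(
                mann_whitney_auc(list(cases), list(controls)), abs=1e-12)

    def test_curve_monotone_and_truncated(self):
        rng = np.random.default_rng(9)
        cases = np.minimum(rng.normal(38, 3, 80), 45.0)
        controls = np.minimum(rng.normal(44, 2, 80), 45.0)
        curve = roc_curve(cases, controls, censor_ct=45.0)
        fprs = [p.false_positive_rate for p in curve.points]
        tprs = [p.true_positive_rate for p in curve.points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)
        assert curve.max_observed_fpr < 1.0  # censored mass never plotted

    def test_empty_inputs_rejected(self):
        with pytest.raises(EstimationError):
            roc_curve([], [45.0], censor_ct=45.0)


class TestSpecificityAtSensitivity:
    def test_perfect_curve(self):
        curve = roc_curve([30.0] * 5, [45.0] * 5, censor_ct=45.0)
        assert specificity_at_sensitivity(curve, 0.9) == pytest.approx(1.0)

    def test_chance_line_interpolation(self):
        scores = [float(x) for x in range(25, 45)]
        curve = roc_curve(scores, list(scores), censor_ct=45.0)
        for t in (0.25, 0.5, 0.77):
            assert specificity_at_sensitivity(curve, t) == pytest.approx(
                1 - t, abs=1e-9)

    def test_unreachable_beyond_censoring(self):
        # 20% of cases are censored: max realized TPR is 0.8
        cases = [30.0] * 8 + [45.0] * 2
        controls = [45.0] * 10
        curve = roc_curve(cases, controls, censor_ct=45.0)
        assert curve.max_tpr == pytest.approx(0.8)
        with pytest.raises(UnreachableTargetError):
            specificity_at_sensitivity(curve, 0.9)


class TestCompareAucBootstrap:
    def test_identical_inputs_delta_zero(self):
        rng = np.random.default_rng(2)
        cases = list(np.minimum(rng.normal(38, 3, 40), 45.0))
        controls = list(np.minimum(rng.normal(44, 2, 40), 45.0))
        res = compare_auc_bootstrap(cases, controls, cases, controls,
                                    censor_ct=45.0, n_boot=200, seed=1)
        assert res.delta_auc == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_fixed_seed_reproducible(self):
        args = ([30.0, 32.0, 40.0], [44.0, 45.0, 45.0],
                [31.0, 35.0, 45.0], [43.0, 45.0, 45.0])
        r1 = compare_auc_bootstrap(*args, censor_ct=45.0, n_boot=150,
                                   seed=7)
        r2 = compare_auc_bootstrap(*args, censor_ct=45.0, n_boot=150,
                                   seed=7)
        assert r1 == r2

    def test_separated_vs_chance_excludes_zero(self):
        rng = np.random.default_rng(4)
        cases_a = [30.0] * 60
        controls_a = [44.0] * 60
        chance = list(np.minimum(rng.uniform(30, 46, 60), 45.0))
        res = compare_auc_bootstrap(cases_a, controls_a, chance,
                                    list(chance), censor_ct=45.0,
                                    n_boot=300, seed=3)
        assert res.delta_auc == pytest.approx(0.5, abs=0.02)
        assert res.ci_low > 0.0

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValidationError):
            compare_auc_bootstrap([30.0], [45.0], [30.0], [45.0],
                                  censor_ct=45.0, n_boot=50)


def test_all_published_chi2_reproduced_from_counts():
    """Every published pairwise chi-square follows from its 2x2 counts
    under the uncorrected Pearson statistic."""
    for comp in PRINTED_CHI2_COMPARISONS:
        res = pearson_chi2(
            ContingencyTable2x2(comp.a, comp.b, comp.c, comp.d))
        assert abs(res.statistic - comp.printed_stat) <= 0.01, comp.label
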