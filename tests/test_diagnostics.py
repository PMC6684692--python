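"""Contingency tables, exact binomial CIs, ROC/AUC, Youden cut-off, DeLong."""

import math

import numpy as np
import pytest

from nac3d.diagnostics import (
    CohortRecord,
    ContingencyTable,
    best_cutoff,
    build_contingency,
    clopper_pearson_ci,
    compare_auc,
    diagnostic_metrics,
    reconstruct_table,
    roc_curve,
    round_half_up,
)
from nac3d.errors import DegenerateCohortError
from oracles import exhaustive_best_youden, pairwise_concordance_auc


def cohort(distances, involved):
    return [
        CohortRecord(str(i), float(d), bool(y))
        for i, (d, y) in enumerate(zip(distances, involved))
    ]


def random_cohort(rng, n=50):
    d = rng.uniform(0, 60, n).round(1)
    y = rng.random(n) < 0.4
    if y.all() or not y.any():
        y[0] = not y[0]
    return cohort(d, y)


class TestBuildContingency:
    def test_separated_cohort(self):
        rec = cohort([2, 7, 15, 40], [True, True, False, False])
        t = build_contingency(rec, 10.0)
        assert (t.tp, t.fn, t.tn, t.fp) == (2, 0, 2, 0)

    def test_cutoff_below_all_distances(self):
        rec = cohort([12, 20, 33], [True, False, True])
        t = build_contingency(rec, 5.0)
        assert t.tp == 0 and t.fp == 0

    def test_boundary_uses_le_by_default_and_lt_on_request(self):
        rec = cohort([10.0, 10.0], [True, False])
        le = build_contingency(rec, 10.0)
        assert (le.tp, le.fp) == (1, 1)
        lt = build_contingency(rec, 10.0, convention="lt")
        assert (lt.tp, lt.fp) == (0, 0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_per_record_tally(self, trial):
        rng = np.random.default_rng(40 + trial)
        rec = random_cohort(rng)
        cut = float(rng.uniform(0, 60))
        t = build_contingency(rec, cut)
        tp = sum(1 for r in rec if r.distance_mm <= cut and r.nac_involved)
        fp = sum(1 for r in rec if r.distance_mm <= cut and not r.nac_involved)
        fn = sum(1 for r in rec if r.distance_mm > cut and r.nac_involved)
        tn = sum(1 for r in rec if r.distance_mm > cut and not r.nac_involved)
        assert (t.tp, t.fp, t.tn, t.fn) == (tp, fp, tn, fn)

    def test_single_class_cohort_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            build_contingency(cohort([1, 2], [True, True]), 5.0)


class TestDiagnosticMetrics:
    def test_best_cutoff_column_of_the_validation_cohort(self):
        """23 involved / 49 uninvolved, sensitivity 78.3 / specificity 71.4
        imply tp=18, fn=5, tn=35, fp=14 and the derived metrics below."""
        s = diagnostic_metrics(ContingencyTable(tp=18, fn=5, tn=35, fp=14, cutoff_mm=30))
        assert s.sensitivity == 78.3
        assert s.specificity == 71.4
        assert s.ppv == 56.3
        assert s.npv == 87.5
        assert s.accuracy == 73.6

    def test_five_mm_column_of_the_validation_cohort(self):
        s = diagnostic_metrics(ContingencyTable(tp=2, fn=21, tn=49, fp=0, cutoff_mm=5))
        assert s.sensitivity == 8.7
        assert s.specificity == 100.0
        assert s.ppv == 100.0
        assert s.npv == 70.0
        assert s.accuracy == 70.8

    def test_undefined_ppv_flagged_not_raised(self):
        s = diagnostic_metrics(ContingencyTable(tp=0, fn=3, tn=5, fp=0, cutoff_mm=1))
        assert math.isnan(s.ppv)
        assert "ppv" in s.undefined
        assert "ppv" not in s.ci95

    def test_cis_cover_point_estimates(self):
        s = diagnostic_metrics(ContingencyTable(tp=18, fn=5, tn=35, fp=14, cutoff_mm=30))
        for key, (lo, hi) in s.ci95.items():
            assert lo - 0.5 <= getattr(s, key) <= hi + 0.5


class TestReconstructTable:
    def test_reconstruction_reproduces_printed_sens_spec(self):
        t = reconstruct_table(78.3, 71.4, n_involved=23, n_uninvolved=49)
        assert (t.tp, t.fn, t.tn, t.fp) == (18, 5, 35, 14)

    def test_unmatchable_percentage_rejected(self):
        # 50.0% cannot arise from 3 patients (0, 33.3, 66.7, 100 only)
        with pytest.raises(ValueError):
            reconstruct_table(50.0, 100.0, n_involved=3, n_uninvolved=4)

    def test_ambiguous_percentage_rejected(self):
        # at n=10000 several integer counts round to 50.0%
        with pytest.raises(ValueError):
            reconstruct_table(50.0, 100.0, n_involved=10000, n_uninvolved=4)


class TestClopperPearson:
    def test_nipple_segmentation_interval(self):
        assert clopper_pearson_ci(141, 154) == (86, 95)

    def test_per_lesion_interval(self):
        assert clopper_pearson_ci(75, 77) == (91, 100)

    def test_all_successes_upper_bound_is_100(self):
        lo, hi = clopper_pearson_ci(20, 20)
        assert hi == 100

    def test_level_to_one_widens_toward_full_interval(self):
        prev = clopper_pearson_ci(8, 12, level=0.9, as_int=False)
        for level in (0.99, 0.9999, 1 - 1e-12):
            lo, hi = clopper_pearson_ci(8, 12, level=level, as_int=False)
            assert lo < prev[0] and hi > prev[1]  # nested intervals
            prev = (lo, hi)
        assert lo < 2.0 and hi > 98.0

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(141, 154), (3, 10), (0, 7), (9, 9)]:
            lo, hi = clopper_pearson_ci(s, n, as_int=False)
            slo, shi = proportion_confint(s, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(100 * slo, abs=1e-9)
            assert hi == pytest.approx(100 * shi, abs=1e-9)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 4)


class TestRocCurve:
    def test_perfect_separation_gives_auc_one(self):
        rec = cohort([1, 2, 3, 20, 30, 40], [True, True, True, False, False, False])
        assert roc_curve(rec).auc == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_distance_gives_auc_half(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0, 50, 2000)
        y = rng.random(2000) < 0.5
        auc = roc_curve(cohort(d, y)).auc
        assert abs(auc - 0.5) < 0.04

    @pytest.mark.parametrize("trial", range(10))
    def test_trapezoid_auc_equals_pairwise_concordance(self, trial):
        rng = np.random.default_rng(70 + trial)
        n = int(rng.integers(10, 60))
        d = rng.choice(np.arange(0, 30, 2.5), size=n)  # force ties
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = not y[0]
        rec = cohort(d, y)
        assert roc_curve(rec).auc == pytest.approx(
            pairwise_concordance_auc(d, y), abs=1e-9
        )

    def test_curve_monotone_in_both_coordinates(self):
        rng = np.random.default_rng(13)
        roc = roc_curve(random_cohort(rng, 80))
        assert (np.diff(roc.points[:, 0]) >= -1e-12).all()
        assert (np.diff(roc.points[:, 1]) >= -1e-12).all()

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(DegenerateCohortError):
            roc_curve(cohort([1, 2], [True, True]))


class TestBestCutoff:
    def test_hand_built_cohort_unique_maximizer(self):
        d = [3, 6, 8, 11, 14, 22, 35, 50]
        y = [True, True, True, False, True, True, False, False]
        rec = cohort(d, y)
        roc = roc_curve(rec)
        t_oracle, j_oracle = exhaustive_best_youden(d, y)
        assert best_cutoff(roc) == t_oracle == 22
        assert roc.youden_at_best == pytest.approx(j_oracle)

    def test_separated_cohort_tie_rules_by_convention(self):
        d = [2, 4, 6, 20, 25, 30]
        y = [True, True, True, False, False, False]
        rec = cohort(d, y)
        # "<=": every cutoff in [6, 20) reaches J=1; smallest on the observed
        # grid is the largest involved distance
        assert best_cutoff(roc_curve(rec, convention="le")) == 6
        # "<": maximizers are (6, 20]; the observed-grid one is the smallest
        # uninvolved distance
        assert best_cutoff(roc_curve(rec, convention="lt")) == 20

    def test_shift_equivariance(self):
        rng = np.random.default_rng(17)
        rec = random_cohort(rng, 40)
        base = best_cutoff(roc_curve(rec))
        shifted = [CohortRecord(r.patient_id, r.distance_mm + 7.5, r.nac_involved)
                   for r in rec]
        assert best_cutoff(roc_curve(shifted)) == pytest.approx(base + 7.5)


class TestMonotonicitySweep:
    def test_sensitivity_up_specificity_down_in_cutoff(self):
        rng = np.random.default_rng(19)
        rec = random_cohort(rng, 60)
        prev_sens, prev_spec = -1.0, 101.0
        for cut in np.linspace(0, 70, 36):
            t = build_contingency(rec, float(cut))
            sens = t.tp / t.n_involved * 100
            spec = t.tn / t.n_uninvolved * 100
            assert sens >= prev_sens - 1e-9
            assert spec <= prev_spec + 1e-9
            assert (t.n_involved, t.n_uninvolved) == (
                sum(r.nac_involved for r in rec),
                sum(not r.nac_involved for r in rec),
            )
            prev_sens, prev_spec = sens, spec


class TestCompareAuc:
    def test_identical_methods_give_p_one(self):
        rng = np.random.default_rng(23)
        d = rng.uniform(0, 40, 60)
        y = rng.random(60) < 0.4
        y[0], y[1] = True, False
        res = compare_auc(d, d, y)
        assert res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_power_increases_with_sample_size(self):
        """Method A strictly more concordant than B: rejections at n=200
        must exceed those at n=50 (monotone power)."""
        rng = np.random.default_rng(29)
        rates = {}
        for n in (50, 200):
            rej = 0
            for _ in range(500):
                y = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
                signal = np.where(y, -8.0, 0.0)
                a = signal + rng.normal(0, 6, n) + 40
                b = signal + rng.normal(0, 14, n) + 40
                if compare_auc(np.clip(a, 0, None), np.clip(b, 0, None), y).p_value < 0.05:
                    rej += 1
            rates[n] = rej / 500
        assert rates[200] > rates[50]
        assert rates[200] > 0.5

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1, 2, 3], [1, 2], [True, False, True])

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            compare_auc([1, 2], [3, 4], [True, True])


class TestRounding:
    def test_half_up_at_the_exact_midpoint(self):
        assert round_half_up(56.25, 1) == 56.3
        assert round_half_up(95.43) == 95.0
        assert round_half_up(90.93) == 91.0
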