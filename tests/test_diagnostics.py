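"""Diagnostic-accuracy statistics: 2x2 metrics, exact CIs, ROC, subgroups."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import marsha_screen as ms
from marsha_screen.diagnostics import RocPoint, likelihood_ratios, select_cutpoint

tables = st.builds(
    ms.ConfusionTable,
    tp=st.integers(0, 200),
    fn=st.integers(0, 200),
    fp=st.integers(0, 200),
    tn=st.integers(0, 200),
)


class TestConfusionTable:
    def test_crosstab(self):
        t = ms.confusion_table([1, 1, 0, 0], [1, 0, 0, 1])
        assert (t.tp, t.fn, t.tn, t.fp) == (1, 1, 1, 1)

    def test_empty_is_all_zero_and_metrics_error(self):
        t = ms.confusion_table([], [])
        assert t.n == 0
        with pytest.raises(ValueError):
            ms.metrics(t)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ms.confusion_table([1, 0], [1])

    def test_reconstructed_study_table(self, reconstructed_table):
        t = reconstructed_table
        assert (t.tp, t.fn, t.fp, t.tn) == (98, 19, 10, 97)
        assert t.n == 224 and t.positives == 117 and t.screen_positives == 108


class TestMetrics:
    def test_full_sample_values(self, reconstructed_table):
        m = ms.metrics(reconstructed_table)
        assert m.sensitivity.value == pytest.approx(0.838, abs=5e-4)
        assert m.specificity.value == pytest.approx(0.907, abs=5e-4)
        assert m.ppv.value == pytest.approx(0.907, abs=5e-4)
        assert m.npv.value == pytest.approx(0.836, abs=5e-4)
        assert m.accuracy.value == pytest.approx(0.871, abs=5e-4)

    def test_perfect_table(self):
        m = ms.metrics(ms.ConfusionTable(tp=1, fn=0, fp=0, tn=1))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(m, name).value == 1.0

    def test_cutoff2_row(self):
        # tp = round(0.436 * 117) = 51 with perfect specificity
        m = ms.metrics(ms.ConfusionTable(tp=51, fn=66, fp=0, tn=107))
        assert m.sensitivity.value == pytest.approx(0.436, abs=5e-4)
        assert m.specificity.value == 1.0

    def test_zero_denominator_is_undefined_not_zero(self):
        m = ms.metrics(ms.ConfusionTable(tp=0, fn=0, fp=3, tn=7))
        assert not m.sensitivity.defined
        assert "zero denominator" in m.sensitivity.note
        assert m.specificity.value == 0.7

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(t=tables)
    def test_bayes_and_accuracy_identities(self, t):
        """PPV and accuracy follow from (sens, spec, prevalence) exactly."""
        if t.n == 0 or t.positives == 0 or t.negatives == 0 or t.screen_positives == 0:
            return
        m = ms.metrics(t)
        pi = t.prevalence
        sens, spec = m.sensitivity.value, m.specificity.value
        ppv_pred = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
        assert m.ppv.value == pytest.approx(ppv_pred, abs=1e-12)
        assert m.accuracy.value == pytest.approx(sens * pi + spec * (1 - pi), abs=1e-12)


class TestExactCI:
    @pytest.mark.parametrize(
        "k, n, lo, hi",
        [
            (98, 117, 0.758, 0.899),
            (107, 107, 0.966, 1.0),
            (97, 107, 0.835, 0.954),
            (98, 108, 0.836, 0.955),
        ],
    )
    def test_published_ci_cells(self, k, n, lo, hi):
        ci = ms.exact_binomial_ci(k, n)
        assert ci.lower == pytest.approx(lo, abs=5e-4)
        assert ci.upper == pytest.approx(hi, abs=5e-4)

    def test_degenerate_endpoints(self):
        assert ms.exact_binomial_ci(0, 10).lower == 0.0
        assert ms.exact_binomial_ci(10, 10).upper == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ms.exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            ms.exact_binomial_ci(-1, 4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(k=st.integers(0, 60), n=st.integers(1, 60))
    def test_matches_beta_quantile_closed_form(self, k, n):
        """Independent oracle: CP bounds are beta-distribution quantiles."""
        if k > n:
            return
        ci = ms.exact_binomial_ci(k, n)
        lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
        assert ci.lower == pytest.approx(lo, abs=1e-10)
        assert ci.upper == pytest.approx(hi, abs=1e-10)

    def test_coverage_at_least_nominal(self):
        """Exact intervals are conservative: simulated coverage >= 95%."""
        from statsmodels.stats.proportion import proportion_confint

        rng = np.random.default_rng(42)
        n, p, reps = 117, 0.84, 10_000
        ks = rng.binomial(n, p, size=reps)
        lo, hi = proportion_confint(ks, n, alpha=0.05, method="beta")
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.95


class TestLikelihoodRatios:
    def test_study_lr_positive_rounds_to_nine(self, reconstructed_table):
        lr = likelihood_ratios(reconstructed_table)
        assert lr.lr_positive == pytest.approx(8.96, abs=0.01)
        assert round(lr.lr_positive) == 9

    def test_uninformative_test(self):
        lr = likelihood_ratios(ms.ConfusionTable(tp=1, fn=1, fp=1, tn=1))
        assert lr.lr_positive == pytest.approx(1.0)
        assert lr.lr_negative == pytest.approx(1.0)

    def test_perfect_specificity_gives_infinity(self):
        lr = likelihood_ratios(ms.ConfusionTable(tp=51, fn=66, fp=0, tn=107))
        assert math.isinf(lr.lr_positive)

    def test_post_test_odds_multiply_pretest_odds(self, reconstructed_table):
        lr = likelihood_ratios(reconstructed_table, pretest_prevalence=0.2)
        assert lr.post_test_odds_positive == pytest.approx(0.25 * lr.lr_positive)


STUDY_POS_SCORES = [0] * 19 + [1] * 47 + [2] * 29 + [3] * 22  # 117 reference-positives
STUDY_NEG_SCORES = [0] * 97 + [1] * 10  # 107 reference-negatives


def study_roc():
    scores = STUDY_POS_SCORES + STUDY_NEG_SCORES
    ref = [1] * len(STUDY_POS_SCORES) + [0] * len(STUDY_NEG_SCORES)
    return ms.roc_curve(scores, ref)


class TestRoc:
    def test_study_curve_points(self):
        roc = study_roc()
        by_cut = {p.cutpoint: p for p in roc.points}
        assert by_cut[1].sensitivity == pytest.approx(98 / 117)
        assert by_cut[1].false_positive_rate == pytest.approx(10 / 107)
        assert by_cut[2].sensitivity == pytest.approx(51 / 117)
        assert by_cut[2].false_positive_rate == 0.0
        assert by_cut[3].sensitivity == pytest.approx(22 / 117)
        # sensitivity and FPR are non-increasing in the cutpoint
        sens = [by_cut[c].sensitivity for c in (1, 2, 3)]
        fpr = [by_cut[c].false_positive_rate for c in (1, 2, 3)]
        assert sens == sorted(sens, reverse=True)
        assert fpr == sorted(fpr, reverse=True)

    def test_perfect_separation(self):
        roc = ms.roc_curve([0, 0, 3, 3], [0, 0, 1, 1])
        assert roc.auc_empirical == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ms.roc_curve([0, 1], [1, 1])

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 4, size=2000)
        ref = rng.permutation(np.repeat([0, 1], 1000))
        roc = ms.roc_curve(scores, ref)
        assert roc.auc_empirical == pytest.approx(0.5, abs=0.05)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        pos=st.lists(st.integers(0, 3), min_size=1, max_size=25),
        neg=st.lists(st.integers(0, 3), min_size=1, max_size=25),
    )
    def test_auc_equals_pair_probability(self, pos, neg):
        """Trapezoidal AUC equals P(score+ > score-) + 0.5 P(tie),
        checked by brute force over all positive/negative pairs."""
        scores = pos + neg
        ref = [1] * len(pos) + [0] * len(neg)
        roc = ms.roc_curve(scores, ref)
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc.auc_empirical == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        pos=st.lists(st.integers(0, 3), min_size=2, max_size=30),
        neg=st.lists(st.integers(0, 3), min_size=2, max_size=30),
    )
    def test_auc_matches_sklearn(self, pos, neg):
        from sklearn.metrics import roc_auc_score

        scores = pos + neg
        ref = [1] * len(pos) + [0] * len(neg)
        roc = ms.roc_curve(scores, ref)
        assert roc.auc_empirical == pytest.approx(
            roc_auc_score(ref, scores), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        scores=st.lists(st.integers(0, 3), min_size=4, max_size=60),
        ref=st.randoms(use_true_random=False),
    )
    def test_cutpoint_monotonicity(self, scores, ref):
        """Raising the cutpoint never raises sensitivity or lowers specificity."""
        labels = [ref.randint(0, 1) for _ in scores]
        if sum(labels) in (0, len(labels)):
            return
        roc = ms.roc_curve(scores, labels)
        pts = sorted(roc.points, key=lambda p: p.cutpoint)
        for a, b in zip(pts, pts[1:]):
            assert b.sensitivity <= a.sensitivity + 1e-12
            assert b.specificity >= a.specificity - 1e-12


class TestCutpointSelection:
    def test_study_selection_under_both_rules(self):
        roc = study_roc()
        assert select_cutpoint(roc, "closest_to_corner") == 1
        assert select_cutpoint(roc, "youden") == 1
        # the published geometry: distances and Youden J per cutpoint
        d = {p.cutpoint: p.distance_to_corner for p in roc.points}
        assert d[1] == pytest.approx(np.hypot(10 / 107, 19 / 117), abs=1e-12)
        assert d[1] == pytest.approx(0.187, abs=1e-3)
        assert d[2] == pytest.approx(0.564, abs=1e-3)
        assert d[3] == pytest.approx(0.812, abs=1e-3)
        j = {p.cutpoint: p.youden for p in roc.points}
        assert j[1] == pytest.approx(0.744, abs=1e-3)

    def test_tie_goes_to_smaller_cutpoint(self):
        pts = [RocPoint(2, 0.8, 0.1), RocPoint(1, 0.8, 0.1)]
        assert select_cutpoint(pts, "closest_to_corner") == 1
        assert select_cutpoint(pts, "youden") == 1

    def test_single_point(self):
        assert select_cutpoint([RocPoint(3, 0.2, 0.0)]) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_cutpoint([])


class TestSubgroups:
    def test_full_sample_roc_area(self, study_cohort):
        sub = ms.subgroup_analysis(study_cohort, "gender")
        full = sub[sub.group == "full_sample"].iloc[0]
        assert full["roc_area_single"] == pytest.approx(
            (full["sensitivity"] + full["specificity"]) / 2
        )
        assert full["n"] == len(study_cohort)

    def test_reconstructed_full_sample_area(self, reconstructed_table):
        m = ms.metrics(reconstructed_table)
        assert m.roc_area_single == pytest.approx(0.872, abs=5e-4)

    def test_homogeneous_groups_have_similar_sensitivity(self, study_cohort):
        """Demographics are independent of severity in the generator, so
        subgroup sensitivity varies only by sampling noise."""
        sub = ms.subgroup_analysis(study_cohort, "sexual_orientation")
        groups = sub[sub.group != "full_sample"]
        assert groups["sensitivity"].max() - groups["sensitivity"].min() < 0.05

    def test_degenerate_group_marked_undefined(self):
        cfg = ms.study_config(n=60, seed=2)
        df = ms.generate_cohort(cfg)
        df["flag"] = "a"
        # one group with no reference positives: zero out all items
        df.loc[:9, list(cfg.item_ids)] = 0
        df.loc[:9, "flag"] = "b"
        sub = ms.subgroup_analysis(df, "flag", min_n=100)
        row_b = sub[sub.group == "b"].iloc[0]
        assert np.isnan(row_b["sensitivity"])
        assert row_b["exploratory"]

    def test_unknown_grouping_column(self, study_cohort):
        with pytest.raises(KeyError):
            ms.subgroup_analysis(study_cohort, "shoe_size")


class TestReconstruction:
    def test_unique_recovery_from_published_metrics(self, reconstructed_table):
        assert (reconstructed_table.tp, reconstructed_table.fp) == (98, 10)

    def test_ambiguity_detected(self):
        # at n=2 the two admissible tables deviate equally from these targets
        with pytest.raises(ValueError):
            ms.reconstruct_confusion_table(
                n=2, n_reference_positive=1,
                sensitivity=0.5, specificity=0.5, ppv=0.5, npv=0.5, accuracy=0.5,
            )
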