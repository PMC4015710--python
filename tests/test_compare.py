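"""Statistics layer: Spearman, dendrogram, ROC/DeLong, ICC, Friedman."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import airtrap as at
from airtrap.compare import delong_auc_ci


def _table(**cols):
    return pd.DataFrame(cols)


class TestSpearman:
    def test_monotone_transform_rho_one(self):
        x = np.linspace(0, 3, 20)
        t = _table(dn2=x, crit=np.exp(x))
        assert at.spearman_vs_dn2(t, "crit").rho == pytest.approx(1.0)

    def test_antitone_rho_minus_one(self):
        x = np.arange(10.0)
        assert at.spearman_vs_dn2(_table(dn2=x, crit=-x), "crit").rho == pytest.approx(-1.0)

    def test_hand_rank_oracle(self):
        # brute-force rank formula: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        d = sps.rankdata(x) - sps.rankdata(y)
        expected = 1 - 6 * (d**2).sum() / (5 * 24)
        res = at.spearman_vs_dn2(_table(dn2=x, crit=y), "crit")
        assert res.rho == pytest.approx(expected)
        assert expected == pytest.approx(0.8)

    def test_constant_column_flagged(self):
        res = at.spearman_vs_dn2(_table(dn2=np.arange(6.0), crit=np.ones(6)), "crit")
        assert not res.defined and math.isnan(res.rho)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            at.spearman_vs_dn2(_table(dn2=[1, 2, 3.0], crit=[1, 2, 3.0]), "crit")


class TestDendrogram:
    def test_identical_variables_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        t = _table(dn2=a, u=a.copy(), v=rng.normal(size=30))
        d = at.build_dendrogram(t, ["dn2", "u", "v"])
        assert d.heights[0] == pytest.approx(0.0, abs=1e-12)
        assert set(d.linkage[0, :2].astype(int)) == {0, 1}

    def test_strong_pair_merges_first(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = a + 0.3 * rng.normal(size=200)  # |rho| ~ 0.95 with a
        c = rng.normal(size=200)
        d = at.build_dendrogram(_table(a=a, b=b, c=c), ["a", "b", "c"])
        assert set(d.linkage[0, :2].astype(int)) == {0, 1}
        assert np.all(np.diff(d.heights) >= -1e-12)  # heights non-decreasing

    def test_heights_within_unit_interval(self):
        rng = np.random.default_rng(2)
        t = _table(**{f"v{i}": rng.normal(size=40) for i in range(5)})
        d = at.build_dendrogram(t, list(t.columns))
        assert (d.heights >= 0).all() and (d.heights <= 1 + 1e-12).all()

    def test_constant_variable_rejected_with_name(self):
        t = _table(dn2=np.arange(10.0), u=np.ones(10), v=np.arange(10.0) ** 2)
        with pytest.raises(ValueError, match="u"):
            at.build_dendrogram(t, ["dn2", "u", "v"])

    def test_closest_branches_recover_strongest_link(self):
        hits = 0
        for seed in range(30):
            t = at.generate_cohort(at.CohortSpec(n_subjects=50, seed=seed))
            d = at.build_dendrogram(t, ["dn2"] + [f"{c}_mean" for c in at.CRITERIA])
            hits += "e_over_i_mld_mean" in d.closest_to("dn2", k=3)
        assert hits >= 29

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(3)
        t = _table(**{f"v{i}": rng.normal(size=30) for i in range(4)})
        nwk = at.build_dendrogram(t, list(t.columns)).to_newick()
        assert nwk.endswith(";")
        for name in t.columns:
            assert name in nwk


class TestROC:
    def test_perfect_separation(self):
        vals = np.r_[np.zeros(20), np.ones(20)]
        labels = vals > 0.5
        r = at.roc_analysis(vals, labels)
        assert r.auc == 1.0
        assert 0.0 < r.best_threshold <= 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_binormal_closed_form(self, rng):
        pos = rng.normal(1, 1, 30000)
        neg = rng.normal(0, 1, 30000)
        r = at.roc_analysis(np.r_[pos, neg], np.r_[np.ones(30000), np.zeros(30000)] > 0)
        assert r.auc == pytest.approx(sps.norm.cdf(1 / np.sqrt(2)), abs=0.01)
        lo, hi = r.auc_ci
        assert lo <= r.auc <= hi

    def test_independent_labels_auc_half(self, rng):
        vals = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert at.roc_analysis(vals, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=300)
        labels = (vals + rng.normal(size=300)) > 0
        a = at.roc_analysis(vals, labels)
        b = at.roc_analysis(np.exp(vals), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert np.allclose(a.tpr, b.tpr) and np.allclose(a.fpr, b.fpr)

    def test_label_duality(self, rng):
        vals = rng.normal(size=400)
        labels = (vals + rng.normal(size=400)) > 0
        a = at.roc_analysis(vals, labels, direction="higher")
        b = at.roc_analysis(vals, ~labels, direction="lower")
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_negation_flips_direction_same_auc(self, rng):
        vals = rng.normal(size=400)
        labels = (vals + rng.normal(size=400)) > 0
        a = at.roc_analysis(vals, labels)
        b = at.roc_analysis(-vals, labels)
        assert a.direction == "higher" and b.direction == "lower"
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert b.best_threshold == pytest.approx(-a.best_threshold, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            at.roc_analysis(np.arange(5.0), np.ones(5, bool))

    def test_delong_matches_mann_whitney(self, rng):
        pos = rng.normal(0.5, 1, 80)
        neg = rng.normal(0, 1, 120)
        auc, _, _ = delong_auc_ci(pos, neg)
        u, _ = sps.mannwhitneyu(pos, neg, alternative="two-sided")
        assert auc == pytest.approx(u / (80 * 120))


class TestICC:
    def test_identical_readers_exactly_one(self, rng):
        a = rng.normal(size=50)
        assert at.icc_two_readers(a, a).icc == pytest.approx(1.0, abs=1e-12)

    def test_variance_component_closed_form(self):
        a, b = at.generate_reader_pair([0.0] * 5000, subject_sd=2.0, error_sd=1.0, seed=42)
        assert at.icc_two_readers(a, b).icc == pytest.approx(0.8, abs=0.02)

    def test_constant_bias_penalised_matches_closed_form(self, rng):
        s = rng.normal(0, 2.0, 2000)
        a, b = s, s + 10.0
        # with zero residual error: ICC(2,1) = MSR/(MSR + k*MSC/n), MSC = n*bias^2/2...
        # closed form from the ANOVA algebra: icc = 2v/(2v + bias^2) with v = var(s)
        v = s.var(ddof=1)
        expected = 2 * v / (2 * v + 100.0)
        res = at.icc_two_readers(a, b)
        assert res.icc == pytest.approx(expected, rel=1e-6)
        assert res.icc < 1.0
        # the consistency form ignores the bias entirely
        assert at.icc_two_readers(a, b, model="icc3_1").icc == pytest.approx(1.0, abs=1e-9)

    def test_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b = at.generate_reader_pair(list(rng.normal(0, 3, 40)), 1.0, 0.8, seed=9)
        ours = at.icc_two_readers(a, b).icc
        df = pd.DataFrame({
            "subject": np.r_[np.arange(40), np.arange(40)],
            "rater": ["a"] * 40 + ["b"] * 40,
            "score": np.r_[a, b],
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]  # two-way random, absolute, single
        assert ours == pytest.approx(float(icc2), abs=1e-6)

    def test_zero_variance_flagged(self):
        res = at.icc_two_readers(np.ones(10), np.ones(10))
        assert not res.defined

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            at.icc_two_readers([1, 2.0], [1, 2.0])


class TestFriedman:
    def test_identical_levels_p_one(self):
        x = np.tile(np.arange(4.0), (8, 1)) * 0 + 5.0
        res = at.level_heterogeneity_test(x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_shifted_level_highly_significant(self, rng):
        x = rng.normal(size=(30, 4))
        x[:, 1] += 50.0
        assert at.level_heterogeneity_test(x).p_value < 1e-3

    def test_missing_subjects_dropped_and_counted(self, rng):
        x = rng.normal(size=(12, 4))
        x[2, 1] = np.nan
        res = at.level_heterogeneity_test(x)
        assert res.n_dropped == 1 and res.n_subjects == 11

    def test_exact_matches_brute_force_enumeration(self, rng):
        x = rng.normal(size=(3, 4))
        res = at.level_heterogeneity_test(x, method="exact")
        # independent oracle: loop over all within-subject orderings
        ranks = np.vstack([sps.rankdata(r) for r in x])
        n, k = ranks.shape
        target = n * (k + 1) / 2.0
        s_obs = (((ranks.sum(axis=0)) - target) ** 2).sum()
        count = total = 0
        for assign in itertools.product(itertools.permutations(range(k)), repeat=n):
            cols = np.zeros(k)
            for row, perm in zip(ranks, assign):
                cols += row[list(perm)]
            total += 1
            count += ((cols - target) ** 2).sum() >= s_obs - 1e-9
        assert res.method == "exact"
        assert res.p_value == pytest.approx(count / total)

    def test_chisq_matches_scipy(self, rng):
        x = rng.normal(size=(25, 4))
        res = at.level_heterogeneity_test(x, method="chisq")
        stat, p = sps.friedmanchisquare(*(x[:, j] for j in range(4)))
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)


class TestRunComparison:
    def test_noiseless_cohort_top_criterion(self):
        t = at.generate_cohort(
            at.CohortSpec(n_subjects=60, dn2_noise_sd=0.0, index_noise_sd=0.0, seed=4)
        )
        rep = at.run_comparison(t)
        # all nine mean-level criteria correlate perfectly in magnitude
        assert rep.spearman["rho"].abs().min() == pytest.approx(1.0)
        assert rep.roc_ranking[0] in rep.top_branches

    def test_prevalence_counting(self):
        t = at.generate_cohort(at.CohortSpec(n_subjects=40, seed=6))
        rep = at.run_comparison(t)
        assert rep.prevalence == pytest.approx((t["dn2"] > 2.5).mean())

    def test_single_class_roc_skipped(self):
        t = at.generate_cohort(at.CohortSpec(n_subjects=30, seed=7))
        t["dn2"] = t["dn2"] + 100.0  # everyone obstructed
        t["obstructed"] = True
        rep = at.run_comparison(t)
        assert rep.roc == {}
        assert any("one obstruction class" in m for m in rep.messages)

    def test_inconsistent_label_rejected(self):
        t = at.generate_cohort(at.CohortSpec(n_subjects=20, seed=8))
        t.loc[0, "obstructed"] = not t.loc[0, "obstructed"]
        with pytest.raises(ValueError):
            at.run_comparison(t)
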