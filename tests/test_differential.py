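import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

import microresist as mr
from microresist import differential as da, diversity as dv


def table_from_matrix(x, unit="relative", prefix="k__B|s__f"):
    names = [f"{prefix}{i}" for i in range(x.shape[0])]
    cols = [f"s{j}" for j in range(x.shape[1])]
    return mr.AbundanceTable(pd.DataFrame(x, index=names, columns=cols), unit, "species")


class TestPermanova:
    def test_perfect_separation(self):
        x = np.repeat([1.0, 0.0], 10)
        d = np.abs(x[:, None] - x[None, :])
        dm = dv.DistanceMatrix([f"s{i}" for i in range(20)], d, "m")
        res = da.permanova(dm, ["g1"] * 10 + ["g2"] * 10, n_perm=99, seed=0)
        assert res["R2"] == pytest.approx(1.0)
        # floor of the permutation p-value; a permutation can reproduce the
        # exact partition (rate ~1e-5 per draw), so allow one collision
        assert res["p"] <= 2 / 100

    def test_euclidean_equals_anova_f(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        d = np.abs(x[:, None] - x[None, :])
        dm = dv.DistanceMatrix([f"s{i}" for i in range(30)], d, "euclidean")
        res = da.permanova(dm, g, n_perm=9, seed=0)
        f_classic = sps.f_oneway(x[:10], x[10:20], x[20:])[0]
        assert res["pseudo_F"] == pytest.approx(f_classic, abs=1e-8)

    def test_single_sample_group_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = dv.DistanceMatrix(list("abc"), d, "m")
        with pytest.raises(ValueError, match="at least 2 samples"):
            da.permanova(dm, ["g1", "g1", "g2"])

    def test_r2_in_unit_interval_and_p_bounds(self):
        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(8), size=20).T
        dm = dv.bray_curtis(table_from_matrix(x))
        res = da.permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=3)
        assert 0 <= res["R2"] <= 1
        assert 1 / 200 <= res["p"] <= 1


class TestOrdinalRegression:
    LAB = (["non_responder"] * 30 + ["partial_responder"] * 30 + ["responder"] * 30)

    def test_null_feature_has_small_beta(self):
        rng = np.random.default_rng(0)
        f = da.fit_ordinal_regression(rng.normal(size=90), self.LAB)
        assert abs(f.beta) < 0.5 and f.p > 0.01 and not f.separation

    def test_constant_feature_flagged_invalid(self):
        f = da.fit_ordinal_regression(np.ones(90), self.LAB)
        assert not f.valid

    def test_all_labels_identical_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            da.fit_ordinal_regression(np.arange(6.0), ["responder"] * 6)

    def test_perfect_monotone_sets_separation_flag(self):
        lab = ["non_responder"] * 2 + ["partial_responder"] * 2 + ["responder"] * 2
        f = da.fit_ordinal_regression(np.array([1, 1, 2, 2, 3, 3], float), lab)
        assert f.separation and f.beta > 0 and f.p < 0.05

    def test_gradient_vanishes_at_optimum(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            f = da.fit_ordinal_regression(rng.normal(size=90), self.LAB)
            assert f.max_grad < 1e-6

    def test_direction_follows_shift_sign(self):
        rng = np.random.default_rng(5)
        shift = np.repeat([0.0, 1.0, 2.0], 30)
        up = da.fit_ordinal_regression(rng.normal(size=90) + shift, self.LAB)
        down = da.fit_ordinal_regression(rng.normal(size=90) - shift, self.LAB)
        assert up.direction == "responder" and down.direction == "non_responder"

    def test_matches_statsmodels_ordered_model(self):
        # independent route: statsmodels' cumulative-logit fit
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1, 2], 30)
        for shift in (0.0, 0.7):
            x = rng.normal(size=90) + shift * y
            ours = da.fit_ordinal_regression(x, self.LAB)
            theirs = OrderedModel(y, x[:, None], distr="logit").fit(
                method="bfgs", disp=False, gtol=1e-9)
            assert ours.beta == pytest.approx(theirs.params[0], abs=1e-5)
            assert ours.p == pytest.approx(theirs.pvalues[0], rel=1e-3, abs=1e-8)

    def test_thresholds_strictly_increasing(self):
        rng = np.random.default_rng(6)
        f = da.fit_ordinal_regression(rng.normal(size=90), self.LAB)
        assert f.thresholds[0] < f.thresholds[1]

    def test_ordinal_da_table_has_bh_q(self):
        rng = np.random.default_rng(7)
        x = rng.dirichlet(np.ones(10), size=90).T
        t = table_from_matrix(x)
        labels = pd.Series(self.LAB, index=t.sample_ids)
        out = da.ordinal_da(t, labels)
        ok = out["q"].notna()
        assert (out.loc[ok, "q"] >= out.loc[ok, "p"] - 1e-12).all()


class TestWilcoxon:
    def _table_labels(self, xr, xn):
        x = np.hstack([xr, xn])
        t = table_from_matrix(x, unit="cpm")
        lab = pd.Series(["responder"] * xr.shape[1] + ["non_responder"] * xn.shape[1],
                        index=t.sample_ids)
        return t, lab

    def test_equal_means_zero_log2fc(self):
        x = np.tile(np.array([[5.0, 10.0]]).T, (1, 8))
        t, lab = self._table_labels(x, x)
        out = da.wilcoxon_da(t, lab)
        assert np.allclose(out["log2FC"], 0.0)

    def test_disjoint_ranges_attain_minimal_p(self):
        rng = np.random.default_rng(0)
        xr = rng.uniform(10, 11, size=(1, 10))
        xn = rng.uniform(1, 2, size=(1, 10))
        t, lab = self._table_labels(xr, xn)
        out = da.wilcoxon_da(t, lab)
        # most extreme rank-sum for 10 vs 10 under the normal approximation
        u_stat, p_min = sps.mannwhitneyu(np.arange(10), 10 + np.arange(10),
                                         alternative="two-sided", method="asymptotic")
        assert out["p"][0] == pytest.approx(p_min)
        assert out["log2FC"][0] > 0

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=(300, 40))
        t, lab = self._table_labels(x[:, :20], x[:, 20:])
        out = da.wilcoxon_da(t, lab)
        ks = sps.kstest(out["p"], "uniform")
        assert ks.pvalue > 1e-3

    def test_empty_group_rejected(self):
        x = np.ones((2, 4))
        t = table_from_matrix(x, unit="cpm")
        lab = pd.Series(["responder"] * 4, index=t.sample_ids)
        with pytest.raises(ValueError, match="non-empty"):
            da.wilcoxon_da(t, lab)


class TestChiSquare:
    def test_identical_proportions_null(self):
        chi2, p = da.chi_square_enrichment(5, 50, 10, 100)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_table_pearson_value(self):
        # 20/100 vs 5/100, Pearson without continuity correction
        chi2, p = da.chi_square_enrichment(20, 100, 5, 100)
        assert chi2 == pytest.approx(10.2857, abs=1e-4)
        assert p < 0.01

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected"):
            da.chi_square_enrichment(43, 384, 0, 11)

    def test_hits_exceeding_totals_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            da.chi_square_enrichment(10, 5, 1, 10)


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.01, 1, size=(1, 20))
        a = table_from_matrix(x, unit="cpm", prefix="k__B|s__a")
        b = table_from_matrix(np.exp(x), unit="cpm", prefix="k__B|s__b")
        out = da.spearman_assoc(a, b)
        assert out["rho"][0] == pytest.approx(1.0)
        assert out["p"][0] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_flips_sign(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=(1, 15))
        a = table_from_matrix(x, unit="cpm", prefix="k__B|s__a")
        b = table_from_matrix(x.max() + 0.1 - x, unit="cpm", prefix="k__B|s__b")
        out = da.spearman_assoc(a, b)
        assert out["rho"][0] == pytest.approx(-1.0)

    def test_constant_vector_flagged_not_tested(self):
        a = table_from_matrix(np.ones((1, 10)), unit="cpm", prefix="k__B|s__a")
        b = table_from_matrix(np.random.default_rng(0).uniform(size=(1, 10)),
                              unit="cpm", prefix="k__B|s__b")
        out = da.spearman_assoc(a, b)
        assert np.isnan(out["rho"][0]) and np.isnan(out["q"][0])

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(2)
        xa, xb = rng.uniform(size=(3, 25)), rng.uniform(size=(2, 25))
        out = da.spearman_assoc(table_from_matrix(xa, unit="cpm", prefix="k__B|s__a"),
                                table_from_matrix(xb, unit="cpm", prefix="k__B|s__b"))
        for _, row in out.iterrows():
            i = int(row.feature_a.rsplit("a", 1)[1])
            j = int(row.feature_b.rsplit("b", 1)[1])
            rho, p = sps.spearmanr(xa[i], xb[j])
            assert row.rho == pytest.approx(rho, abs=1e-12)
            assert row.p == pytest.approx(p, rel=1e-6)

    def test_null_critical_value_near_permutation_oracle(self):
        rng = np.random.default_rng(3)
        xa, xb = rng.normal(size=(25, 100)), rng.normal(size=(25, 100))
        out = da.spearman_assoc(
            table_from_matrix(np.abs(xa) + 1, unit="cpm", prefix="k__B|s__a"),
            table_from_matrix(np.abs(xb) + 1, unit="cpm", prefix="k__B|s__b"))
        q95 = np.quantile(np.abs(out["rho"]), 0.95)
        assert q95 == pytest.approx(0.196, abs=0.03)

    def test_too_few_shared_samples_rejected(self):
        a = table_from_matrix(np.ones((2, 3)), unit="cpm", prefix="k__B|s__a")
        b = table_from_matrix(np.ones((2, 3)), unit="cpm", prefix="k__B|s__b")
        with pytest.raises(ValueError, match="4 shared"):
            da.spearman_assoc(a, b)


class TestContributionLinks:
    def _stratified(self):
        cols = [f"s{j}" for j in range(6)]
        data = pd.DataFrame({
            "PWY-1": [300.0] * 6,
            "PWY-1|g__A.s__spA": [200.0] * 6,
            "PWY-1|g__B.s__spB": [100.0] * 6,
            "PWY-2": [50.0] * 6,
            "PWY-2|g__A.s__spA": [50.0] * 6,
        }, index=cols).T
        return mr.AbundanceTable(data, "cpm", "pathway")

    def test_weight_ratio_recovered(self):
        links = da.link_contributions(self._stratified(),
                                      ["k__B|s__spA", "k__B|s__spB"],
                                      ["PWY-1"])
        frac = {l.species.rsplit("__", 1)[1]: l.fraction for l in links}
        assert frac["spA"] == pytest.approx(2 / 3)
        assert frac["spB"] == pytest.approx(1 / 3)

    def test_single_contributor_fraction_one(self):
        links = da.link_contributions(self._stratified(), ["k__B|s__spA"], ["PWY-2"])
        assert links[0].contributes and links[0].fraction == pytest.approx(1.0)

    def test_absent_species_contributes_false(self):
        links = da.link_contributions(self._stratified(), ["k__B|s__spZ"], ["PWY-1"])
        assert not links[0].contributes and links[0].fraction == 0.0

    def test_generator_weights_recovered(self, control_study):
        func = mr.simulate_stratified_functions(control_study)
        pwy, members = next((p, m) for p, m in control_study.contribution_map.items()
                            if len(m) >= 2)
        species = [sp for sp, _ in members]
        links = da.link_contributions(func, species, [pwy], min_prevalence=0.0)
        total = sum(l.fraction for l in links)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestFdr:
    def test_hand_bh_example(self):
        assert np.allclose(da.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert da.fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(da.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            da.fdr_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st_.lists(st_.floats(0, 1), min_size=1, max_size=40))
    def test_q_monotone_in_p_rank(self, pvals):
        q = da.fdr_adjust(pvals)
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()
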