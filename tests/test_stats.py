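import itertools

import numpy as np
import pandas as pd
import pytest

from petalvision.stats import (
    ContrastSpec,
    DissimilarityMatrix,
    bray_curtis,
    contrast_test,
    design_for_groups,
    fit_fixed_only,
    fit_random_intercept,
    named_contrast,
    oneway_anova,
    permanova,
    select_random_intercept,
)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]), transform="none")
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_is_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]), transform="none")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        d = bray_curtis(np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]]), transform="none")
        assert d.values[0, 1] == pytest.approx(2.0 / 12.0)

    def test_sqrt_transform_changes_shift_behaviour(self):
        """Guard against double transforms: a constant shift leaves raw
        profiles' Bray-Curtis shift-covariant, but not after sqrt."""
        x = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        base = bray_curtis(x, transform="sqrt").values[0, 1]
        shifted = bray_curtis(x + 5.0, transform="sqrt").values[0, 1]
        assert base != pytest.approx(shifted)

    def test_zero_row_named(self):
        with pytest.raises(ValueError, match="all-zero profile for 'b'"):
            bray_curtis(np.array([[1.0, 1.0], [0.0, 0.0]]), labels=["a", "b"])

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(6, 10))
        d = bray_curtis(x).values
        assert np.all(d >= 0) and np.all(d <= 1)
        np.testing.assert_array_equal(d, d.T)


def _naive_pseudo_f(d, codes):
    """Anderson's pseudo-F with explicit loops (independent oracle)."""
    codes = np.asarray(codes)
    n = len(codes)
    groups = sorted(set(codes))
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if codes[i] == g]
        ss_w += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    a = len(groups)
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    x = rng.uniform(0.1, 1.0, size=(6, 8))
    return bray_curtis(x), np.array(["a"] * 3 + ["b"] * 3)


class TestPermanova:
    def test_exact_matches_enumeration_oracle(self, toy):
        dm, groups = toy
        res = permanova(dm, groups, method="exact")
        obs = _naive_pseudo_f(dm.values, [0, 0, 0, 1, 1, 1])
        hits = total = 0
        for perm in itertools.permutations([0, 0, 0, 1, 1, 1]):
            total += 1
            hits += _naive_pseudo_f(dm.values, perm) >= obs - 1e-12
        assert res.pseudo_f == pytest.approx(obs, abs=1e-12)
        assert res.p_perm == pytest.approx(hits / total)

    def test_sampled_p_reproducible_and_bounded(self, toy):
        dm, groups = toy
        r1 = permanova(dm, groups, n_perm=199, seed=7)
        r2 = permanova(dm, groups, n_perm=199, seed=7)
        assert r1.p_perm == r2.p_perm
        assert 1 / 200 <= r1.p_perm <= 1.0

    def test_row_order_invariance(self, toy):
        dm, groups = toy
        order = np.array([3, 1, 5, 0, 4, 2])
        dm2 = DissimilarityMatrix(
            [dm.labels[i] for i in order], dm.values[np.ix_(order, order)]
        )
        f1 = permanova(dm, groups, n_perm=9, seed=0).pseudo_f
        f2 = permanova(dm2, groups[order], n_perm=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_identical_composition_groups_large_p(self):
        """Both groups built from the same profiles: mean p over seeds > 0.5."""
        rng = np.random.default_rng(2)
        trio = rng.uniform(0.1, 1.0, size=(3, 6))
        x = np.vstack([trio, trio])
        dm = bray_curtis(x)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        ps = [
            permanova(dm, groups, n_perm=49, seed=s).p_perm for s in range(200)
        ]
        assert np.mean(ps) > 0.5

    def test_matches_scikit_bio_statistic(self, toy):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        dm, groups = toy
        sk = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(dm.values, [str(i) for i in range(6)]),
            groups,
            permutations=49,
        )
        mine = permanova(dm, groups, n_perm=49, seed=0)
        assert mine.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_singleton_design_errors(self):
        dm = bray_curtis(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="degrees of freedom"):
            permanova(dm, np.array(["a", "b"]))


class TestOnewayAnova:
    def test_textbook_two_groups(self):
        tab = oneway_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        row = tab[tab["term"] == "group"].iloc[0]
        assert row["F"] == pytest.approx(13.5)
        assert row["df"] == 1
        assert int(tab[tab["term"] == "residual"]["df"].iloc[0]) == 4

    def test_degenerate_zero_variance_reported_undefined(self):
        tab = oneway_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert np.isnan(tab[tab["term"] == "group"]["F"].iloc[0])

    def test_ancova_covariate_absorbs_everything(self):
        rng = np.random.default_rng(1)
        cov = rng.uniform(0, 1, 30)
        y = 2.0 * cov
        groups = rng.choice(["a", "b", "c"], 30)
        tab = oneway_anova(y, groups, covariate=cov)
        assert tab[tab["term"] == "group"]["ss"].iloc[0] == pytest.approx(0.0, abs=1e-18)


class TestContrast:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="sum to zero"):
            ContrastSpec(("a", "b"), (1.0, 1.0))
        with pytest.raises(ValueError, match="unknown contrast"):
            named_contrast("bogus")

    def test_equal_means_zero_estimate(self):
        y = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["CFA", "NFA", "FU+"], 3)
        res = contrast_test(y, g, named_contrast("linear_increase"))
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_linear_contrast_matches_regression_on_scores_oracle(self):
        rng = np.random.default_rng(2)
        g = np.repeat(["CFA", "NFA", "FU+"], 9)
        y = rng.normal(0, 1, 27) + np.repeat([1.0, 2.0, 3.0], 9)
        spec = named_contrast("linear_increase")
        res = contrast_test(y, g, spec)
        # oracle: contrast of group means over MSE from the cell-means fit
        means = np.array([y[g == l].mean() for l in spec.levels])
        est = float(np.dot(spec.coefficients, means))
        sse = sum(((y[g == l] - y[g == l].mean()) ** 2).sum() for l in spec.levels)
        mse = sse / (27 - 3)
        f_oracle = est**2 / (mse * sum(c**2 / 9 for c in spec.coefficients))
        assert res.estimate > 0
        assert res.f == pytest.approx(f_oracle, abs=1e-9)
        assert res.df2 == 24

    def test_nfa_vs_rest_hand_arithmetic(self):
        # group means exactly (1, 4, 1): estimate = -1 + 8 - 1 = 6
        y = np.array([0.5, 1.5, 3.5, 4.5, 0.8, 1.2])
        g = np.array(["CFA", "CFA", "NFA", "NFA", "FU+", "FU+"])
        spec = named_contrast("nfa_vs_rest")
        res = contrast_test(y, g, spec)
        assert res.estimate == pytest.approx(6.0)
        means = np.array([1.0, 4.0, 1.0])
        sse = 0.5**2 * 4 + 0.2**2 * 2
        mse = sse / 3
        f_oracle = 36.0 / (mse * (1 + 4 + 1) / 2)
        assert res.f == pytest.approx(f_oracle, rel=1e-9)

    def test_orthogonal_contrasts_decompose_between_ss(self):
        rng = np.random.default_rng(3)
        g = np.repeat(["CFA", "NFA", "FU+"], 8)
        y = rng.normal(0, 1, 24) + np.repeat([0.0, 1.0, 3.0], 8)
        lin = named_contrast("linear_increase")
        quad = ContrastSpec(("CFA", "NFA", "FU+"), (1.0, -2.0, 1.0), "quadratic")
        ss = 0.0
        for spec in (lin, quad):
            means = np.array([y[g == l].mean() for l in spec.levels])
            est = float(np.dot(spec.coefficients, means))
            ss += est**2 / (np.sum(np.square(spec.coefficients)) / 8)
        tab = oneway_anova(y, g)
        assert ss == pytest.approx(tab[tab["term"] == "group"]["ss"].iloc[0], abs=1e-9)

    def test_level_mismatch_errors(self):
        with pytest.raises(ValueError, match="do not match"):
            contrast_test([1, 2], ["a", "b"], named_contrast("linear_increase"))


class TestRandomIntercept:
    @staticmethod
    def _design(n_per_plant=9):
        g = np.repeat(["CFA", "NFA", "FU+"], 2 * n_per_plant)
        plants = np.array(
            [f"{t}-p{(i % (2 * n_per_plant)) // n_per_plant}" for i, t in enumerate(g)]
        )
        return g, plants, design_for_groups(g)

    def test_matches_statsmodels_mixedlm_ml(self):
        sm = pytest.importorskip("statsmodels.api")
        g, plants, x = self._design()
        rng = np.random.default_rng(0)
        offsets = {p: rng.normal(0, 0.5) for p in set(plants)}
        y = rng.normal(0, 1, len(g)) + np.array([offsets[p] for p in plants])
        fit = fit_random_intercept(y, x, plants)
        mlm = sm.MixedLM(y, x, groups=plants).fit(reml=False)
        assert fit.loglik == pytest.approx(mlm.llf, abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(mlm.scale, rel=1e-3)

    def test_location_invariance(self):
        g, plants, x = self._design()
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, len(g)) + np.repeat([0, 1, 2], len(g) // 3)
        f1 = fit_random_intercept(y, x, plants)
        f2 = fit_random_intercept(y + 100.0, x, plants)
        assert f1.sigma2_plant == pytest.approx(f2.sigma2_plant, abs=1e-6)
        assert f1.sigma2_resid == pytest.approx(f2.sigma2_resid, rel=1e-8)
        sel1 = select_random_intercept(y, g, plants)
        sel2 = select_random_intercept(y + 100.0, g, plants)
        assert sel1.treatment_chi2 == pytest.approx(sel2.treatment_chi2, abs=1e-6)

    def test_balanced_anova_variance_components_large_n(self):
        """ML estimates approach method-of-moments on a large balanced design."""
        rng = np.random.default_rng(8)
        n_per, s_plant, s_resid = 2000, 0.7, 1.3
        plants = np.repeat([f"p{i}" for i in range(6)], n_per)
        b = np.repeat(rng.normal(0, s_plant, 6), n_per)
        y = b + rng.normal(0, s_resid, 6 * n_per)
        fit = fit_random_intercept(y, np.ones((len(y), 1)), plants)
        df = pd.DataFrame({"y": y, "p": plants})
        msw = df.groupby("p")["y"].var(ddof=1).mean()
        msb = df.groupby("p")["y"].mean().var(ddof=1) * n_per
        # ML divides the between-plant SS by k rather than k-1 (the
        # intercept is profiled out), hence the (k-1)/k factor vs ANOVA
        k = 6
        ml_plant = ((k - 1) / k * msb - msw) / n_per
        assert fit.sigma2_resid == pytest.approx(msw, rel=0.01)
        assert fit.sigma2_plant == pytest.approx(ml_plant, rel=0.02)

    def test_no_plant_variance_prefers_fixed_model(self):
        g, plants, x = self._design()
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, len(g))
        mixed = fit_random_intercept(y, x, plants)
        fixed = fit_fixed_only(y, x)
        assert fixed.aic <= mixed.aic + 2.0 + 1e-9  # at worst the +1 parameter

    def test_plants_must_nest_in_treatments(self):
        y = np.arange(8.0)
        g = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        plants = np.array(["p1", "p1", "p2", "p2", "p2", "p2", "p3", "p3"])
        with pytest.raises(ValueError, match="nested"):
            select_random_intercept(y, g, plants)

    def test_fewer_plants_than_treatments_errors(self):
        y = np.arange(6.0)
        g = np.array(["a", "a", "b", "b", "c", "c"])
        plants = np.array(["p1", "p1", "p1", "p1", "p2", "p2"])
        with pytest.raises(ValueError, match="nested|fewer plants"):
            select_random_intercept(y, g, plants)
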