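"""Lipidomics preprocessing, routed tests, BKY FDR, class totals, and VIP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from var2func.lipidomics import (
    bky_fdr,
    class_totals,
    differential,
    plsda_vip,
    preprocess,
    route_and_test,
)
from var2func.synth import gen_lipidome


class TestPreprocess:
    def test_no_missing_means_identity_imputation(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [3.0, 6.0, 12.0]})
        prep = preprocess(mat)
        pd.testing.assert_frame_equal(prep.imputed, mat)

    def test_hand_computed_three_by_two(self):
        # lipid a: values (10, NaN, 1000) -> impute 10/5 = 2
        # log10 -> (1, log10(2), 3); mean = (4 + log10 2)/3; sd via ddof=1
        mat = pd.DataFrame({"a": [10.0, np.nan, 1000.0], "b": [1.0, 10.0, 100.0]})
        prep = preprocess(mat)
        assert prep.imputed.loc[1, "a"] == pytest.approx(2.0)
        la = np.array([1.0, np.log10(2.0), 3.0])
        expected_a = (la - la.mean()) / np.sqrt(la.std(ddof=1))
        np.testing.assert_allclose(prep.scaled["a"], expected_a, atol=1e-12)
        lb = np.array([0.0, 1.0, 2.0])
        np.testing.assert_allclose(prep.scaled["b"], (lb - 1.0) / 1.0, atol=1e-12)

    def test_constant_lipid_scaled_to_zero_and_flagged(self):
        mat = pd.DataFrame({"c": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        prep = preprocess(mat)
        assert prep.constant == ["c"]
        assert (prep.scaled["c"] == 0).all()

    def test_all_missing_lipid_dropped_with_warning(self):
        mat = pd.DataFrame({"gone": [np.nan] * 3, "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="dropped"):
            prep = preprocess(mat)
        assert prep.dropped == ["gone"]
        assert list(prep.scaled.columns) == ["b"]


class TestRouting:
    def test_welch_p_matches_textbook_formula(self):
        from scipy import stats

        x = np.array([5.1, 4.8, 6.0, 5.5, 4.9, 5.3, 5.7, 5.0, 5.2, 5.4])
        y = np.array([4.2, 4.6, 4.1, 4.8, 4.4, 4.3, 4.7, 4.5, 4.0, 4.9])
        test_used, p = route_and_test(x, y)
        assert test_used == "welch_t"
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-10)

    def test_heavily_skewed_groups_routed_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 2.0, size=50)
        y = rng.lognormal(0.5, 2.0, size=50)
        test_used, _ = route_and_test(x, y)
        assert test_used == "mann_whitney"

    def test_small_groups_default_to_welch(self):
        # n = 4 per group: the omnibus normality test is undefined
        test_used, _ = route_and_test([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert test_used == "welch_t"

    def test_degenerate_equal_constants_give_p_one(self):
        test_used, p = route_and_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0


class TestBKY:
    def test_hand_worked_five_pvalue_example(self):
        rejected = bky_fdr([0.001, 0.01, 0.02, 0.8, 0.9], q=0.05)
        assert rejected.sum() == 3
        assert list(rejected) == [True, True, True, False, False]

    def test_all_ones_reject_nothing(self):
        assert bky_fdr(np.ones(10), q=0.05).sum() == 0

    def test_empty_input(self):
        assert bky_fdr([], q=0.05).size == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=60),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_statsmodels_two_stage(self, pvals, q):
        mine = bky_fdr(pvals, q=q)
        theirs = multipletests(pvals, alpha=q, method="fdr_tsbky")[0]
        assert np.array_equal(mine, theirs)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rejects_superset_of_stage_one_bh(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(40) ** 2
        q = 0.05
        stage2 = bky_fdr(p, q=q)
        stage1 = multipletests(p, alpha=q / (1 + q), method="fdr_bh")[0]
        r1 = stage1.sum()
        if 0 < r1 < p.size:
            assert np.all(stage2 | ~stage1)

    def test_null_false_discovery_proportion_controlled(self):
        rng = np.random.default_rng(3)
        q = 0.05
        fdp = [bky_fdr(rng.random(200), q=q).any() for _ in range(300)]
        tol = 2.58 * np.sqrt(q * (1 - q) / 300)
        assert np.mean(fdp) <= q + tol


class TestDifferential:
    def test_planted_class_depletion_flagged(self, small_lipid_matrix):
        matrix, groups, class_map = small_lipid_matrix
        diff = differential(matrix, groups, class_map, q=0.05)
        planted = diff[diff["class"] == "B"]
        assert (planted["log2fc"] < -0.58).all()
        assert planted["volcano_sig"].all()
        untouched = diff[diff["class"] == "A"]
        assert (untouched["log2fc"].abs() < 0.3).all()

    def test_log2fc_on_raw_concentrations(self, small_lipid_matrix):
        matrix, groups, class_map = small_lipid_matrix
        diff = differential(matrix, groups, class_map).set_index("lipid")
        treated = matrix.loc[groups == "treated", "B_0"].mean()
        control = matrix.loc[groups == "control", "B_0"].mean()
        assert diff.loc["B_0", "log2fc"] == pytest.approx(np.log2(treated / control))

    def test_missing_class_mapping_rejected(self, small_lipid_matrix):
        matrix, groups, class_map = small_lipid_matrix
        with pytest.raises(ValueError, match="class map"):
            differential(matrix, groups, class_map.drop("B_0"))

    def test_planted_effect_recovery_rate(self):
        # |log2FC| = 1 at cv 0.1 with n = 4/group is called in >= 90% of seeds
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            matrix, class_map, groups = gen_lipidome(
                class_sizes={"X": 3, "Y": 3}, n_per_group=4,
                effect_lipids=("X_000",), target_log2fc=-1.0, cv=0.1, seed=seed)
            diff = differential(matrix, groups, class_map).set_index("lipid")
            row = diff.loc["X_000"]
            hits += bool(row["volcano_sig"] and row["log2fc"] < 0)
        assert hits / n_seeds >= 0.9


class TestClassTotals:
    def test_hand_computable_two_class_sums(self):
        mat = pd.DataFrame({"A_0": [1.0, 2, 3, 4], "A_1": [1.0, 1, 1, 1],
                            "B_0": [10.0, 10, 20, 20]},
                           index=["c1", "c2", "t1", "t2"])
        groups = pd.Series(["control", "control", "treated", "treated"],
                           index=mat.index)
        class_map = pd.Series(["A", "A", "B"], index=mat.columns)
        totals = class_totals(mat, groups, class_map).set_index("class")
        assert totals.loc["A", "mean_control"] == pytest.approx((2 + 3) / 2)
        assert totals.loc["A", "mean_treated"] == pytest.approx((4 + 5) / 2)
        assert totals.loc["B", "mean_treated"] == pytest.approx(20.0)
        assert totals.loc["B", "n_lipids"] == 1

    def test_planted_class_wide_depletion_significant(self):
        matrix, class_map, groups = gen_lipidome(
            class_sizes={"TG": 40, "SM": 15}, n_per_group=4,
            effect_lipids=("TG",), target_log2fc=-1.0, cv=0.1, seed=2)
        totals = class_totals(matrix, groups, class_map).set_index("class")
        assert totals.loc["TG", "p"] < 0.01
        assert totals.loc["TG", "mean_treated"] < totals.loc["TG", "mean_control"]
        assert totals.loc["SM", "p"] > 0.01


class TestVIP:
    def test_mean_squared_vip_is_one(self, small_lipid_matrix):
        matrix, groups, _ = small_lipid_matrix
        vip = plsda_vip(preprocess(matrix).scaled, groups)
        assert float((vip["vip"] ** 2).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_perfect_discriminator_ranks_first(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(rng.normal(size=(12, 51)),
                             columns=[f"l{k}" for k in range(51)])
            groups = pd.Series(["control"] * 6 + ["treated"] * 6, index=x.index)
            x["l0"] = np.where(groups == "treated", 5.0, -5.0) + rng.normal(0, 0.01, 12)
            vip = plsda_vip(x, groups)
            assert vip.loc[vip["vip"].idxmax(), "lipid"] == "l0"

    def test_matches_sklearn_nipals_pls(self, small_lipid_matrix):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        matrix, groups, _ = small_lipid_matrix
        prep = preprocess(matrix).scaled
        vip = plsda_vip(prep, groups, n_components=2)
        y = (groups == "treated").astype(float).to_numpy()
        pls = sklearn.PLSRegression(n_components=2, scale=False)
        pls.fit(prep.to_numpy(), y - y.mean())
        w = pls.x_weights_ / np.linalg.norm(pls.x_weights_, axis=0)
        ssy = (pls.y_loadings_.ravel() ** 2) * (pls.x_scores_ ** 2).sum(axis=0)
        expected = np.sqrt(prep.shape[1] * (ssy[None, :] * w**2).sum(axis=1) / ssy.sum())
        np.testing.assert_allclose(vip["vip"].to_numpy(), expected, atol=1e-8)

    def test_excess_components_reduced_with_warning(self, small_lipid_matrix):
        matrix, groups, _ = small_lipid_matrix
        with pytest.warns(UserWarning, match="reduced"):
            vip = plsda_vip(preprocess(matrix).scaled, groups, n_components=50)
        assert (vip["n_components"] <= 7).all()
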