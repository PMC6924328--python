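"""Regression, rank and group-comparison statistics vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemosignal.stats import (
    kruskal_wallis,
    multiple_regression_anova,
    normalized_range,
    one_way_anova,
    population_contrast,
    simple_linreg,
    spearman,
)

from _oracles import (
    anova_bruteforce,
    kruskal_bruteforce,
    linreg_bruteforce,
    regression_anova_bruteforce,
    spearman_bruteforce,
    tied_ranks,
)


class TestMultipleRegression:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0, 10, 13)
        X = pd.DataFrame({"a": x1, "b": rng.uniform(0, 1, 13)})
        y = 2.0 * x1 + 3.0
        # y depends only on 'a': model R^2 = 1, SSE = 0 up to rounding
        table = multiple_regression_anova(y, X)
        assert table.attrs["r_squared"] == pytest.approx(1.0)
        assert table.loc["error", "SS"] == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_partial_ss_match_reduced_model_refits(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.uniform(0, 5, (13, 3)), columns=["p", "q", "r"])
        y = rng.uniform(0, 100, 13)
        table = multiple_regression_anova(y, X)
        oracle = regression_anova_bruteforce(y, X.values)
        assert table.loc["model", "F"] == pytest.approx(oracle["model_F"], rel=1e-8)
        for j, name in enumerate(X.columns):
            assert table.loc[name, "SS"] == pytest.approx(oracle[f"x{j}_SS"], rel=1e-8)
            assert table.loc[name, "F"] == pytest.approx(oracle[f"x{j}_F"], rel=1e-8)
        assert table.loc["error", "df"] == 13 - 4

    def test_last_effect_partial_equals_sequential(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.uniform(0, 5, (15, 3)), columns=["p", "q", "r"])
        y = rng.uniform(0, 10, 15)
        partial = multiple_regression_anova(y, X)
        sequential = multiple_regression_anova(y, X, sequential=True)
        assert partial.loc["r", "SS"] == pytest.approx(
            sequential.loc["r", "SS"], rel=1e-10
        )

    def test_collinear_design_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "twice_a": 2 * x})
        with pytest.raises(ValueError, match="collinear.*twice_a"):
            multiple_regression_anova(np.random.default_rng(0).uniform(size=10), X)


class TestSimpleLinreg:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3, 4])
        res = simple_linreg(x, 2 * x + 1)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 20)
        y = 3 * x + rng.normal(0, 2, 20)
        res = simple_linreg(x, y)
        slope, intercept = linreg_bruteforce(x, y)
        assert res["slope"] == pytest.approx(slope, rel=1e-10)
        assert res["intercept"] == pytest.approx(intercept, rel=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            simple_linreg([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_pairs_give_one(self):
        rho, _ = spearman([1, 2, 3, 5, 9], [10, 20, 21, 40, 41])
        assert rho == pytest.approx(1.0)

    def test_tied_sample_matches_hand_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        y = [4.0, 4.0, 6.0, 7.0, 7.0, 9.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_bruteforce(x, y), rel=1e-12)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 15).astype(float)  # plenty of ties
        y = rng.integers(0, 5, 15).astype(float)
        rho, _ = spearman(x, y)
        rx, ry = tied_ranks(x), tied_ranks(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-12)
        assert -1.0 <= rho <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 9), st.integers(0, 9)),
            min_size=4, max_size=25,
        )
    )
    def test_bounded_and_matches_rank_oracle_on_arbitrary_ties(self, data):
        x = np.array([a for a, _ in data], float)
        y = np.array([b for _, b in data], float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, p = spearman(x, y)
        # p hits 0 exactly in the degenerate |rho| = 1 limit of the t form
        assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0
        assert rho == pytest.approx(spearman_bruteforce(x, y), abs=1e-10)


class TestKruskalWallis:
    def test_identical_group_multisets_give_zero(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [3, 1, 2]})
        assert res["H"] == pytest.approx(0.0, abs=1e-12)

    def test_small_integer_fixture_matches_rank_oracle(self):
        groups = {"a": [1, 3, 5], "b": [2, 2, 6], "c": [4, 4, 4]}
        res = kruskal_wallis(groups)
        assert res["H"] == pytest.approx(kruskal_bruteforce(groups), rel=1e-10)
        assert res["df"] == 2

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.uniform(0, 10, 5).tolist() for g in "abcd"}
        transformed = {g: list(np.exp(np.asarray(v))) for g, v in groups.items()}
        assert kruskal_wallis(groups)["H"] == pytest.approx(
            kruskal_wallis(transformed)["H"], rel=1e-10
        )

    def test_all_identical_observations_convention(self):
        res = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert res == {"H": 0.0, "df": 1, "p": 1.0}


class TestOneWayAnova:
    def test_matches_direct_ss_oracle(self):
        rng = np.random.default_rng(4)
        groups = {g: (rng.normal(5, 1, 6)).tolist() for g in "abc"}
        res = one_way_anova(groups)
        assert res["F"] == pytest.approx(anova_bruteforce(groups), rel=1e-10)
        assert (res["df1"], res["df2"]) == (2, 15)

    def test_equal_means_give_small_f(self):
        rng = np.random.default_rng(6)
        groups = {g: (10 + rng.normal(0, 1, 50)).tolist() for g in "ab"}
        assert one_way_anova(groups)["F"] < 4.0

    def test_degenerate_within_variance_rejected(self):
        with pytest.raises(ValueError, match="within-group"):
            one_way_anova({"a": [0.0, 0.0], "b": [1.0, 1.0]})


class TestPopulationContrast:
    @staticmethod
    def _table(shift=0.0, seed=0, n=20):
        rng = np.random.default_rng(seed)
        rows = []
        for sp, pops in [("target", 2), ("other", 1)]:
            for pop in range(pops):
                mu = 10 + (shift if (sp == "target" and pop == 1) else 0)
                for v in rng.normal(mu, 1.0, n):
                    rows.append((sp, f"P{pop}", float(v)))
        return pd.DataFrame(rows, columns=["species", "population",
                                           "total_gs_umol_g"])

    def test_identical_populations_give_near_zero_t(self):
        table = self._table(shift=0.0, seed=1, n=200)
        res = population_contrast(table, "target")
        assert abs(res["t_ratio"]) < 2.5

    def test_known_shift_matches_pooled_formula(self):
        table = self._table(shift=3.0, seed=2, n=30)
        res = population_contrast(table, "target")
        # hand computation: pooled MSE over all three cells
        cells = [g["total_gs_umol_g"].to_numpy()
                 for _, g in table.groupby(["species", "population"])]
        mse = sum(((c - c.mean()) ** 2).sum() for c in cells) / (90 - 3)
        t_pop = table[table.species == "target"].groupby("population")[
            "total_gs_umol_g"].mean()
        t_hand = (t_pop["P0"] - t_pop["P1"]) / np.sqrt(mse * (2 / 30))
        assert res["t_ratio"] == pytest.approx(t_hand, rel=1e-10)
        assert res["df"] == 87

    def test_single_population_species_rejected(self):
        table = self._table()
        with pytest.raises(ValueError, match="exactly 2 populations"):
            population_contrast(table, "other")


class TestNormalizedRange:
    def test_known_values(self):
        assert normalized_range([1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert normalized_range([4.0, 4.0, 4.0]) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalized_range([-1.0, 1.0])
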