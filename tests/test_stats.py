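"""Rank tests, BH adjustment, correlation tables/clusters, regression."""

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from petdna import (
    ValidationError,
    bh_adjust,
    correlation_clusters,
    mann_whitney,
    spearman_matrix,
    stepwise_ols,
    univariate_ols,
)


def mwu_enumeration_p(x, y):
    """Full-enumeration two-sided Mann–Whitney oracle (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        r = np.sort(pooled)  # ranks of sorted pooled are 1..N
        u = sum(i + 1 for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = mann_whitney(x, x.copy())  # no shift: p = 1 within tolerance
        assert p == pytest.approx(1.0)

    def test_all_constant_values_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_fully_separated_small_samples_exact(self):
        # 2 of the 20 orderings are as extreme: exact two-sided p = 0.1
        _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_u_statistic_identity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=5)
        u_xy, _ = mann_whitney(x, y)
        u_yx, _ = mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)


def brute_force_bh(p):
    """Literal step-up definition: q_i = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(rng.integers(1, 20))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1)
        # adjusted values non-decreasing in raw-p rank
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestSpearman:
    def test_monotone_gives_one(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 4, 9, 16, 30]})
        t = spearman_matrix(df, ["x"], ["y"])
        assert t.loc[0, "rho"] == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        # d^2 sums to 4: rho = 1 - 6*4 / (4*15) = 0.6
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
        t = spearman_matrix(df, ["x"], ["y"])
        assert t.loc[0, "rho"] == pytest.approx(0.6)

    def test_midrank_ties_match_hand_formula(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 5.0, 7.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0, 7.0])
        rank = lambda v: pd.Series(v).rank().to_numpy()
        rx, ry = rank(x), rank(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on midranks
        t = spearman_matrix(pd.DataFrame({"x": x, "y": y}), ["x"], ["y"])
        assert t.loc[0, "rho"] == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        t1 = spearman_matrix(df, ["x"], ["y"]).loc[0, "rho"]
        t2 = spearman_matrix(df.rename(columns={"x": "y", "y": "x"}), ["x"], ["y"]).loc[0, "rho"]
        assert t1 == pytest.approx(t2)
        df["x"] = np.exp(df["x"])  # strictly monotone transform
        assert spearman_matrix(df, ["x"], ["y"]).loc[0, "rho"] == pytest.approx(t1)

    def test_null_targets_dropped_and_counted(self):
        df = pd.DataFrame(
            {"x": np.arange(10.0), "t": [np.nan, np.nan] + list(np.arange(8.0))}
        )
        t = spearman_matrix(df, ["x"], ["t"])
        assert t.loc[0, "n"] == 8

    def test_too_few_pairs_reported_na(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "t": [1.0, 2, np.nan, np.nan]})
        t = spearman_matrix(df, ["x"], ["t"])
        assert np.isnan(t.loc[0, "rho"]) and t.loc[0, "n"] == 2

    def test_bh_family_per_target(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        t = spearman_matrix(df, ["a", "b", "c"], ["d", "e"])
        for target in ("d", "e"):
            sub = t[t["target"] == target]
            np.testing.assert_allclose(
                sub["p_adj"].to_numpy(), bh_adjust(sub["p"].to_numpy())
            )


class TestClusters:
    @staticmethod
    def _table(edges, features):
        rows = []
        for a, b in combinations(features, 2):
            rho = edges.get((a, b), edges.get((b, a), 0.1))
            rows.append({"feature": a, "target": b, "rho": rho, "p": 0.001 if rho > 0.5 else 0.9,
                         "p_adj": 0.001 if rho > 0.5 else 0.9, "n": 30})
        return pd.DataFrame(rows)

    def test_two_blocks_recovered(self):
        feats = ["A", "B", "C", "D", "E"]
        edges = {("A", "B"): 0.9, ("B", "C"): 0.8, ("D", "E"): 0.85}
        clusters = correlation_clusters(self._table(edges, feats), rho_min=0.7)
        assert [c["members"] for c in clusters] == [["A", "B", "C"], ["D", "E"]]

    def test_threshold_limit_no_perfect_pairs(self):
        feats = ["A", "B", "C"]
        edges = {("A", "B"): 0.95}
        assert correlation_clusters(self._table(edges, feats), rho_min=1.0) == []

    def test_empty_graph_no_clusters(self):
        assert correlation_clusters(self._table({}, ["A", "B"]), rho_min=0.7) == []


class TestUnivariate:
    def test_noiseless_line(self):
        x = np.arange(10.0)
        res = univariate_ols(2 * x + 1, x)
        assert res.terms["x"] == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_affine_invariance_of_fit_quality(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        r1 = univariate_ols(y, x)
        r2 = univariate_ols(y, (x - x.mean()) / x.std())
        assert r1.adj_r2 == pytest.approx(r2.adj_r2, rel=1e-9)
        assert r1.slope_pvalues["x"] == pytest.approx(r2.slope_pvalues["x"], rel=1e-9)

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        res = univariate_ols(y, x)
        n = 25
        r2 = 1 - (1 - res.adj_r2) * (n - 2) / (n - 1)  # invert the reported adjustment
        assert res.adj_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - 2), rel=1e-9)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValidationError):
            univariate_ols(np.arange(5.0), np.ones(5))


class TestStepwise:
    def test_true_predictors_recovered_with_coefficients(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(200, 12)), columns=[f"x{i}" for i in range(1, 13)])
        y = 3 * X["x1"] - 2 * X["x4"] + rng.normal(0, 0.1, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stepwise_ols(y, X)
        assert {"x1", "x4"} <= set(res.terms)
        assert res.terms["x1"] == pytest.approx(3.0, abs=0.1)
        assert res.terms["x4"] == pytest.approx(-2.0, abs=0.1)
        assert res.adj_r2 > 0.99

    def test_pure_noise_low_r2(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 12)), columns=[f"x{i}" for i in range(12)])
        y = rng.normal(size=200)
        res = stepwise_ols(y, X)
        assert res.adj_r2 < 0.1

    def test_fixed_point_empty_trace(self):
        # when the full candidate set is exactly the generating model and noise
        # is tiny, no add/drop improves AIC: the trace is empty
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x1", "x2"])
        y = 2 * X["x1"] + 5 * X["x2"] + rng.normal(0, 0.01, 100)
        res = stepwise_ols(y, X)
        assert res.trace == () and set(res.terms) == {"x1", "x2"}

    def test_refit_reproduces_coefficients(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        y = X["a"] - X["c"] + rng.normal(0, 0.5, 80)
        res = stepwise_ols(y, X)
        import statsmodels.api as sm

        refit = sm.OLS(y, sm.add_constant(X[list(res.terms)])).fit()
        for term, coef in res.terms.items():
            assert coef == pytest.approx(refit.params[term], rel=1e-9)

    def test_collinear_candidate_dropped_with_warning(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        X["dup"] = X["a"]  # exactly collinear
        y = X["a"] + rng.normal(0, 0.1, 60)
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_ols(y, X)
        assert "dup" in res.dropped_collinear

    def test_null_rows_dropped(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = X["a"] + rng.normal(0, 0.1, 50)
        y[:5] = np.nan
        res = stepwise_ols(y, X)
        assert res.n == 45
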