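"""Rank tests, FDR control, correlation tables/clusters and regression.

The statistical battery applied to a cohort table: two-sided
Wilcoxon–Mann–Whitney tests, Benjamini–Hochberg step-up FDR adjustment,
Spearman rank-correlation tables with BH control, correlation-graph
clustering, univariate ordinary least squares, and bidirectional stepwise
model selection by AIC.  Null (missing) targets — patients with no
detectable tumour mutation — are excluded pairwise and the exclusion count
is reported, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "mann_whitney",
    "bh_adjust",
    "spearman_matrix",
    "correlation_clusters",
    "univariate_ols",
    "stepwise_ols",
    "RegressionResult",
]

#: switch from exact enumeration to the tie/continuity-corrected normal
#: approximation above this product of sample sizes
_EXACT_CUTOVER = 400


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Exact enumeration when ``n1 * n2 <= 400`` and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    Returns ``(U, p)`` where U is the statistic of the first sample.  Two
    samples whose pooled values are all identical carry no ordering
    information: p = 1 by convention, with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("mann_whitney requires n >= 1 per sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1 by convention", stacklevel=2)
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= _EXACT_CUTOVER and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, take ``q_i = min_{j >= i} p_(j) * m / j`` capped at 1.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1D p-value vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho (midrank ties) and t-approximation p on complete pairs."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        return np.nan, np.nan, n
    rho, p = sps.spearmanr(x[ok], y[ok])
    return float(rho), float(p), n


def spearman_matrix(
    cohort: pd.DataFrame,
    features: list[str],
    targets: list[str] | None = None,
    drop_null_targets: bool = True,
) -> pd.DataFrame:
    """Spearman correlation table with BH-adjusted p-values.

    With ``targets`` given, correlates each feature with each target and BH
    adjusts within each target's family of ``len(features)`` tests (the
    feature–DNA table layout).  Without targets, correlates all feature
    pairs and BH adjusts over the single feature–feature family.  Null
    (NaN) target values are excluded pairwise when ``drop_null_targets``;
    ``n`` records the pairs actually used.  Pairs with fewer than 4
    complete observations are reported as NA rather than dropped.
    """
    for col in features + (targets or []):
        if col not in cohort.columns:
            raise ValidationError(f"column {col!r} missing from cohort table")
    rows = []
    if targets is not None:
        for target in targets:
            t = cohort[target].to_numpy(float)
            if not drop_null_targets and np.isnan(t).any():
                raise ValidationError(f"target {target!r} has null values and drop_null_targets=False")
            for feat in features:
                rho, p, n = _spearman_pair(cohort[feat].to_numpy(float), t)
                rows.append({"feature": feat, "target": target, "rho": rho, "p": p, "n": n})
        table = pd.DataFrame(rows)
        table["p_adj"] = np.nan
        for target in targets:
            sel = table["target"] == target
            table.loc[sel, "p_adj"] = _bh_with_na(table.loc[sel, "p"].to_numpy())
    else:
        for a, b in combinations(features, 2):
            rho, p, n = _spearman_pair(
                cohort[a].to_numpy(float), cohort[b].to_numpy(float)
            )
            rows.append({"feature": a, "target": b, "rho": rho, "p": p, "n": n})
        table = pd.DataFrame(rows)
        table["p_adj"] = _bh_with_na(table["p"].to_numpy())
    return table


def _bh_with_na(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = bh_adjust(p[ok])
    return out


def correlation_clusters(
    corr: pd.DataFrame, rho_min: float = 0.7, alpha: float = 0.05
) -> list[dict]:
    """Connected clusters of strongly correlated features.

    Builds a graph on features with an edge wherever the BH-adjusted p is
    below ``alpha`` and rho >= ``rho_min``; clusters are the connected
    components with at least two members, each reported with its internal
    edges.  ``corr`` is a feature–feature table from
    :func:`spearman_matrix` (columns feature/target/rho/p_adj).
    """
    graph = nx.Graph()
    for _, row in corr.iterrows():
        if np.isfinite(row["rho"]) and np.isfinite(row["p_adj"]):
            if row["p_adj"] < alpha and row["rho"] >= rho_min:
                graph.add_edge(row["feature"], row["target"], rho=float(row["rho"]))
    clusters = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)[0])):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        clusters.append(
            {
                "members": sorted(comp),
                "edges": sorted(
                    (min(u, v), max(u, v), d["rho"]) for u, v, d in sub.edges(data=True)
                ),
            }
        )
    return clusters


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit: selected terms, fit quality and the selection trace."""

    terms: dict                       # term -> coefficient
    intercept: float
    adj_r2: float
    f_pvalue: float                   # overall model F-test
    n: int
    slope_pvalues: dict = field(default_factory=dict)
    trace: tuple = ()                 # ((action, term, aic), ...) for stepwise
    dropped_collinear: tuple = ()

    @property
    def formula(self) -> str:
        parts = [f"{self.intercept:.6g}"]
        parts += [f"{coef:+.6g}*{term}" for term, coef in self.terms.items()]
        return " ".join(parts)


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def univariate_ols(y, x, name: str = "x") -> RegressionResult:
    """Simple linear regression y = a + b*x on complete pairs."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 4:
        raise ValidationError(f"univariate_ols needs >= 4 complete pairs, got {y.size}")
    if np.ptp(x) == 0:
        raise ValidationError("predictor has zero variance")
    fit = _fit_ols(y, pd.DataFrame({name: x}))
    return RegressionResult(
        terms={name: float(fit.params[name])},
        intercept=float(fit.params["const"]),
        adj_r2=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue),
        n=int(y.size),
        slope_pvalues={name: float(fit.pvalues[name])},
    )


def stepwise_ols(
    y,
    X: pd.DataFrame,
    direction: str = "both",
    start: str = "full",
    max_steps: int = 200,
) -> RegressionResult:
    """Bidirectional stepwise OLS selection by AIC.

    Starts from the full candidate model (default) or the intercept-only
    model and at each step applies the single add/drop that lowers AIC the
    most, until no move improves it.  AIC ties are broken by the fixed
    candidate-column order (drop preferred over add).  Candidates that make
    the design numerically collinear (condition number > 1e10) are removed
    with a warning before selection; rows with any missing value (null
    targets) are dropped first.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValidationError(f"direction must be both/forward/backward, got {direction!r}")
    if start not in ("full", "empty"):
        raise ValidationError(f"start must be 'full' or 'empty', got {start!r}")
    y = np.asarray(y, float)
    X = X.copy()
    ok = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
    y, X = y[ok], X.loc[ok]
    n = int(y.size)
    candidates = list(X.columns)

    dropped = []
    while len(candidates) > 1:
        mat = X[candidates].to_numpy(float)
        std = mat.std(axis=0)
        zero_var = [c for c, s in zip(candidates, std) if s == 0]
        if zero_var:
            dropped += zero_var
            candidates = [c for c in candidates if c not in zero_var]
            continue
        cond = np.linalg.cond((mat - mat.mean(0)) / std)
        if cond <= 1e10:
            break
        dropped.append(candidates.pop())  # peel from the end until well-conditioned
    if dropped:
        warnings.warn(f"dropped collinear/degenerate candidates before selection: {dropped}", stacklevel=2)
    if n <= len(candidates) + 1:
        raise ValidationError(
            f"n = {n} too small for {len(candidates)} candidates in a full-model start"
        )

    current = list(candidates) if start == "full" else []
    can_add = direction in ("both", "forward")
    can_drop = direction in ("both", "backward")

    def aic_of(terms: list[str]) -> float:
        return float(_fit_ols(y, X[terms] if terms else X[[]]).aic)

    current_aic = aic_of(current)
    trace = []
    for _ in range(max_steps):
        moves = []  # (aic, priority, action, term); priority keeps tie-breaks fixed
        if can_drop:
            for i, term in enumerate(current):
                trial = [t for t in current if t != term]
                moves.append((aic_of(trial), (0, candidates.index(term)), "drop", term))
        if can_add:
            for term in candidates:
                if term not in current:
                    moves.append((aic_of(current + [term]), (1, candidates.index(term)), "add", term))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_aic, _, action, term = moves[0]
        if best_aic >= current_aic - 1e-10:
            break
        if action == "drop":
            current = [t for t in current if t != term]
        else:
            current = [t for t in candidates if t in current or t == term]
        current_aic = best_aic
        trace.append((action, term, best_aic))

    fit = _fit_ols(y, X[current] if current else X[[]])
    terms = {t: float(fit.params[t]) for t in current}
    return RegressionResult(
        terms=terms,
        intercept=float(fit.params["const"]),
        adj_r2=float(fit.rsquared_adj) if current else 0.0,
        f_pvalue=float(fit.f_pvalue) if current else 1.0,
        n=n,
        slope_pvalues={t: float(fit.pvalues[t]) for t in current},
        trace=tuple(trace),
        dropped_collinear=tuple(dropped),
    )
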