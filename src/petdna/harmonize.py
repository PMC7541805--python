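"""Scanner batch-effect detection and ComBat harmonization.

Features measured on different PET/CT machines can carry a per-machine
(location/scale) batch effect.  The workflow here is *gate then harmonize*:
each feature's distribution is compared between the two machines with a
two-sided Wilcoxon–Mann–Whitney test, p-values are Benjamini–Hochberg
adjusted across the feature set, and only the flagged features (adjusted
p < 0.05) are replaced by their ComBat-adjusted values.  Harmonizing every
feature regardless of the gate is available via ``mode='all'``.

ComBat is the parametric empirical-Bayes location/scale model: features are
standardized against a batch-size-weighted grand mean and pooled variance,
per-batch location (gamma*) and scale (delta*) parameters are shrunk toward
their across-feature prior moments, and the standardized data are adjusted
and rescaled.  No biological covariates are modelled (the harmonization is
of marginal feature distributions, run within one disease cohort at a time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .stats import bh_adjust, mann_whitney

__all__ = ["CombatModel", "detect_batch_effect", "combat_fit_apply", "harmonize_cohort"]


@dataclass(frozen=True)
class CombatModel:
    """Fitted ComBat parameters: one (gamma*, delta*) pair per feature x batch."""

    features: tuple[str, ...]
    batches: tuple = ()
    grand_mean: dict = field(default_factory=dict)      # feature -> stand. model grand mean
    pooled_var: dict = field(default_factory=dict)      # feature -> pooled variance
    gamma_star: dict = field(default_factory=dict)      # (feature, batch) -> location
    delta_star: dict = field(default_factory=dict)      # (feature, batch) -> scale (variance)


def detect_batch_effect(
    values: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann–Whitney machine-effect test per feature, BH-adjusted.

    ``values`` is a patients x features table; ``batch`` the machine label
    per patient (exactly two levels, each with >= 3 observations).  Returns
    a per-feature frame with columns ``p``, ``p_adj`` and ``flag``
    (``p_adj < alpha``).
    """
    batch = np.asarray(batch)
    levels, counts = np.unique(batch, return_counts=True)
    if len(levels) != 2:
        raise ValidationError(f"batch-effect test needs exactly 2 batches, got {list(levels)}")
    small = [str(l) for l, c in zip(levels, counts) if c < 3]
    if small:
        raise ValidationError(f"batch(es) {small} have fewer than 3 observations")
    pvals = []
    for col in values.columns:
        x = values[col].to_numpy(float)
        _, p = mann_whitney(x[batch == levels[0]], x[batch == levels[1]])
        pvals.append(p)
    p_adj = bh_adjust(pvals)
    return pd.DataFrame(
        {"p": pvals, "p_adj": p_adj, "flag": np.asarray(p_adj) < alpha}, index=values.columns
    )


def _combat_adjust(data: np.ndarray, batch_codes: np.ndarray, n_batches: int):
    """Parametric EB ComBat on a samples x features array.

    Returns (adjusted array, grand mean, pooled var, gamma*, delta*) with
    gamma*/delta* of shape (n_batches, n_features).
    """
    n, g = data.shape
    counts = np.bincount(batch_codes, minlength=n_batches).astype(float)
    batch_means = np.vstack([data[batch_codes == i].mean(axis=0) for i in range(n_batches)])
    grand_mean = (counts / n) @ batch_means
    resid = data - batch_means[batch_codes]
    pooled_var = (resid**2).sum(axis=0) / n

    degenerate = pooled_var <= 0
    if degenerate.any():
        warnings.warn(
            "zero pooled variance; falling back to location-only adjustment for the affected feature(s)",
            stacklevel=3,
        )
    scale = np.sqrt(np.where(degenerate, 1.0, pooled_var))
    z = (data - grand_mean) / scale

    gamma_hat = np.vstack([z[batch_codes == i].mean(axis=0) for i in range(n_batches)])
    delta_hat = np.vstack(
        [z[batch_codes == i].var(axis=0, ddof=1) for i in range(n_batches)]
    )
    delta_hat = np.where(delta_hat <= 0, 1.0 if g < 2 else delta_hat.mean(), delta_hat)

    if g >= 2:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(n_batches):
            gamma_star[i], delta_star[i] = _eb_solve(
                z[batch_codes == i], gamma_hat[i], delta_hat[i]
            )
    else:
        # a single feature gives no across-feature prior: no shrinkage
        gamma_star, delta_star = gamma_hat, delta_hat

    if degenerate.any():
        # location-only, unshrunk: removes the batch means exactly
        gamma_star[:, degenerate] = gamma_hat[:, degenerate]
        delta_star[:, degenerate] = 1.0

    adjusted = (z - gamma_star[batch_codes]) / np.sqrt(delta_star[batch_codes])
    adjusted = adjusted * scale + grand_mean
    return adjusted, grand_mean, pooled_var, gamma_star, delta_star


def _eb_solve(z_batch, gamma_hat, delta_hat, conv=1e-9, max_iter=5000):
    """Iterative EB point estimates for one batch (parametric priors)."""
    n = len(z_batch)
    gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    if s2 <= 0 or tau2 <= 0:
        return gamma_hat.copy(), delta_hat.copy()
    lam = (2 * s2 + m**2) / s2            # inverse-gamma shape prior (moments matched)
    theta = (m * s2 + m**3) / s2          # inverse-gamma scale prior
    g_new, d_new = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sse = ((z_batch - g_new) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * sse) / (n / 2 + lam - 1)
        change = max(
            np.abs((g_new - g_old) / np.where(g_old == 0, 1, g_old)).max(),
            np.abs((d_new - d_old) / d_old).max(),
        )
        if change < conv:
            break
    return g_new, d_new


def combat_fit_apply(
    values: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    flags: list[str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, CombatModel]:
    """Harmonize the flagged feature columns by ComBat; pass the rest through.

    ``flags`` lists the features to harmonize (default: all columns).
    Unflagged columns are returned bit-identical.  Each harmonized feature
    needs >= 2 batches with >= 3 observations each; with a single batch the
    input is returned unchanged (no batch effect is estimable).
    """
    batch = np.asarray(batch)
    if len(batch) != len(values):
        raise ValidationError("batch labels and value rows differ in length")
    if flags is None:
        selected = list(values.columns)
    elif isinstance(flags, pd.Series):
        selected = list(values.columns[np.asarray(flags, bool)]) if flags.dtype == bool else list(flags)
    else:
        selected = list(flags)
    missing = [f for f in selected if f not in values.columns]
    if missing:
        raise ValidationError(f"flagged features absent from table: {missing}")

    levels, counts = np.unique(batch, return_counts=True)
    if len(levels) < 2 or not selected:
        return values.copy(), CombatModel(tuple(selected), tuple(levels))
    small = [str(l) for l, c in zip(levels, counts) if c < 3]
    if small:
        raise ValidationError(f"batch(es) {small} have fewer than 3 observations")

    codes = np.searchsorted(levels, batch)
    data = values[selected].to_numpy(float)
    adjusted, grand_mean, pooled_var, gamma_star, delta_star = _combat_adjust(
        data, codes, len(levels)
    )
    out = values.copy()
    out[selected] = adjusted
    model = CombatModel(
        features=tuple(selected),
        batches=tuple(levels),
        grand_mean={f: float(m) for f, m in zip(selected, grand_mean)},
        pooled_var={f: float(v) for f, v in zip(selected, pooled_var)},
        gamma_star={(f, l): float(gamma_star[i, j]) for i, l in enumerate(levels) for j, f in enumerate(selected)},
        delta_star={(f, l): float(delta_star[i, j]) for i, l in enumerate(levels) for j, f in enumerate(selected)},
    )
    return out, model


def harmonize_cohort(
    values: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    mode: str = "gated",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Gate-then-harmonize workflow with a before/after report.

    ``mode='gated'`` harmonizes only features flagged by
    :func:`detect_batch_effect`; ``mode='all'`` harmonizes every feature;
    ``mode='off'`` passes through.  The report carries raw/adjusted p before
    and after, the flags, and the fitted model; a feature still flagged
    after harmonization is reported, never hidden.
    """
    if mode not in ("gated", "all", "off"):
        raise ValidationError(f"harmonization mode must be gated/all/off, got {mode!r}")
    if mode == "off":
        return values.copy(), {"mode": mode, "flagged": []}
    before = detect_batch_effect(values, batch, alpha)
    flagged = list(before.index[before["flag"]]) if mode == "gated" else list(values.columns)
    if not flagged:
        return values.copy(), {"mode": mode, "before": before, "flagged": [], "model": None}
    harmonized, model = combat_fit_apply(values, batch, flagged)
    after = detect_batch_effect(harmonized, batch, alpha)
    still = list(after.index[after["flag"] & before["flag"]])
    if still:
        warnings.warn(f"features still flagged after harmonization: {still}", stacklevel=2)
    return harmonized, {
        "mode": mode,
        "before": before,
        "after": after,
        "flagged": flagged,
        "still_flagged": still,
        "model": model,
    }
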