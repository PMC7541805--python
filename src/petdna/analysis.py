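"""End-to-end cohort analysis: Model / Results objects.

:class:`CohortAnalysis` is built from a cohort table (one row per patient:
the twelve PET features plus disease, machine and circulating-DNA levels)
and an :class:`AnalysisConfig`; :meth:`CohortAnalysis.fit` runs the full
battery in order — machine-effect gate and ComBat harmonization, disease
distribution comparisons, feature–feature Spearman clusters, feature–DNA
correlation tables, univariate OLS and bidirectional stepwise OLS — and
returns a :class:`CohortAnalysisResults` carrying every table, exclusion
accounting, and a ``summary()``.

BH families follow the tables they feed: one family of 12 tests per
(disease x DNA target) for feature–DNA correlations and univariate fits;
one family over all feature pairs per disease for the feature–feature
matrix; one family of 12 for the machine-effect gate per disease.  Patients
with null ctDNA (no mutation found — an assay false negative, not a zero)
are excluded from ctDNA analyses only, and the exclusion count is a
first-class output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import StageError, ValidationError
from .features import FEATURE_NAMES
from .harmonize import harmonize_cohort
from .stats import (
    RegressionResult,
    bh_adjust,
    correlation_clusters,
    mann_whitney,
    spearman_matrix,
    stepwise_ols,
    univariate_ols,
)

__all__ = ["AnalysisConfig", "CohortAnalysis", "CohortAnalysisResults"]

DNA_TARGETS = ("cfdna_hge", "ctdna_hge")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the cohort analysis; echoed into every output."""

    features: tuple[str, ...] = FEATURE_NAMES
    disease_col: str = "disease"
    machine_col: str | None = "machine"
    harmonize_mode: str = "gated"       # gated | all | off
    alpha: float = 0.05
    rho_min: float = 0.7                # "high correlation" edge threshold for clusters
    stepwise_direction: str = "both"
    stepwise_start: str = "full"
    targets: tuple[str, ...] = DNA_TARGETS

    def __post_init__(self) -> None:
        if self.harmonize_mode not in ("gated", "all", "off"):
            raise ValidationError(f"harmonize_mode must be gated/all/off, got {self.harmonize_mode!r}")


class CohortAnalysis:
    """The analysis model: a cohort table plus configuration.

    Parameters
    ----------
    cohort
        One row per patient.  Must contain ``config.features`` and
        ``config.targets``; ``disease`` and ``machine`` columns are used
        when present (harmonization is skipped, with a notice, without a
        machine column).
    config
        :class:`AnalysisConfig`; defaults reproduce the standard workflow.
    """

    def __init__(self, cohort: pd.DataFrame, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        missing = [c for c in self.config.features if c not in cohort.columns]
        if missing:
            raise ValidationError(f"cohort table is missing feature columns {missing}")
        for t in self.config.targets:
            if t not in cohort.columns:
                raise ValidationError(f"cohort table is missing target column {t!r}")
        self.cohort = cohort.reset_index(drop=True).copy()

    @classmethod
    def from_csv(cls, path, config: AnalysisConfig | None = None) -> "CohortAnalysis":
        return cls(pd.read_csv(path), config=config)

    # ------------------------------------------------------------------
    def _diseases(self) -> dict[str, pd.DataFrame]:
        col = self.config.disease_col
        if col in self.cohort.columns:
            return {str(d): g for d, g in self.cohort.groupby(col, sort=True)}
        return {"all": self.cohort}

    def fit(self) -> "CohortAnalysisResults":
        """Run every stage in order and return the results object."""
        cfg = self.config
        features = list(cfg.features)
        notices: list[str] = []
        harmonization: dict[str, dict] = {}
        groups = self._diseases()
        for name, group in groups.items():
            if len(group) < 4:
                raise StageError(f"stage harmonization: stratum {name!r} has fewer than 4 rows")

        # stage 1: machine-effect gate + ComBat, within each disease
        harmonized_groups = {}
        for name, group in groups.items():
            machine_ok = (
                cfg.machine_col is not None
                and cfg.machine_col in group.columns
                and group[cfg.machine_col].nunique() == 2
                and group[cfg.machine_col].value_counts().min() >= 3
            )
            if cfg.harmonize_mode == "off" or not machine_ok:
                if cfg.harmonize_mode != "off":
                    notices.append(
                        f"harmonization skipped for {name}: no usable machine column "
                        f"({cfg.machine_col!r} missing, single-machine, or a machine with < 3 patients)"
                    )
                harmonized_groups[name] = group
                harmonization[name] = {"mode": "off", "flagged": []}
                continue
            try:
                values, report = harmonize_cohort(
                    group[features], group[cfg.machine_col], mode=cfg.harmonize_mode, alpha=cfg.alpha
                )
            except Exception as exc:
                raise StageError(f"stage harmonization failed for {name}: {exc}") from exc
            g = group.copy()
            g[features] = values
            harmonized_groups[name] = g
            harmonization[name] = report

        # stage 2: disease-vs-disease distribution tests (when 2 diseases)
        disease_comparison = None
        if len(harmonized_groups) == 2:
            (na, ga), (nb, gb) = sorted(harmonized_groups.items())
            rows = []
            for feat in features:
                _, p = mann_whitney(ga[feat].to_numpy(float), gb[feat].to_numpy(float))
                rows.append({"feature": feat, "p": p})
            disease_comparison = pd.DataFrame(rows)
            disease_comparison["p_adj"] = bh_adjust(disease_comparison["p"].to_numpy())
            disease_comparison.attrs["groups"] = (na, nb)

        # stages 3-6, per disease
        descriptives, feature_corr, clusters = {}, {}, {}
        dna_corr, univariate, stepwise, exclusions = {}, {}, {}, {}
        for name, group in harmonized_groups.items():
            descriptives[name] = self._descriptives(group, features)
            try:
                ff = spearman_matrix(group, features)
            except Exception as exc:
                raise StageError(f"stage feature-correlations failed for {name}: {exc}") from exc
            feature_corr[name] = ff
            clusters[name] = correlation_clusters(ff, rho_min=cfg.rho_min, alpha=cfg.alpha)

            dna_corr[name] = spearman_matrix(group, features, targets=list(cfg.targets))
            exclusions[name] = {
                t: int(group[t].isna().sum()) for t in cfg.targets
            }

            uni_rows = []
            for target in cfg.targets:
                for feat in features:
                    try:
                        res = univariate_ols(group[target], group[feat], name=feat)
                    except ValidationError as exc:
                        notices.append(f"univariate {name}/{target}~{feat} skipped: {exc}")
                        continue
                    uni_rows.append(
                        {
                            "target": target,
                            "feature": feat,
                            "slope": res.terms[feat],
                            "intercept": res.intercept,
                            "adj_r2": res.adj_r2,
                            "p": res.slope_pvalues[feat],
                            "n": res.n,
                        }
                    )
            uni = pd.DataFrame(uni_rows)
            if len(uni):
                uni["p_adj"] = np.nan
                for target in cfg.targets:
                    sel = uni["target"] == target
                    if sel.any():
                        uni.loc[sel, "p_adj"] = bh_adjust(uni.loc[sel, "p"].to_numpy())
            univariate[name] = uni

            steps = {}
            for target in cfg.targets:
                usable = group[[target] + features].dropna()
                if len(usable) <= len(features) + 1:
                    notices.append(
                        f"stepwise {name}/{target} skipped: {len(usable)} usable rows for "
                        f"{len(features)} candidates"
                    )
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    steps[target] = stepwise_ols(
                        usable[target],
                        usable[features],
                        direction=cfg.stepwise_direction,
                        start=cfg.stepwise_start,
                    )
            stepwise[name] = steps

        return CohortAnalysisResults(
            config=cfg,
            cohort=self.cohort,
            harmonized={n: g for n, g in harmonized_groups.items()},
            harmonization=harmonization,
            disease_comparison=disease_comparison,
            descriptives=descriptives,
            feature_corr=feature_corr,
            clusters=clusters,
            dna_corr=dna_corr,
            univariate=univariate,
            stepwise=stepwise,
            exclusions=exclusions,
            notices=notices,
        )

    @staticmethod
    def _descriptives(group: pd.DataFrame, features: list[str]) -> pd.DataFrame:
        rows = []
        for feat in features:
            v = group[feat].to_numpy(float)
            rows.append(
                {
                    "feature": feat,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)),
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                    "n": int(v.size),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CohortAnalysisResults:
    """Everything the analysis produced, with save/summary helpers."""

    config: AnalysisConfig
    cohort: pd.DataFrame
    harmonized: dict
    harmonization: dict
    disease_comparison: pd.DataFrame | None
    descriptives: dict
    feature_corr: dict
    clusters: dict
    dna_corr: dict
    univariate: dict
    stepwise: dict
    exclusions: dict
    notices: list = field(default_factory=list)

    def top_dna_correlates(self, disease: str, target: str = "ctdna_hge", k: int = 3) -> list[str]:
        """The k features most rank-correlated with a DNA target."""
        table = self.dna_corr[disease]
        sub = table[table["target"] == target].dropna(subset=["rho"])
        return list(sub.sort_values("rho", ascending=False)["feature"].head(k))

    def summary(self) -> str:
        lines = ["Cohort analysis summary", "=" * 23]
        for name in self.descriptives:
            n = len(self.harmonized[name])
            lines.append(f"\n[{name}] n = {n}")
            rep = self.harmonization.get(name, {})
            flagged = rep.get("flagged", [])
            lines.append(
                f"  machine effect: {len(flagged)} feature(s) flagged"
                + (f" and harmonized: {', '.join(flagged)}" if flagged else ""))
            for target, n_null in self.exclusions[name].items():
                if n_null:
                    lines.append(f"  {target}: {n_null} null row(s) excluded (no mutation found)")
            for i, cluster in enumerate(self.clusters[name], 1):
                lines.append(f"  cluster {i}: {', '.join(cluster['members'])}")
            for target in self.config.targets:
                top = self.top_dna_correlates(name, target)
                table = self.dna_corr[name]
                sub = table[table["target"] == target].set_index("feature")
                tops = ", ".join(f"{f} (rho={sub.loc[f, 'rho']:.2f})" for f in top)
                lines.append(f"  top {target} correlates: {tops}")
            for target, res in self.stepwise[name].items():
                lines.append(
                    f"  stepwise {target}: {res.formula}  [adj R2 = {res.adj_r2:.2f}, "
                    f"p = {res.f_pvalue:.3g}, n = {res.n}]"
                )
        for note in self.notices:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, out_dir) -> None:
        """Write the full report bundle (CSV + JSON) to a directory."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self.descriptives:
            tag = name.replace(" ", "_")
            self.descriptives[name].to_csv(out / f"descriptives_{tag}.csv", index=False)
            self.feature_corr[name].to_csv(out / f"feature_correlations_{tag}.csv", index=False)
            self.dna_corr[name].to_csv(out / f"dna_correlations_{tag}.csv", index=False)
            self.univariate[name].to_csv(out / f"univariate_{tag}.csv", index=False)
        if self.disease_comparison is not None:
            self.disease_comparison.to_csv(out / "disease_comparison.csv", index=False)
        report = {
            "config": asdict(self.config),
            "exclusions": self.exclusions,
            "clusters": self.clusters,
            "notices": self.notices,
            "harmonization": {
                name: {
                    "mode": rep.get("mode"),
                    "flagged": rep.get("flagged", []),
                    "still_flagged": rep.get("still_flagged", []),
                    "p_before": rep["before"]["p_adj"].to_dict() if "before" in rep else None,
                    "p_after": rep["after"]["p_adj"].to_dict() if "after" in rep else None,
                }
                for name, rep in self.harmonization.items()
            },
            "stepwise": {
                name: {
                    target: {
                        "formula": res.formula,
                        "terms": res.terms,
                        "intercept": res.intercept,
                        "adj_r2": res.adj_r2,
                        "f_pvalue": res.f_pvalue,
                        "n": res.n,
                        "trace": [list(t) for t in res.trace],
                    }
                    for target, res in steps.items()
                }
                for name, steps in self.stepwise.items()
            },
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")

    def plot_feature_histograms(self, out_path=None):
        """Per-feature histograms fused across diseases, with the
        between-disease Mann–Whitney p in each panel title."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        features = list(self.config.features)
        fig, axes = plt.subplots(3, 4, figsize=(16, 10))
        pvals = (
            self.disease_comparison.set_index("feature")["p_adj"]
            if self.disease_comparison is not None
            else None
        )
        for ax, feat in zip(axes.ravel(), features):
            for name, group in self.harmonized.items():
                ax.hist(group[feat].dropna(), bins=15, alpha=0.5, label=name)
            title = feat if pvals is None else f"{feat} (p={pvals[feat]:.3g})"
            ax.set_title(title, fontsize=9)
        axes.ravel()[0].legend(fontsize=8)
        fig.tight_layout()
        if out_path:
            fig.savefig(out_path, dpi=120)
            plt.close(fig)
        return fig

    def plot_correlation_clusters(self, disease: str, out_path=None):
        """Graph plot of the high-correlation clusters for one disease."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(self.config.features)
        for cluster in self.clusters[disease]:
            for u, v, rho in cluster["edges"]:
                graph.add_edge(u, v, rho=rho)
        fig, ax = plt.subplots(figsize=(8, 6))
        pos = nx.spring_layout(graph, seed=7)
        nx.draw_networkx(graph, pos, ax=ax, node_size=900, font_size=8, node_color="#cfe2f3")
        nx.draw_networkx_edge_labels(
            graph,
            pos,
            ax=ax,
            edge_labels={(u, v): f"{d['rho']:.2f}" for u, v, d in graph.edges(data=True)},
            font_size=7,
        )
        ax.set_title(f"High Spearman correlations ({disease})")
        ax.axis("off")
        if out_path:
            fig.savefig(out_path, dpi=120)
            plt.close(fig)
        return fig
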