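"""Statistical comparisons and study-report assembly.

Paired per-disk interpretability metrics are compared between attribution
methods with the Wilcoxon signed-rank test under a Bonferroni-corrected
alpha (0.05/3 = 0.017 for the three pairwise method comparisons), and
per-fold AUC vectors are compared with a one-sided Welch t-test.  The
report step writes the summary tables (CSV) and figures (PNG) of the study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    """Too few informative pairs for a paired test."""


@dataclass
class PairedMetricSample:
    """Per-disk metric values for two attribution methods, aligned by disk.

    Missing values (NaN) are deleted pairwise before testing.
    """

    values_a: np.ndarray
    values_b: np.ndarray
    metric: str = ""
    strategy: str = ""

    def cleaned(self) -> tuple[np.ndarray, np.ndarray, int]:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        keep = ~(np.isnan(a) | np.isnan(b))
        return a[keep], b[keep], int((~keep).sum())


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    alpha_corrected: float
    significant: bool
    n_pairs: int = 0
    n_dropped_missing: int = 0


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test alpha for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def wilcoxon_signed_rank(
    sample: PairedMetricSample,
    alternative: str = "two-sided",
    alpha_corrected: float = 0.017,
    min_pairs: int = 6,
) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired per-disk metrics.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 (ties permitting), the normal approximation otherwise.
    """
    a, b, dropped = sample.cleaned()
    diff = a - b
    diff = diff[diff != 0.0]
    n = len(diff)
    if n < min_pairs:
        raise InsufficientDataError(
            f"only {n} non-zero paired differences (need >= {min_pairs})")
    method = "exact" if (n <= 25 and len(np.unique(np.abs(diff))) == n) else "approx"
    res = stats.wilcoxon(diff, alternative=alternative, method=method,
                         zero_method="wilcox")
    p = float(res.pvalue)
    return ComparisonResult(
        statistic=float(res.statistic), p_value=p,
        alpha_corrected=alpha_corrected, significant=bool(p < alpha_corrected),
        n_pairs=n, n_dropped_missing=dropped,
    )


def one_sided_t_test(
    aucs_a: np.ndarray, aucs_b: np.ndarray, alpha: float = 0.05
) -> ComparisonResult:
    """Two-sample one-sided Welch t-test of H1: mean(a) > mean(b)."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate samples: zero variance in both")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    return ComparisonResult(
        statistic=float(res.statistic), p_value=p,
        alpha_corrected=alpha, significant=bool(p < alpha), n_pairs=len(a),
    )


# ---------------------------------------------------------------------------
# method comparisons over the long-format metrics table


def compare_methods(
    table: pd.DataFrame,
    metric: str,
    strategy: str,
    factor: float = 1.0,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise Wilcoxon comparisons between attribution methods for one
    metric/strategy at one threshold factor (Bonferroni m = 3)."""
    sub = table[(table.strategy == strategy) & (table.factor == factor)]
    pivot = sub.pivot_table(index="disk", columns="method", values=metric,
                            aggfunc="first")
    methods = list(pivot.columns)
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1:]]
    alpha_c = bonferroni_alpha(family_alpha, len(pairs) or 1)
    rows = []
    for a, b in pairs:
        sample = PairedMetricSample(pivot[a].to_numpy(), pivot[b].to_numpy(),
                                    metric=metric, strategy=strategy)
        try:
            res = wilcoxon_signed_rank(sample, alpha_corrected=alpha_c)
            rows.append(dict(strategy=strategy, metric=metric, method_a=a,
                             method_b=b, statistic=res.statistic,
                             p_value=res.p_value, alpha_corrected=alpha_c,
                             significant=res.significant, n_pairs=res.n_pairs))
        except InsufficientDataError:
            rows.append(dict(strategy=strategy, metric=metric, method_a=a,
                             method_b=b, statistic=np.nan, p_value=np.nan,
                             alpha_corrected=alpha_c, significant=False,
                             n_pairs=0))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report assembly


def build_report(
    out_dir: str | Path,
    eval_report=None,
    metrics_table: pd.DataFrame | None = None,
    comparisons: pd.DataFrame | None = None,
    averages: dict | None = None,
) -> dict:
    """Write the study's tables and figures; returns a completeness log.

    Emits (when inputs are present): model metrics per fold and summary,
    interpretability metric summaries (mean +- sd by method/strategy/factor),
    pairwise comparison p-values, boxplot figures per metric, averaged
    attribution/lesion maps, and a threshold-sensitivity figure.
    Regeneration over the same inputs is idempotent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"written": [], "missing": []}

    if eval_report is not None:
        eval_report.per_fold.to_csv(out / "model_metrics_per_fold.csv", index=False)
        flat = eval_report.summary.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        flat.to_csv(out / "model_metrics_summary.csv")
        log["written"] += ["model_metrics_per_fold.csv", "model_metrics_summary.csv"]
    else:
        log["missing"].append("eval_report")

    if metrics_table is not None and len(metrics_table):
        metrics_table.to_csv(out / "interpretability_metrics.csv", index=False)
        summary = (metrics_table
                   .groupby(["method", "strategy", "factor"])[["iou", "lesion_pct", "nat_pct"]]
                   .agg(["mean", "std", "count"]))
        summary.columns = ["_".join(c) for c in summary.columns]
        summary.to_csv(out / "interpretability_summary.csv")
        acc = (metrics_table
               .groupby(["method", "strategy", "correct_classification"])[["iou", "lesion_pct", "nat_pct"]]
               .mean())
        acc.to_csv(out / "interpretability_by_correctness.csv")
        log["written"] += ["interpretability_metrics.csv",
                          "interpretability_summary.csv",
                          "interpretability_by_correctness.csv"]

        for metric in ("iou", "lesion_pct", "nat_pct"):
            fig, ax = plt.subplots(figsize=(7, 4))
            sub = metrics_table[metrics_table.factor == 1.0]
            groups, labels_ = [], []
            for strat in sub.strategy.unique():
                for method in sub.method.unique():
                    vals = sub[(sub.strategy == strat) & (sub.method == method)][metric].dropna()
                    groups.append(vals)
                    labels_.append(f"{strat}\n{method}")
            ax.boxplot(groups, tick_labels=labels_)
            ax.set_ylabel(metric)
            fig.tight_layout()
            fig.savefig(out / f"boxplot_{metric}.png", dpi=110)
            plt.close(fig)
            log["written"].append(f"boxplot_{metric}.png")

        sens = (metrics_table
                .groupby(["factor", "method", "strategy"])[["iou", "lesion_pct", "nat_pct"]]
                .mean().reset_index())
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
        for ax, metric in zip(axes, ("iou", "lesion_pct", "nat_pct")):
            for (method, strat), grp in sens.groupby(["method", "strategy"]):
                ax.plot(grp.factor, grp[metric], marker="o", label=f"{method}/{strat}")
            ax.set_xlabel("threshold factor")
            ax.set_ylabel(metric)
        axes[-1].legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "threshold_sensitivity.png", dpi=110)
        plt.close(fig)
        log["written"].append("threshold_sensitivity.png")
    else:
        log["missing"].append("metrics_table")

    if comparisons is not None and len(comparisons):
        comparisons.to_csv(out / "method_comparisons.csv", index=False)
        log["written"].append("method_comparisons.csv")
    else:
        log["missing"].append("comparisons")

    if averages:
        n_fa = len(averages.get("fa", {}))
        if n_fa:
            cols = 3
            rows_n = int(np.ceil(n_fa / cols))
            fig, axes = plt.subplots(rows_n, cols, figsize=(3 * cols, 3 * rows_n))
            axes = np.atleast_1d(axes).ravel()
            for ax, ((method, strat), grid) in zip(axes, sorted(averages["fa"].items())):
                ax.imshow(grid, cmap="inferno")
                ax.set_title(f"{method}/{strat}", fontsize=8)
                ax.axis("off")
            for ax in axes[n_fa:]:
                ax.axis("off")
            fig.tight_layout()
            fig.savefig(out / "population_fa_maps.png", dpi=110)
            plt.close(fig)
            log["written"].append("population_fa_maps.png")
        if averages.get("lesions"):
            fig, axes = plt.subplots(1, len(averages["lesions"]), figsize=(9, 3))
            for ax, (strat, grid) in zip(np.atleast_1d(axes), sorted(averages["lesions"].items())):
                ax.imshow(grid, cmap="viridis")
                ax.set_title(strat, fontsize=8)
                ax.axis("off")
            fig.tight_layout()
            fig.savefig(out / "population_lesions.png", dpi=110)
            plt.close(fig)
            log["written"].append("population_lesions.png")
    else:
        log["missing"].append("averages")

    pd.Series(log["missing"], dtype=object).to_csv(out / "completeness_log.csv", index=False)
    return log
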