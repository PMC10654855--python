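"""Model evaluation: discrimination, calibration, F1-optimal threshold
metrics, median-centering, rank-sum comparisons of feature-set families,
predictive-multiplicity correlations, and per-algorithm feature
importance.

Metric conventions: AUROC is the Mann-Whitney/rank statistic with tie
correction; AUPRC is the area under the precision-recall step function
(average precision); the Brier score is the mean squared difference
between predicted probability and outcome. Precision, recall, and F1 are
reported at the probability threshold that maximizes F1, found by
exhaustive scan over the unique predicted probabilities (ties broken
toward the smallest threshold).

Family comparisons use two-sided unpaired Wilcoxon rank-sum tests (exact
enumeration when both groups have <= 10 tie-free values, normal
approximation with tie correction otherwise), Bonferroni-adjusted over
the family pairs tested within one (task, validation-type, metric)
analysis. Predictive multiplicity between two models is the Pearson
correlation of their predicted probabilities over a shared observation
set, averaged across text-representation and algorithm cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import MetricError

FAMILIES = ("S", "T", "S+T")
CORRELATION_BANDS = ((0.8, "very strong"), (0.6, "strong"),
                     (0.4, "moderate"), (-np.inf, "weak"))


@dataclass
class EvaluationRecord:
    """Metrics for one (task, combo, algorithm, validation-type) cell."""

    task: str
    combo: str
    representation: str
    algorithm: str
    validation_type: str
    auroc: float
    auprc: float
    brier: float
    precision: float
    recall: float
    f1: float
    threshold: float


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise MetricError("metrics are undefined for single-class labels")


def auroc(labels, probabilities) -> float:
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, probabilities))


def auprc(labels, probabilities) -> float:
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, probabilities))


def brier(labels, probabilities) -> float:
    labels = np.asarray(labels, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    return float(np.mean((probabilities - labels) ** 2))


def f1_max_threshold(labels, probabilities) -> dict:
    """Precision/recall/F1 at the F1-maximizing threshold.

    Candidate thresholds are the unique predicted probabilities
    (prediction rule: positive iff p >= threshold); among equal-F1
    thresholds the smallest is reported.
    """
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    _check_two_classes(labels)
    n_pos = labels.sum()
    best = None
    for t in np.unique(probabilities):
        pred = probabilities >= t
        tp = int(np.sum(labels[pred]))
        n_pred = int(pred.sum())
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_pos
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        if best is None or f1 > best["f1"] + 1e-15:
            best = {"precision": precision, "recall": recall, "f1": f1,
                    "threshold": float(t)}
    return best


def compute_metrics(labels, probabilities) -> dict:
    """All scalar metrics for one validation of one model."""
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    _check_two_classes(labels)
    out = {
        "auroc": auroc(labels, probabilities),
        "auprc": auprc(labels, probabilities),
        "brier": brier(labels, probabilities),
    }
    out.update(f1_max_threshold(labels, probabilities))
    return out


# ---------------------------------------------------------------------------
# Median-centering and family comparisons
# ---------------------------------------------------------------------------


def median_center(records: pd.DataFrame, metric: str = "auroc",
                  group_cols: tuple[str, ...] = ("task", "validation_type",
                                                 "family")) -> pd.DataFrame:
    """Subtract each group's median metric so representation/algorithm
    effects are comparable across tasks and feature-set families."""
    out = records.copy()
    out[f"{metric}_centered"] = records[metric] - records.groupby(
        list(group_cols)
    )[metric].transform("median")
    return out


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration for tie-free groups of <= 10 values each, otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and tie_free) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_combos(records: pd.DataFrame, metric: str = "auroc"
                   ) -> pd.DataFrame:
    """Pairwise family comparisons (S vs T vs S+T) per (task,
    validation_type), Bonferroni-adjusted within each analysis."""
    rows = []
    for (task, vtype), grp in records.groupby(["task", "validation_type"]):
        pairs = [
            (a, b) for a, b in combinations(FAMILIES, 2)
            if (grp["family"] == a).sum() >= 2 and (grp["family"] == b).sum() >= 2
        ]
        n_comparisons = len(pairs)
        for fam_a, fam_b in pairs:
            stat, p = rank_sum_test(
                grp.loc[grp["family"] == fam_a, metric],
                grp.loc[grp["family"] == fam_b, metric],
            )
            rows.append({
                "task": task, "validation_type": vtype, "metric": metric,
                "family_a": fam_a, "family_b": fam_b, "statistic": stat,
                "p_raw": p,
                "p_adjusted": min(1.0, p * n_comparisons),
                "n_comparisons": n_comparisons,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Predictive multiplicity
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlation_band(r: float) -> str:
    for lo, name in CORRELATION_BANDS:
        if r > lo:
            return name
    return "weak"

MODEL_PAIRS = (("S", "T"), ("S", "S+T"), ("T", "S+T"))


def multiplicity(predictions: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of predicted probabilities between the S, T,
    and S+T models for the same observations, averaged across the
    representation x algorithm cells of each (task, pair, validation_type).
    """
    reps = ("term", "tfidf", "concept")
    rows = []
    for (task, vtype), grp in predictions.groupby(["task", "validation_type"]):
        pivot = grp.pivot_table(
            index=["person_id", "index_date"],
            columns=["combo", "algorithm"],
            values="probability",
        )
        algorithms = sorted(grp["algorithm"].unique())

        def cell(combo, alg):
            return pivot[(combo, alg)].to_numpy() \
                if (combo, alg) in pivot.columns else None

        for fam_a, fam_b in MODEL_PAIRS:
            rs = []
            for rep in reps:
                for alg in algorithms:
                    a = cell("S" if fam_a == "S" else
                             ("T_" if fam_a == "T" else "ST_") + _rep_suffix(rep),
                             alg)
                    b = cell("S" if fam_b == "S" else
                             ("T_" if fam_b == "T" else "ST_") + _rep_suffix(rep),
                             alg)
                    if a is None or b is None:
                        continue
                    r = pearson_r(a, b)
                    if not np.isnan(r):
                        rs.append(r)
            if rs:
                mean_r = float(np.mean(rs))
                rows.append({
                    "task": task, "validation_type": vtype,
                    "pair": f"{fam_a} vs {fam_b}", "pearson_r": mean_r,
                    "band": correlation_band(mean_r), "n_cells": len(rs),
                })
    return pd.DataFrame(rows)


def _rep_suffix(rep: str) -> str:
    return {"term": "term", "tfidf": "tfidf", "concept": "con"}[rep]


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------


def feature_importance(model, k: int = 10) -> pd.DataFrame:
    """Top-k features of a trained model.

    LR: signed coefficients ranked by absolute value (exact zeros
    dropped). RF: mean decrease in impurity. XGB: average split gain.
    ``k`` larger than the feature count returns everything; k = 0 returns
    an empty table.
    """
    algorithm = model.algorithm
    est = model.estimator
    if algorithm == "lr":
        clf = est.named_steps["clf"] if hasattr(est, "named_steps") else est
        values = clf.coef_.ravel()
        keep = np.flatnonzero(values != 0)
    elif algorithm == "rf":
        values = est.feature_importances_
        keep = np.arange(len(values))
    else:  # xgb: average gain per feature, absent features scored 0
        gain = est.get_booster().get_score(importance_type="gain")
        values = np.zeros(len(model.feature_ids))
        for key, v in gain.items():
            values[int(key[1:])] = v
        keep = np.arange(len(values))

    order = keep[np.argsort(-np.abs(values[keep]), kind="stable")]
    if k >= 0:
        order = order[:k]
    rows = []
    for rank, j in enumerate(order, start=1):
        d = model.descriptors[j]
        rows.append({
            "rank": rank, "feature_id": d.feature_id,
            "source_set": d.source_set, "window_tag": d.window_tag,
            "name": d.name, "importance": float(values[j]),
        })
    return pd.DataFrame(
        rows, columns=["rank", "feature_id", "source_set", "window_tag",
                       "name", "importance"],
    )


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------


def write_report(records: pd.DataFrame, comparisons: pd.DataFrame,
                 multiplicity_table: pd.DataFrame, out_dir: str | Path,
                 metric: str = "auroc") -> Path:
    """Markdown summary with box-plot figures (feature-family performance
    per task and validation type, plus multiplicity bars)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tasks = sorted(records["task"].unique())
    fig, axes = plt.subplots(1, len(tasks), figsize=(3.2 * len(tasks), 3.5),
                             squeeze=False, sharey=True)
    for ax, task in zip(axes[0], tasks):
        sub = records[records["task"] == task]
        data, labels = [], []
        for fam in FAMILIES:
            for vtype in ("internal", "external"):
                vals = sub.loc[(sub["family"] == fam)
                               & (sub["validation_type"] == vtype), metric]
                data.append(vals)
                labels.append(f"{fam}\n{vtype[:3]}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(task, fontsize=9)
        ax.tick_params(labelsize=7)
    axes[0][0].set_ylabel(metric.upper())
    fig.tight_layout()
    fig.savefig(out / f"family_{metric}_boxplots.png", dpi=120)
    plt.close(fig)

    lines = [
        "# Benchmark summary", "",
        f"Models evaluated: {len(records) // 2} "
        f"({records['task'].nunique()} tasks x "
        f"{records['combo'].nunique()} feature combinations x "
        f"{records['algorithm'].nunique()} algorithms)", "",
        f"## Median {metric.upper()} by task, family, validation", "",
        "```",
        records.groupby(["task", "family", "validation_type"])[metric]
        .median().round(3).to_string(),
        "```", "",
        "## Family comparisons (rank-sum, Bonferroni-adjusted)", "",
        "```", comparisons.round(4).to_string(index=False), "```", "",
        "## Predictive multiplicity (mean Pearson r)", "",
        "```", multiplicity_table.round(3).to_string(index=False), "```", "",
        f"![boxplots](family_{metric}_boxplots.png)", "",
    ]
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
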