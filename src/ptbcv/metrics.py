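"""Discrimination and classification metrics with cross-fold summaries.

AUROC uses the Mann-Whitney formulation (fraction of case/control pairs
ranked correctly, ties counted one half), so it is invariant under strictly
monotone transformations of the scores.  The confusion-matrix panel
(sensitivity, specificity, PPV, NPV, FPR, FNR) is computed from the 2x2
table at a score threshold; ratios with a zero denominator are reported as
NaN and excluded from aggregation with a logged count, never silently
substituted.  Cross-fold aggregation reports mean and a normal-approximation
95% CI (mean +/- 1.96 * SD / sqrt(n_folds)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auroc", "sensitivity", "specificity", "ppv", "npv", "fpr", "fnr")


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC; raises if only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Sensitivity/specificity panel at ``score >= threshold``; NaN where undefined."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("confusion metrics need both classes present")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "fpr": 1.0 - spec if np.isfinite(spec) else float("nan"),
        "fnr": 1.0 - sens if np.isfinite(sens) else float("nan"),
    }


@dataclass
class PerformanceReport:
    """Cross-fold metric panel for one (model family, evaluation set)."""

    set_label: str
    metrics: dict[str, tuple[float, float, float]]  # name -> (mean, ci_low, ci_high)
    n_folds: int
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    excluded: dict[str, int] = field(default_factory=dict)

    def to_row(self, clip_display: bool = True) -> dict[str, str]:
        """One performance-table row of ``mean(low-high)`` strings."""
        row = {"set": self.set_label}
        for name in METRIC_NAMES:
            mean, lo, hi = self.metrics[name]
            if clip_display:
                lo, hi = max(lo, 0.0), min(hi, 1.0)
            row[name] = (f"{mean:.2f}({lo:.2f}-{hi:.2f})"
                         if np.isfinite(mean) else "NA")
        return row


def aggregate_folds(
    fold_metrics: list[dict[str, float]],
    set_label: str = "",
    n_pos: int = 0,
    n_neg: int = 0,
    threshold: float = 0.5,
) -> PerformanceReport:
    """Mean and normal-approximation 95% CI across folds for each metric.

    NaN fold values (undefined ratios) are excluded with a logged count.
    CI bounds are retained unclipped; clipping to [0, 1] is display-only.
    """
    if len(fold_metrics) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    out: dict[str, tuple[float, float, float]] = {}
    excluded: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = np.array([fm[name] for fm in fold_metrics if name in fm], dtype=float)
        finite = vals[np.isfinite(vals)]
        n_excl = len(vals) - len(finite)
        if n_excl:
            excluded[name] = n_excl
            logger.info("excluded %d undefined fold value(s) for %s", n_excl, name)
        if len(finite) == 0:
            out[name] = (float("nan"), float("nan"), float("nan"))
            continue
        mean = float(finite.mean())
        half = (1.96 * float(finite.std(ddof=1)) / np.sqrt(len(finite))
                if len(finite) > 1 else 0.0)
        out[name] = (mean, mean - half, mean + half)
    return PerformanceReport(set_label, out, len(fold_metrics), n_pos, n_neg,
                             threshold, excluded)


def stability_summary(selections: list[list[tuple[str, int]]]) -> pd.DataFrame:
    """Cross-iteration feature-stability table.

    ``selections`` holds, per outer iteration, the (feature, rank) pairs
    selected in that iteration (rank 1 = first/highest).  Returns a frame
    with ``times_selected`` and ``average_rank`` per feature, sorted by
    times selected (descending) then average rank; features never selected
    are absent.
    """
    counts: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    for sel in selections:
        for feature, rank in sel:
            counts[feature] = counts.get(feature, 0) + 1
            rank_sums[feature] = rank_sums.get(feature, 0.0) + rank
    if not counts:
        return pd.DataFrame(columns=["times_selected", "average_rank"])
    df = pd.DataFrame({
        "times_selected": pd.Series(counts),
        "average_rank": pd.Series({f: rank_sums[f] / counts[f] for f in counts}),
    })
    df.index.name = "feature"
    return df.sort_values(["times_selected", "average_rank"],
                          ascending=[False, True])


def selection_overlap(method_sets: dict[str, set]) -> dict[str, set]:
    """Pairwise and full intersections of per-method selected-feature sets."""
    names = list(method_sets)
    out: dict[str, set] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}&{b}"] = set(method_sets[a]) & set(method_sets[b])
    if len(names) > 2:
        inter = set(method_sets[names[0]])
        for nm in names[1:]:
            inter &= set(method_sets[nm])
        out["&".join(names)] = inter
    return out
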