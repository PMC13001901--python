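"""Group-fairness gaps and race-stratified performance for multiclass models.

All metrics use a macro one-vs-rest formulation over the predicted classes:

* demographic parity gap — for each class c, the spread across protected
  groups of the positive-prediction rate P(pred = c | group), averaged over
  classes;
* equal-opportunity gaps — the spreads of the class-conditional true-positive
  rate and false-positive rate, reported as a (TPR gap, FPR gap) pair;
* stratified performance — macro precision/recall/F1 and accuracy computed
  within each protected group.

Spread defaults to max − min across groups (mean absolute pairwise
difference is available as an option).  Rates for (class, group) cells with
fewer than ``min_support`` relevant records are undefined; classes left with
fewer than two defined groups contribute a gap of 0 and are recorded as
excluded rather than silently dropped — with heavily imbalanced protected
groups these per-cell rates are noisy, and exclusions make that visible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support


@dataclass
class GroupClassTable:
    """Exact per-(class, group) prediction counts.

    For every class c and group g: ``n_g`` group size, ``n_cg`` records of
    class c in g, ``pred_cg`` records in g predicted c, ``tp_cg`` and
    ``fp_cg`` true/false positives.  Each record contributes exactly one
    predicted class, so pred counts sum to the group size.
    """

    classes: tuple[str, ...]
    groups: tuple[str, ...]
    n_g: dict[str, int]
    n_cg: dict[tuple[str, str], int]
    pred_cg: dict[tuple[str, str], int]
    tp_cg: dict[tuple[str, str], int]
    fp_cg: dict[tuple[str, str], int]


def build_table(y_true: Sequence, y_pred: Sequence,
                groups: Sequence) -> GroupClassTable:
    """Count per-(class, group) outcomes for fairness computation."""
    y_true, y_pred, groups = (np.asarray(a).astype(str)
                              for a in (y_true, y_pred, groups))
    if not (len(y_true) == len(y_pred) == len(groups)):
        raise ValueError("y_true, y_pred and groups must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    classes = tuple(sorted(set(y_true) | set(y_pred)))
    group_names = tuple(sorted(set(groups)))
    n_g = {g: int(np.sum(groups == g)) for g in group_names}
    n_cg, pred_cg, tp_cg, fp_cg = {}, {}, {}, {}
    for g in group_names:
        in_g = groups == g
        for c in classes:
            true_c = y_true == c
            pred_c = y_pred == c
            n_cg[(c, g)] = int(np.sum(in_g & true_c))
            pred_cg[(c, g)] = int(np.sum(in_g & pred_c))
            tp_cg[(c, g)] = int(np.sum(in_g & true_c & pred_c))
            fp_cg[(c, g)] = int(np.sum(in_g & ~true_c & pred_c))
    return GroupClassTable(classes, group_names, n_g, n_cg, pred_cg, tp_cg, fp_cg)


def _spread(rates: list[float], aggregation: str) -> float:
    if len(rates) < 2:
        return 0.0
    if aggregation == "max_min":
        return max(rates) - min(rates)
    if aggregation == "mean_pairwise":
        pairs = list(itertools.combinations(rates, 2))
        return float(np.mean([abs(a - b) for a, b in pairs]))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def demographic_parity_gap(table: GroupClassTable, min_support: int = 1,
                           aggregation: str = "max_min"
                           ) -> tuple[dict[str, float], float]:
    """Per-class positive-prediction-rate spreads and their macro average."""
    eligible = [g for g in table.groups if table.n_g[g] >= min_support]
    if not eligible:
        raise ValueError(f"no group has at least min_support={min_support} records")
    per_class = {}
    for c in table.classes:
        rates = [table.pred_cg[(c, g)] / table.n_g[g] for g in eligible]
        per_class[c] = _spread(rates, aggregation)
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


def equal_opportunity_gaps(table: GroupClassTable, min_support: int = 1,
                           aggregation: str = "max_min"):
    """Per-class TPR and FPR spreads across groups, plus macro averages.

    TPR_{c,g} is defined only where the group holds at least ``min_support``
    true positives of class c; FPR_{c,g} where it holds at least
    ``min_support`` true negatives.  Classes with fewer than two defined
    groups get gap 0 and an exclusion record.
    """
    if not any(table.n_g[g] >= min_support for g in table.groups):
        raise ValueError(f"no group has at least min_support={min_support} records")
    tpr_gaps, fpr_gaps, excluded = {}, {}, []
    for c in table.classes:
        tprs, fprs = [], []
        for g in table.groups:
            pos = table.n_cg[(c, g)]
            neg = table.n_g[g] - pos
            if pos >= min_support:
                tprs.append(table.tp_cg[(c, g)] / pos)
            if neg >= min_support:
                fprs.append(table.fp_cg[(c, g)] / neg)
        if len(tprs) < 2:
            tpr_gaps[c] = 0.0
            excluded.append((c, "tpr"))
        else:
            tpr_gaps[c] = _spread(tprs, aggregation)
        if len(fprs) < 2:
            fpr_gaps[c] = 0.0
            excluded.append((c, "fpr"))
        else:
            fpr_gaps[c] = _spread(fprs, aggregation)
    macro_tpr = float(np.mean(list(tpr_gaps.values())))
    macro_fpr = float(np.mean(list(fpr_gaps.values())))
    return tpr_gaps, fpr_gaps, macro_tpr, macro_fpr, excluded


def stratified_performance(y_true: Sequence, y_pred: Sequence,
                           groups: Sequence) -> pd.DataFrame:
    """Macro precision/recall/F1 and accuracy within each protected group.

    Metrics are macro-averaged over the classes present (as truth or
    prediction) in the group; zero-division cells contribute 0.
    """
    y_true, y_pred, groups = (np.asarray(a).astype(str)
                              for a in (y_true, y_pred, groups))
    if not (len(y_true) == len(y_pred) == len(groups)):
        raise ValueError("y_true, y_pred and groups must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    rows = []
    for g in sorted(set(groups)):
        mask = groups == g
        yt, yp = y_true[mask], y_pred[mask]
        labels = sorted(set(yt) | set(yp))
        prec, rec, f1, _ = precision_recall_fscore_support(
            yt, yp, labels=labels, average="macro", zero_division=0)
        rows.append({
            "group": g,
            "n": int(mask.sum()),
            "macro_precision": float(prec),
            "macro_recall": float(rec),
            "macro_f1": float(f1),
            "accuracy": float(np.mean(yt == yp)),
        })
    return pd.DataFrame(rows).set_index("group")


@dataclass
class FairnessReport:
    """All fairness outputs for one prediction set."""

    dp_per_class: dict[str, float]
    dp_gap: float
    tpr_per_class: dict[str, float]
    fpr_per_class: dict[str, float]
    eo_tpr_gap: float
    eo_fpr_gap: float
    stratified: pd.DataFrame
    min_support: int
    aggregation: str
    excluded: list = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "dp_gap": self.dp_gap,
            "eo_tpr_gap": self.eo_tpr_gap,
            "eo_fpr_gap": self.eo_fpr_gap,
            "dp_per_class": self.dp_per_class,
            "tpr_per_class": self.tpr_per_class,
            "fpr_per_class": self.fpr_per_class,
            "min_support": self.min_support,
            "aggregation": self.aggregation,
            "excluded": [list(e) for e in self.excluded],
            "stratified": self.stratified.reset_index().to_dict(orient="records"),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def fairness_report(y_true: Sequence, y_pred: Sequence, groups: Sequence,
                    min_support: int = 1,
                    aggregation: str = "max_min") -> FairnessReport:
    """Compute the full fairness report for one prediction set."""
    table = build_table(y_true, y_pred, groups)
    dp_per_class, dp_gap = demographic_parity_gap(table, min_support, aggregation)
    tpr, fpr, macro_tpr, macro_fpr, excl = equal_opportunity_gaps(
        table, min_support, aggregation)
    strat = stratified_performance(y_true, y_pred, groups)
    return FairnessReport(
        dp_per_class=dp_per_class,
        dp_gap=dp_gap,
        tpr_per_class=tpr,
        fpr_per_class=fpr,
        eo_tpr_gap=macro_tpr,
        eo_fpr_gap=macro_fpr,
        stratified=strat,
        min_support=min_support,
        aggregation=aggregation,
        excluded=excl,
    )
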