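"""Post-training feature pruning and threshold-sweep sensitivity analysis.

Pruning here means removing embedding columns and fully retraining the
downstream models — not zeroing importances or shuffling values — so the
comparison measures what the models can do without the suspect dimensions.

The sweep progressively prunes overlap dimensions ranked by their importance
in the demographic (race) model: for a target level L (a fraction of total
race-model importance mass), the pruned set is the shortest prefix whose
cumulative race importance reaches min(L, total overlap mass).  Levels above
the available overlap mass are capped at the full overlap set and annotated,
mirroring the common situation where the overlap's CFI sits below the audit
threshold.  Distinct pruned sets are retrained exactly once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .cohort import EmbeddingCohort
from .fairness import FairnessReport, fairness_report
from .models import ImportanceVector, SplitIndices, TrainedModel, train_multiclass

DEFAULT_SWEEP_LEVELS: tuple[float, ...] = tuple(
    round(0.05 + 0.01 * i, 2) for i in range(11))  # 5% .. 15% in 1% steps


def prune_features(cohort: EmbeddingCohort, dims: Iterable[str]) -> EmbeddingCohort:
    """Return a cohort without the listed embedding columns.

    Labels are untouched and surviving columns keep their original names, so
    a dimension means the same thing before and after pruning.
    """
    dims = set(dims)
    unknown = dims - set(cohort.feature_names)
    if unknown:
        raise KeyError(f"unknown dimensions: {sorted(unknown)}")
    keep = [j for j, name in enumerate(cohort.feature_names) if name not in dims]
    if not keep:
        raise ValueError("pruning all dimensions would leave an empty matrix")
    return EmbeddingCohort(
        X=cohort.X[:, keep],
        site=cohort.site,
        race=cohort.race,
        record_id=cohort.record_id,
        feature_names=tuple(cohort.feature_names[j] for j in keep),
    )


@dataclass
class ModelEvaluation:
    """Held-out site metrics (plus fairness) for one trained cohort state."""

    site_model: TrainedModel
    race_model: TrainedModel | None
    accuracy: float
    macro_f1: float
    race_accuracy: float | None
    fairness: FairnessReport
    y_pred: np.ndarray


def train_and_evaluate(cohort: EmbeddingCohort, split: SplitIndices,
                       params: Mapping | None = None, seed: int = 0,
                       train_race: bool = True, min_support: int = 1,
                       aggregation: str = "max_min") -> ModelEvaluation:
    """Train site (and optionally race) models on one split and score them."""
    tr, te = split.train_idx, split.test_idx
    site_model = train_multiclass(
        cohort.X[tr], cohort.site[tr], params=params, seed=seed,
        feature_names=cohort.feature_names, target_kind="site")
    y_pred = site_model.predict(cohort.X[te])
    y_true = cohort.site[te]
    race_model = None
    race_acc = None
    if train_race:
        race_model = train_multiclass(
            cohort.X[tr], cohort.race[tr], params=params, seed=seed,
            feature_names=cohort.feature_names, target_kind="race")
        race_acc = race_model.accuracy(cohort.X[te], cohort.race[te])
    fr = fairness_report(y_true, y_pred, cohort.race[te],
                         min_support=min_support, aggregation=aggregation)
    return ModelEvaluation(
        site_model=site_model,
        race_model=race_model,
        accuracy=float(np.mean(y_pred == y_true)),
        macro_f1=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        race_accuracy=race_acc,
        fairness=fr,
        y_pred=y_pred,
    )


def prune_retrain_compare(cohort: EmbeddingCohort, dims: Iterable[str],
                          split: SplitIndices, params: Mapping | None = None,
                          seed: int = 0, train_race: bool = True,
                          min_support: int = 1,
                          aggregation: str = "max_min"
                          ) -> dict[str, ModelEvaluation]:
    """Before/after comparison for pruning ``dims`` and retraining.

    Both states use the same split and seed so the comparison isolates the
    effect of the removed columns.
    """
    dims = list(dims)
    if not dims:
        raise ValueError("dims must be nonempty; use train_and_evaluate for a baseline")
    before = train_and_evaluate(cohort, split, params, seed, train_race,
                                min_support, aggregation)
    pruned = prune_features(cohort, dims)
    after = train_and_evaluate(pruned, split, params, seed, train_race,
                               min_support, aggregation)
    return {"before": before, "after": after}


@dataclass
class SweepRow:
    level: float
    pruned_dims: tuple[str, ...]
    n_pruned: int
    capped: bool
    accuracy: float
    macro_f1: float
    dp_gap: float
    eo_tpr_gap: float
    eo_fpr_gap: float


@dataclass
class SweepResult:
    """Rows of the pruning-threshold sweep, baseline (level 0) first."""

    rows: list[SweepRow]
    n_retrains: int
    overlap_mass: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "level": r.level,
            "n_pruned": r.n_pruned,
            "capped": r.capped,
            "accuracy": r.accuracy,
            "macro_f1": r.macro_f1,
            "dp_gap": r.dp_gap,
            "eo_tpr_gap": r.eo_tpr_gap,
            "eo_fpr_gap": r.eo_fpr_gap,
            "pruned_dims": ";".join(r.pruned_dims),
        } for r in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "overlap_mass": self.overlap_mass,
            "n_retrains": self.n_retrains,
            "rows": self.to_frame().to_dict(orient="records"),
        }, indent=2))


def rank_by_race_importance(overlap: Iterable[str],
                            race_imp: ImportanceVector) -> list[str]:
    """Overlap dims by descending race importance, ties by ascending index."""
    return sorted(overlap,
                  key=lambda f: (-race_imp[f], race_imp.feature_names.index(f)))


def pruned_prefix_for_level(overlap_ranked: Sequence[str],
                            race_imp: ImportanceVector,
                            level: float) -> tuple[tuple[str, ...], bool]:
    """Shortest ranked prefix reaching min(level, total overlap mass).

    Returns the prefix and whether the level was capped by the available
    overlap mass.
    """
    masses = np.array([race_imp[f] for f in overlap_ranked])
    total = float(masses.sum())
    capped = level > total + 1e-12
    target = min(level, total)
    cum = np.cumsum(masses)
    n_take = int(np.searchsorted(cum, target - 1e-12) + 1)
    n_take = min(n_take, len(overlap_ranked))
    return tuple(overlap_ranked[:n_take]), capped


def threshold_sweep(cohort: EmbeddingCohort, race_imp: ImportanceVector,
                    overlap: Iterable[str], split: SplitIndices,
                    levels: Sequence[float] = DEFAULT_SWEEP_LEVELS,
                    params: Mapping | None = None, seed: int = 0,
                    min_support: int = 1,
                    aggregation: str = "max_min") -> SweepResult:
    """Run the pruning sweep over ``levels`` (ascending fractions in (0, 1])."""
    levels = list(levels)
    if levels != sorted(levels) or any(not (0 < l <= 1) for l in levels):
        raise ValueError("levels must be ascending fractions in (0, 1]")
    overlap = list(overlap)
    n_retrains = 0
    cache: dict[tuple[str, ...], ModelEvaluation] = {}

    def evaluate(pruned_dims: tuple[str, ...]) -> ModelEvaluation:
        nonlocal n_retrains
        if pruned_dims not in cache:
            data = prune_features(cohort, pruned_dims) if pruned_dims else cohort
            cache[pruned_dims] = train_and_evaluate(
                data, split, params, seed, train_race=False,
                min_support=min_support, aggregation=aggregation)
            n_retrains += 1
        return cache[pruned_dims]

    def row(level: float, pruned: tuple[str, ...], capped: bool) -> SweepRow:
        ev = evaluate(pruned)
        return SweepRow(
            level=level, pruned_dims=pruned, n_pruned=len(pruned), capped=capped,
            accuracy=ev.accuracy, macro_f1=ev.macro_f1,
            dp_gap=ev.fairness.dp_gap, eo_tpr_gap=ev.fairness.eo_tpr_gap,
            eo_fpr_gap=ev.fairness.eo_fpr_gap)

    rows = [row(0.0, (), False)]
    if not overlap:
        warnings.warn("empty overlap set: sweep returns the baseline row only")
        return SweepResult(rows=rows, n_retrains=n_retrains, overlap_mass=0.0)

    ranked = rank_by_race_importance(overlap, race_imp)
    total_mass = float(sum(race_imp[f] for f in ranked))
    for level in levels:
        pruned, capped = pruned_prefix_for_level(ranked, race_imp, level)
        rows.append(row(level, pruned, capped))
    return SweepResult(rows=rows, n_retrains=n_retrains, overlap_mass=total_mass)
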