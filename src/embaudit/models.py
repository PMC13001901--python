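"""Tree-ensemble classifiers on shared embeddings and gain-based importance.

Both the outcome (cancer-site) model and the demographic (race) model are
gradient-boosted decision trees trained on the same embedding matrix with a
stratified 70/30 split and a multiclass log-loss objective.  Per-feature
importance is the gain summed over all trees, normalized to total 1 per
model; the audit statistics downstream only ever use sums and comparisons of
these normalized scores, so the per-tree averaging constant of the raw gain
definition cancels.

Training is configured for reproducibility: single-threaded histogram tree
construction with a fixed seed gives identical models, predictions and
importances for identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import xgboost as xgb

#: Default hyperparameters.  Deliberately plain: the audit's statistics are
#: about importance structure, not squeezing out accuracy.
DEFAULT_PARAMS: dict = {
    "max_depth": 6,
    "n_estimators": 200,
    "learning_rate": 0.1,
}


@dataclass(frozen=True)
class ImportanceVector:
    """Normalized per-feature importance of one trained model.

    ``values[i]`` is the share of total across-tree gain attributed to
    ``feature_names[i]``; entries are nonnegative and sum to 1.  Features the
    booster never split on have importance exactly 0.
    """

    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.feature_names),):
            raise ValueError("values must align with feature_names")
        if (v < 0).any():
            raise ValueError("importances must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("importances must sum to 1")
        object.__setattr__(self, "values", v)

    def __getitem__(self, feature: str) -> float:
        try:
            return float(self.values[self.feature_names.index(feature)])
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.values.tolist()))


@dataclass(frozen=True)
class SplitIndices:
    """A stratified train/test partition of record indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    stratify_label: str

    def __post_init__(self):
        tr, te = np.asarray(self.train_idx), np.asarray(self.test_idx)
        if np.intersect1d(tr, te).size:
            raise ValueError("train and test indices overlap")
        object.__setattr__(self, "train_idx", tr)
        object.__setattr__(self, "test_idx", te)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "stratify_label": self.stratify_label,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitIndices":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["train_idx"]), np.array(d["test_idx"]),
                   d["stratify_label"])


def stratified_split(labels: Sequence, train_frac: float = 0.7, seed: int = 0,
                     stratify_label: str = "site") -> SplitIndices:
    """Stratified train/test split preserving class proportions.

    Per-class train counts use largest-remainder rounding: each class
    contributes floor(train_frac * count), and the remaining slots (to reach
    round(train_frac * n) in total) go to the classes with the largest
    fractional remainders, ties broken by class label order.  Every class
    keeps at least one record on each side.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie strictly between 0 and 1")
    classes, counts = np.unique(labels, return_counts=True)
    singletons = classes[counts < 2]
    if singletons.size:
        raise ValueError(
            f"classes with fewer than 2 records cannot be split: {singletons.tolist()}"
        )
    n = len(labels)
    quota = train_frac * counts
    base = np.floor(quota).astype(int)
    # every class keeps >=1 record on each side
    base = np.clip(base, 1, counts - 1)
    target_total = int(round(train_frac * n))
    remainder = quota - np.floor(quota)
    order = np.lexsort((np.arange(len(classes)), -remainder))
    alloc = base.copy()
    extra = target_total - int(base.sum())
    if extra > 0:
        for idx in order:
            if extra == 0:
                break
            if alloc[idx] < counts[idx] - 1:
                alloc[idx] += 1
                extra -= 1
    elif extra < 0:  # clipping to >=1 per class overshot the target
        for idx in order[::-1]:
            if extra == 0:
                break
            if alloc[idx] > 1:
                alloc[idx] -= 1
                extra += 1

    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls_label, n_train in zip(classes, alloc):
        members = np.flatnonzero(labels == cls_label)
        perm = rng.permutation(members)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return SplitIndices(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        stratify_label=stratify_label,
    )


@dataclass
class TrainedModel:
    """A fitted tree-ensemble classifier plus its normalized importance."""

    model: xgb.XGBClassifier
    target_kind: str                  # "site" | "race" | "binary_site"
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    importance: ImportanceVector

    def predict(self, X: np.ndarray) -> np.ndarray:
        enc = self.model.predict(np.asarray(X, dtype=float))
        return np.asarray(self.classes, dtype=object)[enc].astype(str)

    def accuracy(self, X: np.ndarray, y: Sequence) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def save(self, stem: str | Path) -> dict[str, Path]:
        """Persist as native booster JSON plus a metadata sidecar."""
        stem = Path(stem)
        booster_path = stem.with_suffix(".ubj.json")
        self.model.get_booster().save_model(booster_path)
        sidecar = stem.with_suffix(".meta.json")
        sidecar.write_text(json.dumps({
            "target_kind": self.target_kind,
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "importance": self.importance.values.tolist(),
        }, indent=2))
        return {"booster": booster_path, "sidecar": sidecar}

    @classmethod
    def load(cls, stem: str | Path) -> "TrainedModel":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".meta.json").read_text())
        clf = xgb.XGBClassifier()
        clf.load_model(stem.with_suffix(".ubj.json"))
        return cls(
            model=clf,
            target_kind=meta["target_kind"],
            classes=tuple(meta["classes"]),
            feature_names=tuple(meta["feature_names"]),
            importance=ImportanceVector(tuple(meta["feature_names"]),
                                        np.array(meta["importance"])),
        )


def _gain_importance(booster: xgb.Booster, n_features: int,
                     feature_names: tuple[str, ...]) -> ImportanceVector:
    raw = booster.get_score(importance_type="gain")
    values = np.zeros(n_features)
    for key, gain in raw.items():
        values[int(key.lstrip("f"))] = gain
    total = values.sum()
    if total > 0:
        values /= total
    else:  # no split anywhere (degenerate fit): fall back to uniform
        values[:] = 1.0 / n_features
    return ImportanceVector(feature_names, values)


def _fit(X: np.ndarray, y_enc: np.ndarray, n_classes: int,
         params: Mapping | None, seed: int) -> xgb.XGBClassifier:
    merged = dict(DEFAULT_PARAMS)
    if params:
        merged.update(params)
    if n_classes > 2:
        merged.setdefault("objective", "multi:softprob")
        merged.setdefault("eval_metric", "mlogloss")
    else:
        merged.setdefault("objective", "binary:logistic")
        merged.setdefault("eval_metric", "logloss")
    clf = xgb.XGBClassifier(
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **merged,
    )
    clf.fit(X, y_enc)
    return clf


def train_multiclass(X: np.ndarray, y: Sequence, params: Mapping | None = None,
                     seed: int = 0, feature_names: Sequence[str] | None = None,
                     target_kind: str = "site") -> TrainedModel:
    """Train a multiclass tree-ensemble classifier minimizing log-loss."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"need at least 2 classes, got only {classes.tolist()}")
    if feature_names is None:
        feature_names = tuple(f"dim_{j}" for j in range(X.shape[1]))
    else:
        feature_names = tuple(feature_names)
    lookup = {c: i for i, c in enumerate(classes)}
    y_enc = np.array([lookup[v] for v in y])
    clf = _fit(X, y_enc, len(classes), params, seed)
    imp = _gain_importance(clf.get_booster(), X.shape[1], feature_names)
    return TrainedModel(clf, target_kind, tuple(str(c) for c in classes),
                        feature_names, imp)


def train_binary_site(X: np.ndarray, y_site: Sequence, target_site: str,
                      params: Mapping | None = None, seed: int = 0,
                      feature_names: Sequence[str] | None = None) -> TrainedModel:
    """Train a one-vs-rest binary model for one cancer site.

    Mirrors the per-cancer analyses (breast, lung, colon, ovarian, prostate):
    records of ``target_site`` against all other cancers, on the same
    embeddings as the multiclass models.
    """
    y_site = np.asarray(y_site)
    if target_site not in set(y_site):
        raise ValueError(f"target site {target_site!r} absent from labels")
    y_bin = np.where(y_site == target_site, target_site, "rest")
    if len(np.unique(y_bin)) < 2:
        raise ValueError(f"target site {target_site!r} is the only class present")
    return train_multiclass(X, y_bin, params=params, seed=seed,
                            feature_names=feature_names,
                            target_kind="binary_site")
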