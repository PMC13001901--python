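"""Feature-overlap and cumulative-importance statistics for model pairs.

The audit asks whether an outcome model and a demographic model trained on
the same embeddings lean on the same dimensions: the top-k (default 50)
features of each are intersected, and the cumulative feature importance
(CFI) of the intersection is computed in each model.  A pair is flagged when
the overlap's CFI in the demographic model strictly exceeds a threshold
(default 10% of that model's total importance mass).

Importance scores are normalized per model (sum 1), so CFIs lie in [0, 1]
and the percentage threshold is well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .models import ImportanceVector, TrainedModel

DEFAULT_TOP_K = 50
DEFAULT_CFI_THRESHOLD = 0.10


def top_k_features(imp: ImportanceVector, k: int) -> list[str]:
    """The k most important features, descending; ties by ascending index."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(imp.feature_names):
        raise ValueError(f"k={k} exceeds the {len(imp.feature_names)} features")
    order = sorted(range(len(imp.feature_names)),
                   key=lambda i: (-imp.values[i], i))
    return [imp.feature_names[i] for i in order[:k]]


def overlap_set(f1: Iterable[str], f2: Iterable[str]) -> set[str]:
    """Exact intersection of two significant-feature sets."""
    return set(f1) & set(f2)


def cumulative_importance(f_overlap: Iterable[str], imp: ImportanceVector) -> float:
    """Sum of the model's importance scores over the overlap set; in [0, 1]."""
    f_overlap = set(f_overlap)
    unknown = f_overlap - set(imp.feature_names)
    if unknown:
        raise KeyError(f"features not in the importance domain: {sorted(unknown)}")
    return float(sum(imp[f] for f in f_overlap))


@dataclass(frozen=True)
class OverlapAuditReport:
    """Overlap statistics for one (outcome model, demographic model) pair.

    ``flagged`` is True when the overlap's cumulative importance in the
    demographic model (model 2) strictly exceeds ``threshold``.
    """

    model1_id: str
    model2_id: str
    k: int
    f1: tuple[str, ...]
    f2: tuple[str, ...]
    f_overlap: tuple[str, ...]
    cfi_model1: float
    cfi_model2: float
    threshold: float
    flagged: bool

    @property
    def overlap_count(self) -> int:
        return len(self.f_overlap)

    #: Header of the tabular report emitted for each audited pair.
    CSV_HEADER = ("Model 1,Model 2,No. of Overlapping Features,"
                  "Cumulative Importance in Model 1,Cumulative Importance in Model 2")

    def to_csv_row(self) -> str:
        return (f"{self.model1_id},{self.model2_id},{self.overlap_count},"
                f"{self.cfi_model1:.4f},{self.cfi_model2:.4f}")

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "model1_id": self.model1_id,
            "model2_id": self.model2_id,
            "k": self.k,
            "overlap_count": self.overlap_count,
            "f_overlap": list(self.f_overlap),
            "cfi_model1": self.cfi_model1,
            "cfi_model2": self.cfi_model2,
            "threshold": self.threshold,
            "flagged": self.flagged,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def audit_pair(m1: TrainedModel, m2: TrainedModel,
               k: int = DEFAULT_TOP_K,
               threshold: float = DEFAULT_CFI_THRESHOLD,
               model1_id: str | None = None,
               model2_id: str | None = None) -> OverlapAuditReport:
    """Audit a model pair: top-k overlap plus CFI in each model.

    Model 2 is the demographic model; the flag applies to its CFI.
    """
    if m1.feature_names != m2.feature_names:
        raise ValueError("models were trained on different feature domains")
    f1 = top_k_features(m1.importance, k)
    f2 = top_k_features(m2.importance, k)
    shared = overlap_set(f1, f2)
    ordered = tuple(sorted(shared, key=m1.feature_names.index))
    cfi1 = cumulative_importance(shared, m1.importance)
    cfi2 = cumulative_importance(shared, m2.importance)
    return OverlapAuditReport(
        model1_id=model1_id or m1.target_kind,
        model2_id=model2_id or m2.target_kind,
        k=k,
        f1=tuple(f1),
        f2=tuple(f2),
        f_overlap=ordered,
        cfi_model1=cfi1,
        cfi_model2=cfi2,
        threshold=threshold,
        flagged=cfi2 > threshold,
    )
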