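"""High-level Model/Results interface for the embedding bias audit.

`EmbeddingBiasAudit` is constructed from an :class:`~embaudit.cohort.EmbeddingCohort`
(or a pair of dataframes); ``fit()`` trains the outcome and demographic
models on one shared stratified split and returns a
:class:`BiasAuditResults` carrying the overlap audit, fairness report and
held-out performance, with ``summary()``, ``prune_and_refit()``,
``threshold_sweep()`` and ``plot_importance()`` hanging off the results.

Example
-------
>>> from embaudit import SyntheticConfig, generate_cohort, EmbeddingBiasAudit
>>> cfg = SyntheticConfig(n_records=2000, n_dims=40, n_sites=4,
...                       site_dims=range(0, 8), race_dims=range(6, 14),
...                       beta_site=2.0, beta_race=2.0, seed=7)
>>> cohort, truth = generate_cohort(cfg)
>>> res = EmbeddingBiasAudit(cohort, seed=7).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .audit import (DEFAULT_CFI_THRESHOLD, DEFAULT_TOP_K, OverlapAuditReport,
                    audit_pair)
from .cohort import EmbeddingCohort
from .fairness import FairnessReport
from .models import SplitIndices, TrainedModel, stratified_split, train_binary_site
from .pruning import (ModelEvaluation, SweepResult, prune_features,
                      threshold_sweep, train_and_evaluate)


class EmbeddingBiasAudit:
    """Dual outcome/demographic classifier audit on shared embeddings.

    Parameters
    ----------
    cohort : EmbeddingCohort
        Embedding matrix plus site and race labels.
    params : mapping, optional
        Tree-ensemble hyperparameter overrides shared by all models.
    k : int
        Top-k cutoff for the overlap analysis (default 50).
    threshold : float
        CFI flag threshold on the demographic model (default 0.10).
    train_frac, seed : split configuration.  One shared split stratified by
        the site label is used for both models, so fairness metrics are
        computed on a single common test set.
    binary_sites : sequence of site labels, optional
        Sites for which additional one-vs-rest models are audited.
    """

    def __init__(self, cohort: EmbeddingCohort, params: Mapping | None = None,
                 k: int = DEFAULT_TOP_K, threshold: float = DEFAULT_CFI_THRESHOLD,
                 train_frac: float = 0.7, seed: int = 0,
                 min_support: int = 1, aggregation: str = "max_min",
                 binary_sites: Sequence[str] = ()):
        self.cohort = cohort
        self.params = dict(params) if params else None
        self.k = k
        self.threshold = threshold
        self.train_frac = train_frac
        self.seed = seed
        self.min_support = min_support
        self.aggregation = aggregation
        self.binary_sites = tuple(binary_sites)

    @classmethod
    def from_dataframes(cls, embeddings: pd.DataFrame, labels: pd.DataFrame,
                        **kwargs) -> "EmbeddingBiasAudit":
        """Build from an embeddings frame and a (record_id, site, race) frame."""
        cohort = EmbeddingCohort(
            X=embeddings.to_numpy(dtype=float),
            site=labels["site"].to_numpy().astype(str),
            race=labels["race"].to_numpy().astype(str),
            record_id=labels["record_id"].to_numpy().astype(str),
            feature_names=tuple(embeddings.columns),
        )
        return cls(cohort, **kwargs)

    def fit(self) -> "BiasAuditResults":
        split = stratified_split(self.cohort.site, self.train_frac, self.seed,
                                 stratify_label="site")
        evaluation = train_and_evaluate(
            self.cohort, split, self.params, self.seed, train_race=True,
            min_support=self.min_support, aggregation=self.aggregation)
        site_model = evaluation.site_model
        race_model = evaluation.race_model
        overlap = audit_pair(site_model, race_model, self.k, self.threshold,
                             model1_id="Site", model2_id="Race")
        binary_reports = {}
        binary_models = {}
        tr = split.train_idx
        for target in self.binary_sites:
            bm = train_binary_site(self.cohort.X[tr], self.cohort.site[tr],
                                   target, params=self.params, seed=self.seed,
                                   feature_names=self.cohort.feature_names)
            binary_models[target] = bm
            binary_reports[target] = audit_pair(
                bm, race_model, self.k, self.threshold,
                model1_id=target, model2_id="Race")
        return BiasAuditResults(
            model=self, split=split, evaluation=evaluation,
            site_model=site_model, race_model=race_model,
            overlap_report=overlap, binary_models=binary_models,
            binary_reports=binary_reports)


@dataclass
class BiasAuditResults:
    """Fitted audit: trained models, overlap statistics and fairness."""

    model: EmbeddingBiasAudit
    split: SplitIndices
    evaluation: ModelEvaluation
    site_model: TrainedModel
    race_model: TrainedModel
    overlap_report: OverlapAuditReport
    binary_models: dict[str, TrainedModel] = field(default_factory=dict)
    binary_reports: dict[str, OverlapAuditReport] = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    @property
    def accuracy(self) -> float:
        return self.evaluation.accuracy

    @property
    def macro_f1(self) -> float:
        return self.evaluation.macro_f1

    @property
    def race_accuracy(self) -> float:
        return self.evaluation.race_accuracy

    @property
    def fairness(self) -> FairnessReport:
        return self.evaluation.fairness

    @property
    def overlap_dims(self) -> tuple[str, ...]:
        return self.overlap_report.f_overlap

    def audit_table(self) -> pd.DataFrame:
        """All pair audits in the standard report layout."""
        reports = [self.overlap_report, *self.binary_reports.values()]
        return pd.DataFrame([{
            "Model 1": r.model1_id,
            "Model 2": r.model2_id,
            "No. of Overlapping Features": r.overlap_count,
            "Cumulative Importance in Model 1": round(r.cfi_model1, 4),
            "Cumulative Importance in Model 2": round(r.cfi_model2, 4),
        } for r in reports])

    # -- post-hoc analyses -----------------------------------------------
    def prune_and_refit(self, dims: Sequence[str] | None = None) -> "BiasAuditResults":
        """Prune dimensions (default: the site/race overlap set) and refit.

        The same split indices and seed are reused so the before/after
        comparison isolates the effect of the removed columns.
        """
        dims = tuple(dims) if dims is not None else self.overlap_dims
        m = self.model
        pruned = prune_features(m.cohort, dims) if dims else m.cohort
        refit_model = EmbeddingBiasAudit(
            pruned, params=m.params, k=m.k, threshold=m.threshold,
            train_frac=m.train_frac, seed=m.seed, min_support=m.min_support,
            aggregation=m.aggregation, binary_sites=m.binary_sites)
        return refit_model.fit()

    def threshold_sweep(self, levels: Sequence[float] | None = None) -> SweepResult:
        """Sweep pruning levels over the overlap set ranked by race importance."""
        m = self.model
        kwargs = {} if levels is None else {"levels": levels}
        return threshold_sweep(
            m.cohort, self.race_model.importance, self.overlap_dims,
            self.split, params=m.params, seed=m.seed,
            min_support=m.min_support, aggregation=m.aggregation, **kwargs)

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        r = self.overlap_report
        lines = [
            "Embedding Bias Audit Results",
            "=" * 64,
            f"records: {self.model.cohort.n_records}   "
            f"dims: {len(self.model.cohort.feature_names)}   "
            f"top-k: {r.k}   threshold: {r.threshold:.2f}",
            "-" * 64,
            f"site model   accuracy: {self.accuracy:.4f}   macro-F1: {self.macro_f1:.4f}",
            f"race model   accuracy: {self.race_accuracy:.4f}",
            "-" * 64,
            f"overlapping features (|top{r.k}(site) ∩ top{r.k}(race)|): {r.overlap_count}",
            f"cumulative importance in site model: {r.cfi_model1:.4f}",
            f"cumulative importance in race model: {r.cfi_model2:.4f}",
            f"flagged (race CFI > {r.threshold:.0%}): {r.flagged}",
            "-" * 64,
            f"demographic parity gap: {self.fairness.dp_gap:.4f}",
            f"equal-opportunity TPR gap: {self.fairness.eo_tpr_gap:.4f}",
            f"equal-opportunity FPR gap: {self.fairness.eo_fpr_gap:.4f}",
        ]
        if self.binary_reports:
            lines.append("-" * 64)
            lines.append("binary site models vs race model:")
            for name, rep in self.binary_reports.items():
                lines.append(f"  {name}: overlap {rep.overlap_count}, "
                             f"CFI {rep.cfi_model1:.4f} / {rep.cfi_model2:.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_importance(self, which: str = "site", ax=None, log: bool = True):
        """Bar plot of feature importances, overlap dims highlighted.

        Parameters
        ----------
        which : "site" or "race"
        log : plot the y axis on a log scale (importances span decades).
        """
        import matplotlib.pyplot as plt

        model = self.site_model if which == "site" else self.race_model
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        imp = model.importance
        x = np.arange(len(imp.feature_names))
        overlap = set(self.overlap_dims)
        colors = ["red" if f in overlap else "steelblue" for f in imp.feature_names]
        ax.bar(x, np.maximum(imp.values, 1e-12), color=colors, width=1.0)
        if log:
            ax.set_yscale("log")
        ax.set_xlabel("feature index")
        ax.set_ylabel("importance")
        ax.set_title(f"{which} model feature importance (overlap in red)")
        return ax
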