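"""End-to-end reproducible audit runs: config, staging, reports, manifest.

``run_full_audit`` executes simulate → split → train (site, race, binary
site models) → pair audits → prune overlap → retrain → post-pruning audits →
threshold sweep → fairness reports, writing every artifact into one run
directory together with the exact config used, so a run can be reproduced
byte-for-byte from its directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import sklearn
import xgboost
import yaml

from .audit import OverlapAuditReport, audit_pair
from .cohort import SyntheticConfig, generate_cohort
from .model import EmbeddingBiasAudit
from .pruning import DEFAULT_SWEEP_LEVELS

logger = logging.getLogger("embaudit")


@dataclass
class PipelineConfig:
    """Serializable configuration for one full audit run."""

    synthetic: dict
    seed: int
    model_params: dict = field(default_factory=dict)
    k: int = 50
    threshold: float = 0.10
    train_frac: float = 0.7
    levels: list = field(default_factory=lambda: list(DEFAULT_SWEEP_LEVELS))
    min_support: int = 1
    aggregation: str = "max_min"
    n_binary_sites: int = 5
    cohort_format: str = "csv"

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("config must specify a seed")
        if "synthetic" not in d:
            raise ValueError("config must specify a synthetic block")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "synthetic": dict(self.synthetic),
            "seed": self.seed,
            "model_params": dict(self.model_params),
            "k": self.k,
            "threshold": self.threshold,
            "train_frac": self.train_frac,
            "levels": list(self.levels),
            "min_support": self.min_support,
            "aggregation": self.aggregation,
            "n_binary_sites": self.n_binary_sites,
            "cohort_format": self.cohort_format,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of a completed (or aborted) pipeline run."""

    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    completed_stages: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "outputs": self.outputs,
            "versions": self.versions,
            "started": self.started,
            "finished": self.finished,
            "completed_stages": self.completed_stages,
        }, indent=2))

    def validate(self) -> None:
        missing = [k for k, p in self.outputs.items() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")


def _write_audit_csv(path: Path, reports: list[OverlapAuditReport]) -> None:
    header = OverlapAuditReport.CSV_HEADER
    lines = [header] + [r.to_csv_row() for r in reports]
    path.write_text("\n".join(lines) + "\n")


def run_full_audit(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Run the whole audit pipeline into ``out_dir`` and return its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest = RunManifest(
        config_hash=chash, seed=config.seed, started=time.time(),
        versions={
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        })
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest.outputs["config"] = str(out / "config.yaml")

    stage = "simulate"
    try:
        logger.info("stage=%s seed=%d config=%s", stage, config.seed, chash)
        syn = SyntheticConfig(**{**config.synthetic, "seed": config.seed})
        cohort, truth = generate_cohort(syn)
        paths = cohort.write(out / "cohort", fmt=config.cohort_format)
        truth.to_json(out / "cohort" / "ground_truth.json")
        manifest.outputs["embeddings"] = str(paths["embeddings"])
        manifest.outputs["labels"] = str(paths["labels"])
        manifest.outputs["ground_truth"] = str(out / "cohort" / "ground_truth.json")
        manifest.completed_stages.append(stage)

        stage = "fit"
        logger.info("stage=%s seed=%d config=%s", stage, config.seed, chash)
        site_counts = pd.Series(cohort.site).value_counts()
        binary_sites = tuple(site_counts.index[:config.n_binary_sites])
        audit_model = EmbeddingBiasAudit(
            cohort, params=config.model_params or None, k=config.k,
            threshold=config.threshold, train_frac=config.train_frac,
            seed=config.seed, min_support=config.min_support,
            aggregation=config.aggregation, binary_sites=binary_sites)
        results = audit_model.fit()
        results.split.to_json(out / "split.json")
        results.site_model.save(out / "site_model")
        results.race_model.save(out / "race_model")
        for name, bm in results.binary_models.items():
            bm.save(out / f"binary_{name}")
        manifest.outputs["split"] = str(out / "split.json")
        manifest.completed_stages.append(stage)

        stage = "audit"
        logger.info("stage=%s seed=%d config=%s", stage, config.seed, chash)
        pre_reports = [results.overlap_report, *results.binary_reports.values()]
        _write_audit_csv(out / "overlap_pre_pruning.csv", pre_reports)
        results.fairness.to_json(out / "fairness_pre_pruning.json")
        manifest.outputs["overlap_pre_pruning"] = str(out / "overlap_pre_pruning.csv")
        manifest.outputs["fairness_pre_pruning"] = str(out / "fairness_pre_pruning.json")
        manifest.completed_stages.append(stage)

        stage = "prune"
        logger.info("stage=%s seed=%d config=%s", stage, config.seed, chash)
        if results.overlap_dims:
            pruned_results = results.prune_and_refit()
            post_reports = [pruned_results.overlap_report,
                            *pruned_results.binary_reports.values()]
            _write_audit_csv(out / "overlap_post_pruning.csv", post_reports)
            pruned_results.fairness.to_json(out / "fairness_post_pruning.json")
            manifest.outputs["overlap_post_pruning"] = str(out / "overlap_post_pruning.csv")
            manifest.outputs["fairness_post_pruning"] = str(out / "fairness_post_pruning.json")
        manifest.completed_stages.append(stage)

        stage = "sweep"
        logger.info("stage=%s seed=%d config=%s", stage, config.seed, chash)
        sweep = results.threshold_sweep(levels=config.levels)
        sweep.to_csv(out / "sweep.csv")
        sweep.to_json(out / "sweep.json")
        manifest.outputs["sweep_csv"] = str(out / "sweep.csv")
        manifest.outputs["sweep_json"] = str(out / "sweep.json")
        manifest.completed_stages.append(stage)
    except Exception as exc:
        manifest.finished = time.time()
        manifest.to_json(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.time()
    manifest.to_json(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    manifest.validate()
    return manifest
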