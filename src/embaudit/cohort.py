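"""Synthetic embedding cohorts with planted outcome and demographic signal.

Real pathology-report embeddings from population cancer registries cannot be
redistributed, so every downstream audit stage in this package is exercised
against cohorts generated here.  The generator plants independently tunable
cancer-site and race signal in chosen embedding dimensions, so that the
"ground truth" of which dimensions leak demographic information is known and
recoverable — the property the audit is supposed to detect.

The generative model is a deliberate stand-in: nothing is known about the
distribution of real attention-network document embeddings, and none of the
distributional choices below (Gaussian class templates, additive noise)
should be read as a claim about real embeddings.  See docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The seven race/ethnicity categories used throughout, in canonical order.
RACE_CATEGORIES: tuple[str, ...] = (
    "White", "Black", "Asian", "Island", "Native", "Other", "Unknown",
)

#: Registry report counts by race for the cohort whose marginal the default
#: synthetic race distribution emulates (3,514,324 reports in total).
REGISTRY_RACE_COUNTS: dict[str, int] = {
    "White": 2_957_901,
    "Black": 361_738,
    "Asian": 123_877,
    "Island": 11_108,
    "Native": 19_295,
    "Other": 7_932,
    "Unknown": 32_473,
}

# One-decimal percentages as printed in the registry sample description.
_PRINTED_RACE_PCT: dict[str, float] = {
    "White": 84.2, "Black": 10.3, "Asian": 3.5, "Island": 0.3,
    "Native": 0.5, "Other": 0.2, "Unknown": 0.9,
}


def registry_race_percentages() -> dict[str, float]:
    """Exact race percentages computed from the registry report counts."""
    total = sum(REGISTRY_RACE_COUNTS.values())
    return {r: 100.0 * c / total for r, c in REGISTRY_RACE_COUNTS.items()}


def default_race_marginal() -> np.ndarray:
    """Default race probability vector over :data:`RACE_CATEGORIES`.

    The printed one-decimal percentages (84.2, 10.3, ...) sum to 99.9 due to
    rounding; the vector is renormalized to sum exactly 1.
    """
    p = np.array([_PRINTED_RACE_PCT[r] for r in RACE_CATEGORIES], dtype=float)
    p /= 100.0
    return p / p.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic embedding cohort.

    Parameters
    ----------
    n_records : int
        Cohort size; must be at least ``10 * n_sites`` so that a stratified
        70/30 split leaves usable per-class counts.
    n_dims : int
        Embedding dimensionality D (default 400, matching the document
        embeddings the audit was designed around).
    n_sites : int
        Number of cancer-site classes (2–70).
    race_probs : array-like of length 7, optional
        Race marginal; defaults to :func:`default_race_marginal`.
    site_dims, race_dims : sequence of int
        Dimensions carrying site / race signal.  Their intersection is the
        planted overlap set.
    beta_site, beta_race : float
        Nonnegative effect sizes scaling the planted class templates.
    noise_sd : float
        Standard deviation of the iid Gaussian noise on every dimension.
    confounding : float in [0, 1]
        0 makes site independent of race; 1 gives each race its own site
        distribution.  Interpolates linearly between the two.
    site_skew : float
        Exponent of the power-law site class weights (0 = balanced); mimics
        the heavy class imbalance of registry site labels.
    seed : int
        Master seed, split into independent substreams for patterns, labels
        and noise, so changing ``n_records`` does not change the templates.
    """

    n_records: int
    n_dims: int = 400
    n_sites: int = 10
    race_probs: Sequence[float] | None = None
    site_dims: tuple[int, ...] = ()
    race_dims: tuple[int, ...] = ()
    beta_site: float = 1.0
    beta_race: float = 1.0
    noise_sd: float = 1.0
    confounding: float = 0.0
    site_skew: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "site_dims", tuple(sorted(set(self.site_dims))))
        object.__setattr__(self, "race_dims", tuple(sorted(set(self.race_dims))))
        if self.race_probs is not None:
            object.__setattr__(self, "race_probs", tuple(float(x) for x in self.race_probs))

    @property
    def overlap_dims(self) -> tuple[int, ...]:
        """Planted overlap: dimensions informative for both site and race."""
        return tuple(sorted(set(self.site_dims) & set(self.race_dims)))

    def resolved_race_probs(self) -> np.ndarray:
        if self.race_probs is None:
            return default_race_marginal()
        return np.asarray(self.race_probs, dtype=float)

    def validate(self) -> None:
        if self.n_records <= 0 or self.n_dims <= 0:
            raise ValueError("n_records and n_dims must be positive")
        if not (2 <= self.n_sites <= 70):
            raise ValueError("n_sites must be between 2 and 70")
        p = self.resolved_race_probs()
        if p.shape != (len(RACE_CATEGORIES),):
            raise ValueError("race_probs must have length 7")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("race_probs must be nonnegative and sum to 1")
        for name, dims in (("site_dims", self.site_dims), ("race_dims", self.race_dims)):
            if any(d < 0 or d >= self.n_dims for d in dims):
                raise ValueError(f"{name} out of range [0, {self.n_dims})")
        if not self.site_dims:
            raise ValueError("site_dims must be nonempty")
        if self.n_records < 10 * self.n_sites:
            raise ValueError(
                f"n_records={self.n_records} too small for {self.n_sites} site "
                f"classes (need at least {10 * self.n_sites} for a stratified split)"
            )
        if self.beta_site < 0 or self.beta_race < 0 or self.noise_sd <= 0:
            raise ValueError("effect sizes must be >=0 and noise_sd > 0")
        if not (0.0 <= self.confounding <= 1.0):
            raise ValueError("confounding must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["race_probs"] = list(self.resolved_race_probs())
        return d


@dataclass
class EmbeddingCohort:
    """An embedding matrix plus its label table — the shared model substrate."""

    X: np.ndarray                    # (n, D) float
    site: np.ndarray                 # (n,) str site labels
    race: np.ndarray                 # (n,) str race labels
    record_id: np.ndarray            # (n,) str identifiers
    feature_names: tuple[str, ...]   # length D, preserved under pruning

    def __post_init__(self):
        n, d = self.X.shape
        if not (len(self.site) == len(self.race) == len(self.record_id) == n):
            raise ValueError("label arrays must match the number of embedding rows")
        if len(self.feature_names) != d:
            raise ValueError("feature_names must match the number of columns")
        if not np.isfinite(self.X).all():
            raise ValueError("embedding matrix contains non-finite values")
        bad = set(np.unique(self.race)) - set(RACE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown race categories: {sorted(bad)}")

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    def embeddings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.feature_names))

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"record_id": self.record_id, "site": self.site, "race": self.race}
        )

    def write(self, directory: str | Path, fmt: str = "csv") -> dict[str, Path]:
        """Write embeddings and labels; returns the paths written."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        emb = self.embeddings_frame()
        if fmt == "parquet":
            emb_path = directory / "embeddings.parquet"
            emb.to_parquet(emb_path, index=False)
        elif fmt == "csv":
            emb_path = directory / "embeddings.csv"
            emb.to_csv(emb_path, index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        lab_path = directory / "labels.csv"
        self.labels_frame().to_csv(lab_path, index=False)
        return {"embeddings": emb_path, "labels": lab_path}

    @classmethod
    def read(cls, directory: str | Path) -> "EmbeddingCohort":
        directory = Path(directory)
        pq = directory / "embeddings.parquet"
        emb = pd.read_parquet(pq) if pq.exists() else pd.read_csv(directory / "embeddings.csv")
        lab = pd.read_csv(directory / "labels.csv", dtype=str)
        return cls(
            X=emb.to_numpy(dtype=float),
            site=lab["site"].to_numpy(),
            race=lab["race"].to_numpy(),
            record_id=lab["record_id"].to_numpy(),
            feature_names=tuple(emb.columns),
        )


@dataclass(frozen=True)
class GroundTruthSpec:
    """Which dimensions carry planted signal — the recovery target."""

    planted_site_dims: tuple[str, ...]
    planted_race_dims: tuple[str, ...]
    beta_site: float
    beta_race: float
    noise_sd: float

    @property
    def planted_overlap_dims(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.planted_site_dims) & set(self.planted_race_dims),
                            key=lambda s: int(s.split("_")[1])))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_site_dims": list(self.planted_site_dims),
            "planted_race_dims": list(self.planted_race_dims),
            "planted_overlap_dims": list(self.planted_overlap_dims),
            "beta_site": self.beta_site,
            "beta_race": self.beta_race,
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def site_class_weights(n_sites: int, skew: float) -> np.ndarray:
    """Power-law class weights w_k ∝ (k+1)^-skew, normalized."""
    w = (np.arange(1, n_sites + 1, dtype=float)) ** (-skew)
    return w / w.sum()


def generate_cohort(config: SyntheticConfig) -> tuple[EmbeddingCohort, GroundTruthSpec]:
    """Generate a cohort with planted site/race signal.

    Race is drawn from ``race_probs``; site from a mixture that interpolates
    (via ``confounding``) between one shared power-law distribution and
    race-specific distributions.  Embedding entry (i, d) is

        beta_site * mu[site_i, d] * [d in site_dims]
      + beta_race * nu[race_i, d] * [d in race_dims]
      + Normal(0, noise_sd^2)

    with class-template matrices mu, nu drawn once (iid standard normal) from
    a pattern substream independent of the label and noise substreams, so the
    templates do not change with ``n_records``.  Identical config gives
    bit-identical output.
    """
    config.validate()
    n, d_total = config.n_records, config.n_dims
    n_sites = config.n_sites
    race_probs = config.resolved_race_probs()

    ss = np.random.SeedSequence(config.seed)
    pat_ss, lab_ss, noise_ss = ss.spawn(3)
    rng_pat = np.random.default_rng(pat_ss)
    rng_lab = np.random.default_rng(lab_ss)
    rng_noise = np.random.default_rng(noise_ss)

    # Fixed class-by-dimension templates (full matrices; masked below).
    mu = rng_pat.standard_normal((n_sites, d_total))
    nu = rng_pat.standard_normal((len(RACE_CATEGORIES), d_total))
    # Race-specific site distributions for the confounding mixture.
    race_site_probs = rng_pat.dirichlet(np.ones(n_sites), size=len(RACE_CATEGORIES))

    race_idx = rng_lab.choice(len(RACE_CATEGORIES), size=n, p=race_probs)
    shared = site_class_weights(n_sites, config.site_skew)
    c = config.confounding
    site_idx = np.empty(n, dtype=int)
    for r in range(len(RACE_CATEGORIES)):
        mask = race_idx == r
        if not mask.any():
            continue
        p = (1.0 - c) * shared + c * race_site_probs[r]
        site_idx[mask] = rng_lab.choice(n_sites, size=int(mask.sum()), p=p)

    X = rng_noise.normal(0.0, config.noise_sd, size=(n, d_total))
    site_dims = np.array(config.site_dims, dtype=int)
    race_dims = np.array(config.race_dims, dtype=int)
    if site_dims.size:
        X[:, site_dims] += config.beta_site * mu[site_idx][:, site_dims]
    if race_dims.size:
        X[:, race_dims] += config.beta_race * nu[race_idx][:, race_dims]

    feature_names = tuple(f"dim_{j}" for j in range(d_total))
    site_labels = np.array([f"site{k:02d}" for k in range(n_sites)])
    race_labels = np.array(RACE_CATEGORIES)
    cohort = EmbeddingCohort(
        X=X,
        site=site_labels[site_idx],
        race=race_labels[race_idx],
        record_id=np.array([f"rec{i:07d}" for i in range(n)]),
        feature_names=feature_names,
    )
    truth = GroundTruthSpec(
        planted_site_dims=tuple(feature_names[j] for j in site_dims),
        planted_race_dims=tuple(feature_names[j] for j in race_dims),
        beta_site=config.beta_site,
        beta_race=config.beta_race,
        noise_sd=config.noise_sd,
    )
    return cohort, truth
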