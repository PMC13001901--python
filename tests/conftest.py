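"""Shared fixtures: small planted-signal cohorts and trained models.

Session-scoped so the expensive tree-ensemble fits are reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from embaudit import (EmbeddingBiasAudit, SyntheticConfig, generate_cohort,
                      stratified_split, train_multiclass)


@pytest.fixture(scope="session")
def small_cohort():
    """1,500 records, 25 dims, 4 sites; site dims 0-7, race dims 6-13.

    Overlap is dims 6-7; dims 14+ are pure noise.  Strong effect sizes so
    tree models reliably find the planted structure.
    """
    cfg = SyntheticConfig(
        n_records=1500, n_dims=25, n_sites=4,
        site_dims=range(0, 8), race_dims=range(6, 14),
        beta_site=2.0, beta_race=2.0, noise_sd=1.0, seed=42)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def fast_params():
    return {"n_estimators": 30, "max_depth": 4}


@pytest.fixture(scope="session")
def fitted_results(small_cohort, fast_params):
    """A fitted audit on the small cohort (site + race + one binary model)."""
    _, cohort, _ = small_cohort
    model = EmbeddingBiasAudit(cohort, params=fast_params, k=10,
                               seed=42, binary_sites=("site00",))
    return model.fit()


@pytest.fixture(scope="session")
def small_models(small_cohort, fast_params):
    """(site_model, race_model, split) trained directly on the small cohort."""
    _, cohort, _ = small_cohort
    split = stratified_split(cohort.site, 0.7, seed=0)
    tr = split.train_idx
    site = train_multiclass(cohort.X[tr], cohort.site[tr], fast_params,
                            seed=0, feature_names=cohort.feature_names,
                            target_kind="site")
    race = train_multiclass(cohort.X[tr], cohort.race[tr], fast_params,
                            seed=0, feature_names=cohort.feature_names,
                            target_kind="race")
    return site, race, split
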