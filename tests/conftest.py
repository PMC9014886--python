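import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rootfate as rf
from rootfate import simulate as sim
from rootfate.preprocess import log_normalize, pca_embed

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_atlas():
    """Compact atlas with dying cells for QC/annotation tests."""
    cfg = rf.default_config(n_cells=2000, n_genes=1000, seed=42)
    adata, truth = rf.simulate_root(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def clean_atlas():
    """Atlas without dying cells or anchor population; good for recovery tests."""
    cfg = rf.default_config(
        n_cells=1200, n_genes=1000, seed=43, dying_fraction=0.0, qc_center_fraction=0.0
    )
    adata, truth = rf.simulate_root(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def clean_embedding(clean_atlas):
    _, adata, _ = clean_atlas
    return pca_embed(log_normalize(adata.X), n_comps=50, random_state=0)


@pytest.fixture(scope="session")
def lineage_rates(clean_atlas):
    cfg, _, _ = clean_atlas
    return {l.name: l.growth_rate for l in cfg.lineages}
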