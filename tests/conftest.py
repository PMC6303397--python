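import numpy as np
import pandas as pd
import pytest

from senokit.expression import CountMatrix
from senokit.simulate import CellSimConfig, ExpressionSimConfig, simulate_cell_features, simulate_counts


@pytest.fixture
def tiny_counts():
    """3 genes x 6 samples, one tissue, all three groups, hand-enterable."""
    counts = pd.DataFrame(
        {
            "liver_young_r1": [10, 0, 100],
            "liver_young_r2": [12, 1, 90],
            "liver_old_vehicle_r1": [40, 2, 100],
            "liver_old_vehicle_r2": [44, 1, 110],
            "liver_old_treated_r1": [20, 0, 95],
            "liver_old_treated_r2": [22, 2, 105],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "tissue": ["liver"] * 6,
            "group": ["young", "young", "old_vehicle", "old_vehicle", "old_treated", "old_treated"],
            "replicate": [1, 2, 1, 2, 1, 2],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts=counts, metadata=meta)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-tissue simulated study with a strong rejuvenation effect."""
    cfg = ExpressionSimConfig(
        n_genes=800,
        n_replicates_per_group=4,
        tissues=("kidney", "liver"),
        dispersion=0.05,
        age_effect_sd=1.5,
        rejuvenation_kappa=0.6,
        seed=11,
    )
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def gated_cells():
    cfg = CellSimConfig(n_cells=20_000, senescent_fraction=0.1, seed=5)
    cells, truth = simulate_cell_features(cfg)
    return cfg, cells, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
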