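import pandas as pd
import pytest

from droughtmem.expression import CountMatrix
from droughtmem.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def planted_dataset():
    """Synthetic dataset at the standard recovery conditions: 2,000 genes,
    planted effect log2fc = 2, dispersion 0.05, 3 replicates."""
    cfg = SimulationConfig(
        n_genes=2000, effect_log2fc=2.0, dispersion=0.05, n_replicates=3, seed=7
    )
    return cfg, simulate(cfg)


@pytest.fixture
def toy_counts():
    """4 genes x 4 samples (one ecotype, two treatments, 2 replicates)."""
    values = pd.DataFrame(
        {
            "AEX_R0_1": [10, 100, 0, 7],
            "AEX_R0_2": [12, 110, 0, 9],
            "AEX_S1_1": [40, 100, 0, 8],
            "AEX_S1_2": [44, 105, 0, 7],
        },
        index=["g_up", "g_flat", "g_zero", "g_small"],
    )
    design = pd.DataFrame(
        {
            "ecotype": ["AEX"] * 4,
            "treatment": ["R0", "R0", "S1", "S1"],
            "replicate": [1, 2, 1, 2],
        },
        index=values.columns,
    )
    return CountMatrix(values, design)
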