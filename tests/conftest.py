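import numpy as np
import pandas as pd
import pytest

from coexnet import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_matrix():
    """20 uncorrelated genes x 12 samples, fixed seed."""
    rng = np.random.default_rng(1)
    genes = [f"G{i:03d}" for i in range(20)]
    cols = [f"S{i:02d}" for i in range(12)]
    return pd.DataFrame(8 + rng.normal(size=(20, 12)), index=genes, columns=cols)


@pytest.fixture(scope="session")
def planted():
    """Default planted-module simulation (3 x 10 genes, r = 0.9, seed 7)."""
    cfg = SimulationConfig(seed=7)
    m, ann, labels = simulate_expression(cfg)
    return cfg, m, ann, labels


@pytest.fixture
def annotation():
    rows = []
    i = 0
    for genotype in ("Atlas", "R159"):
        for tissue in ("shoot", "root", "stem"):
            for rep in (1, 2):
                i += 1
                rows.append({"sample_id": f"S{i:02d}", "series_id": "X",
                             "tissue": tissue, "genotype": genotype,
                             "treatment": "none", "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")
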