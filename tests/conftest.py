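import numpy as np
import pandas as pd
import pytest

from lncscreen import simulate as sim


@pytest.fixture(scope="session")
def default_study():
    """Full-scale synthetic cohort at the default (paper-scale) conditions."""
    config = sim.SimulationConfig(seed=20)
    counts, samples, models, peaks, truth = sim.simulate_study(config)
    return {"config": config, "counts": counts, "samples": samples,
            "models": models, "peaks": peaks, "truth": truth}


@pytest.fixture
def small_config():
    """Down-scaled cohort for fast structural tests."""
    return sim.SimulationConfig(
        n_patients=8,
        n_primaries_per_patient=[1, 1, 2, 0, 0, 0, 0, 0],
        mets_per_patient=2,
        n_normals_per_site=3,
        n_bph=3,
        n_genes=300,
        n_planted_met_genes=6,
        n_tissue_specific_genes=2,
        n_background_tissue_genes=5,
        seed=11,
    )


@pytest.fixture
def null_counts():
    """Null NB counts (no signal), 400 genes x 10 vs 10, with group lists."""
    rng = np.random.default_rng(5)
    mu = rng.uniform(20, 500, 400)[:, None]
    a = 0.2
    y = rng.negative_binomial(1 / a, 1 / (1 + a * mu), size=(400, 20))
    cols = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
    counts = pd.DataFrame(y, index=[f"g{i}" for i in range(400)], columns=cols)
    return counts, cols[:10], cols[10:]
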