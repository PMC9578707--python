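import numpy as np
import pytest

import crispra_screen as cs


@pytest.fixture(scope="session")
def standard_null():
    """Null model fitted to a large standard-normal control sample."""
    rng = np.random.default_rng(12345)
    return cs.fit_null(rng.normal(size=10_000))


@pytest.fixture(scope="session")
def benchmark_screen():
    """Small two-round screen with one strength-1 receptor among 50 genes."""
    design = cs.ScreenDesign(
        gene_ids=tuple(f"G{i:03d}" for i in range(50)),
        guides_per_gene=10,
        n_controls=100,
        true_receptors={"G000": 1.0},
    )
    params = cs.SimulationParams(n_rounds=2, sequencing_depth=500_000, seed=42)
    return cs.simulate_screen(design, params)


@pytest.fixture()
def small_config():
    return cs.CastleConfig(n_perm=200, seed=0)
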