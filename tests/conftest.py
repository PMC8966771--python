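import numpy as np
import pandas as pd
import pytest

from canopygp.quantgen import compute_grm
from canopygp.simulate import SimConfig, plot_param_table, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A small two-environment trial used across cross-validation tests."""
    cfg = SimConfig(
        n_genotypes=30,
        n_markers=400,
        years=(2018,),
        flights_per_env=8,
        seed=42,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_data(small_sim):
    from canopygp.cv import build_panel

    params = plot_param_table(small_sim)
    grm = compute_grm(small_sim.markers)
    return build_panel(small_sim.pheno, params, grm, small_sim.thermal)


@pytest.fixture(scope="session")
def random_grm():
    """A 60-genotype GRM from random unlinked markers."""
    rng = np.random.default_rng(7)
    n, m = 60, 300
    codes = pd.DataFrame(
        rng.binomial(2, np.clip(rng.beta(0.5, 0.5, m), 0.05, 0.95), (n, m)).astype(float) - 1,
        index=[f"g{i:02d}" for i in range(n)],
    )
    codes = codes.loc[:, codes.std() > 0]
    return compute_grm(codes)
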