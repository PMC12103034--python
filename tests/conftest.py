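import numpy as np
import pandas as pd
import pytest

from coexsig.normalize import cqn_like_normalize, filter_zero_genes, log2_fpkm
from coexsig.network import build_adjacency, cluster_and_cut, compute_tom
from coexsig.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def scenario():
    """Canonical seeded cohort: 3 modules (120/100/80) + 200 grey, 11 vs 35."""
    config = SimulationConfig(seed=1)
    ds, truth = generate_dataset(config)
    return config, ds, truth


@pytest.fixture(scope="session")
def detrended(scenario):
    """GC/length-detrended log2 FPKM of the canonical cohort."""
    _, ds, _ = scenario
    return cqn_like_normalize(log2_fpkm(filter_zero_genes(ds)), quantile=False)


@pytest.fixture(scope="session")
def network_fit(scenario, detrended):
    """TOM and recovered module labels of the canonical cohort (power 4)."""
    tom = compute_tom(build_adjacency(detrended.values, 4))
    linkage, labels = cluster_and_cut(tom, 50, 2, expr=detrended.values)
    return tom, linkage, labels


def me_cohort(n_case=11, n_ctrl=35, delta=1.0, n_noise=2, seed=0):
    """Latent-level eigengene cohort: module 1 shifted in cases, rest null."""
    rng = np.random.default_rng(seed)
    idx = [f"P{i}" for i in range(n_case)] + [f"C{i}" for i in range(n_ctrl)]
    cols = {1: np.r_[rng.normal(delta, 1, n_case), rng.normal(0, 1, n_ctrl)]}
    for m in range(2, 2 + n_noise):
        cols[m] = rng.standard_normal(n_case + n_ctrl)
    me = pd.DataFrame(cols, index=idx)
    status = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=idx)
    return me, status
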