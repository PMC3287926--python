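import numpy as np
import pytest

from pathscore.config import RunConfig
from pathscore.simulate import (
    CausalPathwaySpec,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_null_dataset():
    """Small stratified dataset with no causal effects."""
    cfg = SimulationConfig(
        n_samples=300,
        n_genes=60,
        mean_snps_per_gene=3.0,
        n_pathways=15,
        genes_per_pathway=(5, 10),
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_causal_dataset():
    """Small dataset with one causal pathway (PW0001)."""
    cfg = SimulationConfig(
        n_samples=600,
        n_genes=80,
        mean_snps_per_gene=5.0,
        n_pathways=10,
        genes_per_pathway=(6, 10),
        causal_pathways=[CausalPathwaySpec("PW0001")],
        reserve_causal_genes=True,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def run_config():
    return RunConfig(top_k=3, run_univariate=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_binary_outcome(table: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """(predictor, outcome) arrays from 2x2 counts
    {exposed_case, exposed_ctrl, unexposed_case, unexposed_ctrl}."""
    x = np.r_[
        np.ones(table["exposed_case"] + table["exposed_ctrl"]),
        np.zeros(table["unexposed_case"] + table["unexposed_ctrl"]),
    ]
    y = np.r_[
        np.ones(table["exposed_case"]),
        np.zeros(table["exposed_ctrl"]),
        np.ones(table["unexposed_case"]),
        np.zeros(table["unexposed_ctrl"]),
    ]
    return x, y
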