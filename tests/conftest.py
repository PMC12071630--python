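import numpy as np
import pytest

import triploid_ase as ta


@pytest.fixture(scope="session")
def sim_small():
    """Small seeded dataset for plumbing tests (300 pairs, 3 stages)."""
    cfg = ta.SimulationConfig(n_pairs=300, seed=1)
    matrix, pairs, truth = ta.simulate_dataset(cfg)
    return cfg, matrix, pairs, truth


@pytest.fixture(scope="session")
def sim_bench():
    """Benchmark-scale dataset: 2,000 pairs, default injection fractions."""
    cfg = ta.SimulationConfig(n_pairs=2000, seed=7)
    matrix, pairs, truth = ta.simulate_dataset(cfg)
    return cfg, matrix, pairs, truth


@pytest.fixture(scope="session")
def deg_bench(sim_bench):
    """DEG screen on the benchmark dataset (shared: the NB test is the
    expensive stage)."""
    cfg, matrix, pairs, truth = sim_bench
    return ta.call_deg_alleles(matrix, pairs, ta.PipelineConfig())


@pytest.fixture(scope="session")
def null_nb_pvalues():
    """Exact-test p-values for 2,500 genes where both groups share one NB law."""
    rng = np.random.default_rng(11)
    n_genes, disp = 2500, 0.1
    mu = rng.lognormal(np.log(200), 1.0, n_genes)
    size = 1 / disp
    c1 = rng.negative_binomial(size, size / (size + mu[:, None]), (n_genes, 3))
    c2 = rng.negative_binomial(size, size / (size + mu[:, None]), (n_genes, 3))
    ones = np.ones(3)
    return ta.nb_test(c1, c2, ones, ones)
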