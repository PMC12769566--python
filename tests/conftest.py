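import pytest

from tetralog import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic panel shared by read-only tests."""
    return simulate_all(SimConfig(seed=5))


@pytest.fixture(scope="session")
def dominance_panel():
    """Fully retained 2000-pair panel for expression-dominance recovery."""
    from tetralog import gen_expression, gen_genome

    config = SimConfig(seed=11, n_chromosomes_per_subgenome=2,
                       genes_per_chromosome=1000,
                       retention_rates=(1.0, 0.0, 0.0),
                       dominance_proportions=(0.10, 0.80, 0.10))
    _, _, truth = gen_genome(config)
    tpm, samples = gen_expression(truth, config)
    return config, truth, tpm, samples
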