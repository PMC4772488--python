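import numpy as np
import pytest

from geosba import (
    GeneratorConfig,
    McmcConfig,
    default_full_spec,
    generate_survey,
    make_lattice_graph,
    sequential_build,
)


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic scenario: 110 districts, ~12,200 births."""
    cfg = GeneratorConfig()
    graph = make_lattice_graph(cfg.rows, cfg.cols)
    table, truth = generate_survey(cfg, graph)
    return cfg, graph, table, truth


@pytest.fixture(scope="session")
def default_sequential(default_scenario):
    """Sequential Model 1-4 cascade on the default scenario.

    Chain length is reduced from the reporting default (2,500 iterations,
    500 burn-in, thin 4) to keep the suite fast; the Polya-Gamma Gibbs
    sampler mixes quickly enough that 500 retained draws give stable
    posterior means and interval summaries at this sample size.
    """
    _, graph, table, _ = default_scenario
    mcmc = McmcConfig(iterations=2500, burn_in=500, thin=4, seed=11)
    return sequential_build(table, graph, default_full_spec(), mcmc)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced scenario (16 districts, 1,500 births) for cheaper fits."""
    cfg = GeneratorConfig(rows=4, cols=4, n_births=1500, seed=5)
    graph = make_lattice_graph(cfg.rows, cfg.cols)
    table, truth = generate_survey(cfg, graph)
    return cfg, graph, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
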