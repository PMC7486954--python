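import numpy as np
import pytest

from mutacc.filters import FilterParams, compute_callable_sites, filter_candidates
from mutacc.simulate import (SimulationConfig, generate_genome, implant_cds,
                             simulate_codon_usage, simulate_ma_lines,
                             synthesize_variant_calls)


@pytest.fixture(scope="session")
def sim_config():
    # desk-scale emulation of the 15-line bottleneck design
    return SimulationConfig(genome_length=200_000, n_genes=30, mu_true=1e-7,
                            seed=42)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    rng = np.random.default_rng(101)
    genome = generate_genome(sim_config, rng)
    codon_sim = simulate_codon_usage(genome, sim_config, rng)
    return implant_cds(genome, codon_sim.cds)


@pytest.fixture(scope="session")
def sim_truth(sim_genome, sim_config):
    return simulate_ma_lines(sim_genome, sim_config,
                             np.random.default_rng(202))


@pytest.fixture(scope="session")
def sim_calls(sim_truth, sim_genome, sim_config):
    return synthesize_variant_calls(sim_truth, sim_genome, sim_config,
                                    np.random.default_rng(303))


@pytest.fixture(scope="session")
def filtered(sim_calls, sim_genome):
    params = FilterParams()
    masks = {line: compute_callable_sites(sim_calls.pileup, line,
                                          "ancestor", params)[0]
             for line in sim_calls.candidates.lines}
    accepted, rejected = filter_candidates(sim_calls.candidates, params,
                                           genome=sim_genome,
                                           callable_masks=masks)
    return accepted, rejected
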