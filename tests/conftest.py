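import dataclasses

import networkx as nx
import numpy as np
import pytest

from mbnet import mapping, network, synth


@pytest.fixture(scope="session")
def demo_config() -> synth.SynthConfig:
    """The packaged demo world (defaults of SynthConfig)."""
    return synth.SynthConfig()


@pytest.fixture(scope="session")
def tiny_config() -> synth.SynthConfig:
    """A scaled-down world for fast unit tests."""
    return synth.SynthConfig(
        n_proteins=160,
        n_modules=3,
        module_size_range=(10, 14),
        overlap_nodes=2,
        n_disease_modules=2,
        n_background_seeds=8,
        background_halo=4.0,
        n_pathways=6,
        n_metabolites=5,
    )


@pytest.fixture(scope="session")
def demo_world(demo_config):
    """Generated demo inputs + the network built from them (seed 1)."""
    cfg = dataclasses.replace(demo_config, seed=1)
    data = synth.generate_all(cfg)
    seeds = mapping.SeedSets(scz=data.truth.seed_scz, bd=data.truth.seed_bd)
    net = network.build_network(data.interactions, seeds)
    return data, seeds, net


def random_graph(rng: np.random.Generator, n_max: int = 40, p_max: float = 0.4) -> nx.Graph:
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, p_max))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    return nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
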