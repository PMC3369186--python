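import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import sparseasm as sa


TOY_READ = "ACGTACGGATT"  # k=3, g=2 walkthrough sequence


@pytest.fixture
def toy_params():
    return sa.GraphParams(k=3, g=2, node_min_cov=0, link_min_cov=0)


@pytest.fixture
def toy_graph(toy_params):
    reads = [sa.Read("toy", TOY_READ)]
    graph = sa.select_nodes(reads, toy_params)
    sa.build_links(reads, graph)
    return graph


@pytest.fixture(scope="session")
def small_genome():
    return sa.random_genome(20_000, seed=42)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    return sa.simulate_reads(
        small_genome,
        sa.SimulationConfig(coverage=30, read_len=100, seed=7),
    )


def write_fasta(path, records):
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
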