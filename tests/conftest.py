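from __future__ import annotations

import random

import pytest

from tfmodminer.io import ConfidenceNetwork
from tfmodminer.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def easy_bundle():
    """One synthetic bundle in the easy planted-module regime."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture
def write_tsv(tmp_path):
    """Write tab-separated lines to a temp file and return its path."""

    def _write(name: str, *rows: str) -> str:
        p = tmp_path / name
        p.write_text("\n".join(rows) + "\n")
        return str(p)

    return _write


def random_connected_network(
    rng: random.Random, n_nodes: int, extra_edge_prob: float = 0.3
) -> ConfidenceNetwork:
    """A random connected confidence network: a random spanning tree plus
    Bernoulli extra edges, confidences uniform in (0.05, 0.95)."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    net = ConfidenceNetwork()
    shuffled = nodes[:]
    rng.shuffle(shuffled)
    for i in range(1, len(shuffled)):
        a = shuffled[rng.randrange(i)]
        net.add_edge(a, shuffled[i], rng.uniform(0.05, 0.95))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if not net.has_edge(a, b) and rng.random() < extra_edge_prob:
                net.add_edge(a, b, rng.uniform(0.05, 0.95))
    return net
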