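"""Shared fixtures and graph-building helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from oneironet.cooccurrence import NetworkThresholds, WordNetwork
from oneironet.corpus_io import DreamReport, Stratum


def make_report(report_id: str, tokens, stratum="increased") -> DreamReport:
    return DreamReport(report_id, f"resp_{report_id}", Stratum(stratum), tuple(tokens))


def make_network(edges, doc_freq: int = 5, min_phi: float = -1.0) -> WordNetwork:
    """Build a WordNetwork directly from (a, b, weight) triples."""
    edge_map = {}
    nodes = {}
    for a, b, w in edges:
        a, b = sorted((a, b))
        edge_map[(a, b)] = (float(w), 0)
        nodes[a] = nodes[b] = doc_freq
    return WordNetwork(
        nodes=nodes, edges=edge_map,
        thresholds=NetworkThresholds(min_doc_freq=1, min_phi=min_phi),
    )


def random_connected_network(rng: np.random.Generator, n_nodes: int,
                             extra_edge_prob: float = 0.3) -> WordNetwork:
    """Random connected weighted graph: spanning tree plus random extras."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = {}
    perm = [nodes[i] for i in rng.permutation(n_nodes)]
    for i in range(1, n_nodes):
        a, b = sorted((perm[i], perm[int(rng.integers(0, i))]))
        edges[(a, b)] = float(rng.uniform(0.05, 1.0))
    for a, b in itertools.combinations(nodes, 2):
        if (a, b) not in edges and rng.random() < extra_edge_prob:
            edges[(a, b)] = float(rng.uniform(0.05, 1.0))
    return make_network([(a, b, w) for (a, b), w in edges.items()])


@pytest.fixture
def four_report_corpus() -> list[DreamReport]:
    """Small corpus with known doc frequencies: corona=3, death=2, work=2."""
    return [
        make_report("r1", ["corona", "death"]),
        make_report("r2", ["corona", "work"]),
        make_report("r3", ["death"]),
        make_report("r4", ["work", "corona"]),
    ]
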