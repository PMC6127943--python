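"""Shared fixtures: the hand-built scenario fixture and random-graph factories."""

from __future__ import annotations

import numpy as np
import pytest

from kgscreen import (
    Combination,
    KnowledgeGraph,
    ProteinSet,
    Triple,
    scenario_fixture,
)

PREDICATES = ("binds", "activates", "inhibits", "regulates")
SOURCES = ("S1", "S2", "S3")


def random_graph(
    rng: np.random.Generator,
    n_nodes: int = 20,
    n_edges: int = 30,
    self_loop_prob: float = 0.1,
) -> KnowledgeGraph:
    """Small random multigraph with multi-source provenance for oracle tests."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    triples = []
    for _ in range(n_edges):
        if rng.random() < self_loop_prob:
            a = b = nodes[rng.integers(n_nodes)]
        else:
            a, b = (nodes[int(i)] for i in rng.choice(n_nodes, size=2, replace=False))
        pred = PREDICATES[rng.integers(len(PREDICATES))]
        srcs = frozenset(
            SOURCES[int(i)]
            for i in rng.choice(len(SOURCES), size=int(rng.integers(1, 3)), replace=False)
        )
        triples.append(Triple(a, pred, b, srcs))
    return KnowledgeGraph(triples, proteins=nodes)


def random_combo(
    rng: np.random.Generator,
    graph: KnowledgeGraph,
    dt_size: int = 3,
    dp_size: int = 3,
    combo_id: str = "c0",
    label: str = "unlabeled",
) -> Combination:
    nodes = sorted(graph.proteins)
    dt = frozenset(nodes[int(i)] for i in rng.choice(len(nodes), size=dt_size, replace=False))
    dp = frozenset(nodes[int(i)] for i in rng.choice(len(nodes), size=dp_size, replace=False))
    return Combination(combo_id, ProteinSet(dt, "DT"), ProteinSet(dp, "DP"), label)


@pytest.fixture
def scenario_fx():
    return scenario_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
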