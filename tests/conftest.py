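"""Shared fixtures: tiny hand-built networks and the hierarchical toy graph."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from trntopo.model import (
    EdgeRecord,
    EvidenceTag,
    NetworkView,
    NodeRecord,
    RegulatoryNetwork,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_net(edges, roles=None, categories=None, name="fixture"):
    """Network from (source, target, sign, evidence) tuples.

    ``sign`` may be omitted (None); ``evidence`` is an iterable of
    (tag, category) pairs.
    """
    roles = roles or {}
    categories = categories or {}
    node_ids = []
    for row in edges:
        node_ids.extend(row[:2])
    sources = {row[0] for row in edges}
    nodes = [
        NodeRecord(
            i,
            role=roles.get(i, "transcription_factor" if i in sources else "target_only"),
            functional_category=categories.get(i),
        )
        for i in dict.fromkeys(node_ids)
    ]
    recs = []
    for row in edges:
        src, tgt = row[0], row[1]
        sign = row[2] if len(row) > 2 else None
        ev = frozenset(EvidenceTag(t, c) for t, c in (row[3] if len(row) > 3 else ()))
        recs.append(EdgeRecord(src, tgt, sign=sign, evidence=ev))
    return RegulatoryNetwork(nodes, recs, name=name)


@pytest.fixture
def fig3_toy():
    """The schematic suspicious-link example: activating/inhibiting edges
    where 1->2 and 3->4 are paralleled by sign-coherent 2-link cascades
    but 1->5 is paralleled only by an incoherent one."""
    return build_net(
        [
            ("g1", "g3", 1),
            ("g3", "g2", -1),
            ("g1", "g2", -1),
            ("g3", "g5", 1),
            ("g1", "g5", -1),
            ("g5", "g4", 1),
            ("g3", "g4", 1),
        ]
    )


def hierarchical_toy_view() -> NetworkView:
    """Two-level benchmark: 4 cliques of 5 nodes; cliques paired into 2
    supergroups by 2 inter-clique links each; 1 link between supergroups."""
    n = 20
    m = np.zeros((n, n))

    def add(i, j):
        m[i, j] = m[j, i] = 1.0

    for c in range(4):
        for i in range(5 * c, 5 * c + 5):
            for j in range(i + 1, 5 * c + 5):
                add(i, j)
    add(0, 5)
    add(1, 6)
    add(10, 15)
    add(11, 16)
    add(2, 12)
    return NetworkView("UU", tuple(f"n{i:02d}" for i in range(n)), m)


@pytest.fixture
def hierarchical_toy():
    return hierarchical_toy_view()


def view_from_edges(edges, n=None, level="DU"):
    """Directed 0/1 view from integer edge pairs."""
    if n is None:
        n = max(max(e) for e in edges) + 1
    m = np.zeros((n, n))
    for u, v in edges:
        m[u, v] = 1.0
    ids = tuple(f"x{i:03d}" for i in range(n))
    return NetworkView(level, ids, m)
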