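"""Core data model for transcriptional regulatory networks (TRNs).

A TRN is a directed graph whose nodes are genes (or operons) and whose
edges are transcriptional regulations.  Edges may carry a sign
(+1 activation, -1 inhibition, or unknown) and a set of experimental
evidence tags, each tag belonging to one of two methodological
categories:

* ``BA`` -- binding assays, direct detection of the protein--DNA
  interaction;
* ``TELC`` -- target-expression-level comparison between wild-type and
  regulator-perturbed strains.

Nodes carry a regulatory role (``transcription_factor``,
``sigma_factor`` or ``target_only``) and an optional functional
category label.

Three projections of one network are used throughout:

* ``DS`` -- directed signed: only edges with known sign, weight = sign;
* ``DU`` -- directed unsigned: every edge, weight 1;
* ``UU`` -- undirected unsigned: OR-symmetrized, weight 1 (a mutual
  dyad collapses to a single undirected link).

Self-loops (auto-regulations) are legal and are book-kept separately
from ordinary links; they appear on the diagonal of every projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

__all__ = [
    "ROLES",
    "EVIDENCE_CATEGORIES",
    "EvidenceTag",
    "NodeRecord",
    "EdgeRecord",
    "RegulatoryNetwork",
    "NetworkView",
    "NetworkStats",
    "project",
    "network_stats",
    "remove_sigma_factors",
]

ROLES = ("transcription_factor", "sigma_factor", "target_only")
REGULATOR_ROLES = ("transcription_factor", "sigma_factor")
EVIDENCE_CATEGORIES = ("BA", "TELC")
VIEW_LEVELS = ("DS", "DU", "UU")


@dataclass(frozen=True, order=True)
class EvidenceTag:
    """One experimental technique supporting an edge.

    ``category`` is the methodological class of the technique:
    ``"BA"`` (binding assay) or ``"TELC"`` (target expression level
    comparison).
    """

    name: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in EVIDENCE_CATEGORIES:
            raise ValueError(
                f"evidence category must be one of {EVIDENCE_CATEGORIES}, "
                f"got {self.category!r}"
            )


@dataclass(frozen=True)
class NodeRecord:
    id: str
    role: str = "target_only"
    functional_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def is_regulator(self) -> bool:
        return self.role in REGULATOR_ROLES


@dataclass(frozen=True)
class EdgeRecord:
    """A regulation source -> target.

    ``sign`` is +1 (activation), -1 (inhibition) or ``None`` (unknown).
    Unknown-sign edges are excluded from every signed (DS) computation
    and from the suspicious-link analysis.
    """

    source: str
    target: str
    sign: Optional[int] = None
    evidence: frozenset[EvidenceTag] = frozenset()

    def __post_init__(self) -> None:
        if self.sign not in (1, -1, None):
            raise ValueError(f"sign must be +1, -1 or None, got {self.sign!r}")
        object.__setattr__(self, "evidence", frozenset(self.evidence))

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


class RegulatoryNetwork:
    """Directed, signed, evidence-annotated regulatory network.

    At most one edge per ordered (source, target) pair; every edge
    endpoint must be a registered node.  The class is a thin container:
    all analyses work on projections (:func:`project`) or directly on
    the edge records.
    """

    def __init__(
        self,
        nodes: Iterable[NodeRecord] = (),
        edges: Iterable[EdgeRecord] = (),
        name: str = "",
    ) -> None:
        self.name = name
        self._nodes: dict[str, NodeRecord] = {}
        self._edges: dict[tuple[str, str], EdgeRecord] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------
    def add_node(self, node: NodeRecord, replace_existing: bool = True) -> None:
        if node.id in self._nodes and not replace_existing:
            return
        self._nodes[node.id] = node

    def ensure_node(self, node_id: str, role: str = "target_only") -> None:
        """Register ``node_id`` if unseen; never downgrades an existing record."""
        if node_id not in self._nodes:
            self._nodes[node_id] = NodeRecord(node_id, role=role)

    def add_edge(self, edge: EdgeRecord) -> None:
        key = (edge.source, edge.target)
        if key in self._edges:
            raise ValueError(f"duplicate edge {edge.source}->{edge.target}")
        for endpoint in key:
            if endpoint not in self._nodes:
                raise KeyError(f"edge endpoint {endpoint!r} is not a node")
        self._edges[key] = edge

    # -- access -------------------------------------------------------
    @property
    def nodes(self) -> Mapping[str, NodeRecord]:
        return self._nodes

    @property
    def edges(self) -> Mapping[tuple[str, str], EdgeRecord]:
        return self._edges

    def node_ids(self) -> list[str]:
        """Node identifiers in sorted (deterministic) order."""
        return sorted(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[EdgeRecord]:
        return iter(self._edges.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:  # pragma: no cover
        s = self.stats()
        return (
            f"<RegulatoryNetwork {self.name!r}: N={s.n_nodes} L={s.n_links} "
            f"SL={s.n_self_loops}>"
        )

    def regulators(self) -> list[str]:
        """Nodes annotated with a regulatory role (TF or sigma factor)."""
        return sorted(i for i, n in self._nodes.items() if n.is_regulator)

    def copy(self, name: Optional[str] = None) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            self._nodes.values(),
            self._edges.values(),
            name=self.name if name is None else name,
        )

    def drop_edges(
        self, keys: Iterable[tuple[str, str]], name: Optional[str] = None
    ) -> "RegulatoryNetwork":
        """New network without the given (source, target) edges."""
        drop = set(keys)
        return RegulatoryNetwork(
            self._nodes.values(),
            (e for k, e in self._edges.items() if k not in drop),
            name=self.name if name is None else name,
        )

    # -- convenience --------------------------------------------------
    def stats(self) -> "NetworkStats":
        return network_stats(self)

    def project(self, level: str) -> "NetworkView":
        return project(self, level)


@dataclass(frozen=True)
class NetworkView:
    """A square weighted adjacency over a fixed node ordering.

    ``matrix[i, j]`` is the weight of the edge ``nodes[i] -> nodes[j]``
    (for UU the matrix is symmetric).  Self-loops sit on the diagonal.
    """

    level: str
    nodes: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.level not in VIEW_LEVELS:
            raise ValueError(f"level must be one of {VIEW_LEVELS}")
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node ordering")
        object.__setattr__(self, "matrix", m)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.nodes)}

    def edge_list(self) -> list[tuple[str, str, float]]:
        src, tgt = np.nonzero(self.matrix)
        return [
            (self.nodes[i], self.nodes[j], float(self.matrix[i, j]))
            for i, j in zip(src.tolist(), tgt.tolist())
        ]


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_links: int          # ordinary (non-self-loop) edges, L
    n_self_loops: int     # SL
    n_regulators: int
    n_feedback_loops: int  # mutual dyads {i, j} with both i->j and j->i


def project(net: RegulatoryNetwork, level: str) -> NetworkView:
    """Project a network to its DS, DU or UU adjacency view.

    DS keeps only known-sign edges (weight = sign); DU keeps every edge
    with weight 1; UU symmetrizes DU by logical OR.  Self-loops are
    preserved on the diagonal at every level.
    """
    if level not in VIEW_LEVELS:
        raise ValueError(f"level must be one of {VIEW_LEVELS}, got {level!r}")
    order = tuple(net.node_ids())
    idx = {v: i for i, v in enumerate(order)}
    m = np.zeros((len(order), len(order)))
    if level == "DS":
        if not any(e.sign is not None for e in net):
            raise ValueError("DS projection requested on a fully unsigned network")
        for e in net:
            if e.sign is not None:
                m[idx[e.source], idx[e.target]] = e.sign
    else:
        for e in net:
            m[idx[e.source], idx[e.target]] = 1.0
        if level == "UU":
            m = np.maximum(m, m.T)
    return NetworkView(level=level, nodes=order, matrix=m)


def network_stats(net: RegulatoryNetwork) -> NetworkStats:
    n_self = sum(1 for e in net if e.is_self_loop)
    n_links = len(net.edges) - n_self
    keys = set(net.edges)
    n_mutual = sum(
        1
        for (u, v) in keys
        if u < v and (v, u) in keys
    )
    return NetworkStats(
        n_nodes=len(net),
        n_links=n_links,
        n_self_loops=n_self,
        n_regulators=len(net.regulators()),
        n_feedback_loops=n_mutual,
    )


def remove_sigma_factors(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Network with every sigma-factor node and its incident edges removed.

    The input is not modified.  Used to re-run the evidence-bias
    analysis with transcription factors as the only regulators.
    """
    sigma = {i for i, n in net.nodes.items() if n.role == "sigma_factor"}
    return RegulatoryNetwork(
        (n for n in net.nodes.values() if n.id not in sigma),
        (
            e
            for e in net
            if e.source not in sigma and e.target not in sigma
        ),
        name=net.name,
    )
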