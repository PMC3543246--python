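"""Triad statistics: census, switching null model, Z-scores and TSPs.

Every weakly connected 3-node directed subgraph falls into one of 13
isomorphism classes ("triads").  The catalog below fixes their order:

* 1, 2, 3 -- the single-edge-type open triads: divergence ``A<-B->C``,
  convergence ``A->B<-C`` and the cascade ``A->B->C``;
* 7 -- the feed-forward loop (FFL) ``{A->B, A->C, B->C}``;
* 8 -- the directed 3-cycle;
* 4, 5, 6, 9, 10, 11, 12, 13 -- the eight classes containing at least
  one mutual dyad, ordered by (number of mutual dyads, number of arcs).

The statistical significance of triad ``h`` in a network is its
Z-score against a null ensemble obtained by degree-preserving edge
switching that randomizes single (non-reciprocated) links and mutual
dyads separately, so that every node keeps its single-out, single-in
and mutual degree and the total number of mutual dyads is conserved:

    Z_h = (n_h - <n_rand,h>) / sigma_rand,h .

When sigma_rand,h = 0 (e.g. triads containing mutual dyads in a
feedback-free network, where the null ensemble cannot create any) the
Z-score is *undefined* and reported as such, never as a number.  The
13-vector of Z-scores, normalized to unit Euclidean norm over its
defined entries, is the triad significance profile (TSP).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .model import NetworkView

__all__ = [
    "TriadClass",
    "TRIAD_CATALOG",
    "TRIAD_NAME_BY_INDEX",
    "MUTUAL_CONTAINING_TRIADS",
    "CASCADE_TRIAD",
    "FFL_TRIAD",
    "TriadCensus",
    "TriadZScores",
    "TSP",
    "triad_census",
    "switching_null",
    "zscores",
    "normalize_tsp",
    "tsp_correlation",
]

#: networkx triad-type name for each catalog index 1..13.
TRIAD_NAME_BY_INDEX: dict[int, str] = {
    1: "021D",   # divergence A<-B->C
    2: "021U",   # convergence A->B<-C
    3: "021C",   # cascade A->B->C
    4: "111D",
    5: "111U",
    6: "120D",
    7: "030T",   # feed-forward loop
    8: "030C",   # 3-cycle
    9: "120U",
    10: "120C",
    11: "201",
    12: "210",
    13: "300",
}

CASCADE_TRIAD = 3
FFL_TRIAD = 7
#: Indices whose class contains at least one mutual dyad; their Z-scores
#: are undefined on feedback-free networks.
MUTUAL_CONTAINING_TRIADS = frozenset({4, 5, 6, 9, 10, 11, 12, 13})


@dataclass(frozen=True)
class TriadClass:
    index: int
    name: str
    edges: frozenset[tuple[str, str]]

    @property
    def n_mutual_dyads(self) -> int:
        return sum(1 for (u, v) in self.edges if u < v and (v, u) in self.edges)


def _build_catalog() -> tuple[TriadClass, ...]:
    relabel = {"a": "A", "b": "B", "c": "C"}
    catalog = []
    for idx in range(1, 14):
        name = TRIAD_NAME_BY_INDEX[idx]
        g = nx.triad_graph(name)
        edges = frozenset((relabel[u], relabel[v]) for u, v in g.edges())
        catalog.append(TriadClass(index=idx, name=name, edges=edges))
    return tuple(catalog)


TRIAD_CATALOG: tuple[TriadClass, ...] = _build_catalog()


@dataclass(frozen=True)
class TriadCensus:
    """Counts of the 13 connected triad classes (index h -> counts[h-1])."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (13,):
            raise ValueError("triad census must have 13 entries")
        object.__setattr__(self, "counts", c)

    def __getitem__(self, h: int) -> int:
        return int(self.counts[h - 1])

    @property
    def n_connected_triples(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TriadZScores:
    """Per-triad Z-scores; NaN entries are *undefined* (sigma = 0)."""

    z: np.ndarray              # 13 floats, NaN = undefined
    counts: TriadCensus        # observed counts
    ensemble_mean: np.ndarray
    ensemble_std: np.ndarray   # sample std, ddof=1
    n_ensemble: int

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.z)

    def __getitem__(self, h: int) -> float:
        return float(self.z[h - 1])

    def is_defined(self, h: int) -> bool:
        return not math.isnan(self.z[h - 1])


@dataclass(frozen=True)
class TSP:
    """Unit-normalized triad significance profile; NaN = undefined entry."""

    values: np.ndarray

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __getitem__(self, h: int) -> float:
        return float(self.values[h - 1])


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------


def _directed_edges(view: NetworkView) -> tuple[int, set[tuple[int, int]]]:
    """Node count and self-loop-free integer edge set of a view.

    Signs and weights are ignored: triad statistics live on directed
    unsigned structure.  UU views are rejected (a symmetric matrix would
    count every undirected link as a mutual dyad).
    """
    if view.level == "UU":
        raise ValueError("triad analysis requires a directed (DS/DU) view")
    src, tgt = np.nonzero(view.matrix)
    edges = {(int(i), int(j)) for i, j in zip(src, tgt) if i != j}
    return view.n_nodes, edges


def _census_from_edges(n_nodes: int, edges: Iterable[tuple[int, int]]) -> TriadCensus:
    a = np.zeros((n_nodes, n_nodes))
    e = list(edges)
    if e:
        src, tgt = zip(*e)
        a[list(src), list(tgt)] = 1.0
    return _census_from_matrix(a)


def _census_from_matrix(a: np.ndarray) -> TriadCensus:
    """Closed-form triad census from dyad-type matrix products.

    Decomposes the adjacency into mutual (M) and single (S) parts and
    counts each class by the dyad census of the triple plus the
    orientation of its single edges; all terms are dense matrix
    products, so the census is O(n^3) flops in BLAS rather than a
    Python-level triple loop.
    """
    n = a.shape[0]
    if n < 3:
        return TriadCensus(counts=np.zeros(13, dtype=np.int64))
    a = np.asarray(a, dtype=np.float32)  # 0/1 counts: exact well past 2^24
    m = a * a.T                      # mutual dyads (symmetric)
    s = a - m                        # single (non-reciprocated) edges
    nn = 1.0 - a - a.T + m           # null dyads
    np.fill_diagonal(nn, 0.0)

    s2 = s @ s
    ssT = s @ s.T
    sTs = s.T @ s
    m2 = m @ m

    c = np.zeros(13)
    c[0] = 0.5 * (nn * sTs).sum()                    # 021D  j<-i->k
    c[1] = 0.5 * (nn * ssT).sum()                    # 021U  j->i<-k
    c[2] = (nn * s2).sum()                           # 021C  cascade
    c[3] = 0.5 * (m * (s.T @ nn + nn @ s)).sum()     # 111D  single into the dyad
    c[4] = 0.5 * (m * (s @ nn + nn @ s.T)).sum()     # 111U  single out of the dyad
    c[5] = 0.5 * (m * sTs).sum()                     # 120D  both singles into the dyad
    c[6] = (s2 * s).sum()                            # 030T  feed-forward loop
    c[7] = np.trace(s2 @ s) / 3.0                    # 030C  3-cycle
    c[8] = 0.5 * (m * ssT).sum()                     # 120U  both singles out of the dyad
    c[9] = (m * s2).sum()                            # 120C  single path through the dyad
    c[10] = 0.5 * (nn * m2).sum()                    # 201
    c[11] = (s * m2).sum()                           # 210
    c[12] = np.trace(m2 @ m) / 6.0                   # 300
    return TriadCensus(counts=np.rint(c).astype(np.int64))


def triad_census(view: NetworkView) -> TriadCensus:
    """Exact 13-class census of weakly connected node triples.

    Self-loops are stripped; each unordered triple is counted once under
    its isomorphism class.
    """
    n, edges = _directed_edges(view)
    return _census_from_edges(n, edges)


# ---------------------------------------------------------------------------
# switching null model
# ---------------------------------------------------------------------------


def _split_single_mutual(
    edges: set[tuple[int, int]]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    singles = [(u, v) for (u, v) in edges if (v, u) not in edges]
    mutuals = [(u, v) for (u, v) in edges if u < v and (v, u) in edges]
    return singles, mutuals


def _rewire_edges(
    edges: set[tuple[int, int]],
    n_switch_per_edge: int,
    rng: random.Random,
) -> set[tuple[int, int]]:
    """Degree-preserving switching, randomizing singles and mutual dyads
    by separate swap moves; illegal proposals (self-loops, multi-edges,
    single<->mutual conversions) are rejected."""
    edges = set(edges)
    singles, mutuals = _split_single_mutual(edges)

    if len(singles) >= 2:
        for _ in range(n_switch_per_edge * len(singles)):
            i = rng.randrange(len(singles))
            j = rng.randrange(len(singles))
            if i == j:
                continue
            a, b = singles[i]
            c, d = singles[j]
            if a == c or b == d or a == d or c == b:
                continue
            e1, e2 = (a, d), (c, b)
            if (
                e1 in edges or e2 in edges
                or (d, a) in edges or (b, c) in edges
            ):
                continue
            edges.discard((a, b))
            edges.discard((c, d))
            edges.add(e1)
            edges.add(e2)
            singles[i] = e1
            singles[j] = e2

    if len(mutuals) >= 2:
        for _ in range(n_switch_per_edge * len(mutuals)):
            i = rng.randrange(len(mutuals))
            j = rng.randrange(len(mutuals))
            if i == j:
                continue
            a, b = mutuals[i]
            c, d = mutuals[j]
            if len({a, b, c, d}) < 4:
                continue
            if rng.random() < 0.5:
                p1, p2 = (a, d), (c, b)
            else:
                p1, p2 = (a, c), (d, b)
            new_arcs = [p1, (p1[1], p1[0]), p2, (p2[1], p2[0])]
            if any(e in edges for e in new_arcs):
                continue
            for u, v in ((a, b), (b, a), (c, d), (d, c)):
                edges.discard((u, v))
            edges.update(new_arcs)
            mutuals[i] = (min(p1), max(p1))
            mutuals[j] = (min(p2), max(p2))

    return edges


def switching_null(
    view: NetworkView, n_switch_per_edge: int = 100, seed: int = 0
) -> NetworkView:
    """One sample of the null ensemble for ``view`` (self-loops stripped).

    Every node's (single-out, single-in, mutual) degree triple and the
    total number of mutual dyads are conserved, so a feedback-free
    network stays feedback-free in every sample.
    """
    n, edges = _directed_edges(view)
    rng = random.Random(seed)
    new_edges = _rewire_edges(edges, n_switch_per_edge, rng)
    m = np.zeros((n, n))
    for u, v in new_edges:
        m[u, v] = 1.0
    return NetworkView(level="DU", nodes=view.nodes, matrix=m)


# ---------------------------------------------------------------------------
# Z-scores and TSPs
# ---------------------------------------------------------------------------


def zscores(
    view: NetworkView,
    R: int = 1000,
    n_switch_per_edge: int = 100,
    seed: int = 0,
) -> TriadZScores:
    """Triad Z-scores against R independent switching-null samples.

    Each sample is rewired from the original network with its own child
    seed.  The ensemble std uses ddof=1; a zero std makes the entry
    undefined (NaN), which exact integer counts make unambiguous.
    """
    if R < 2:
        raise ValueError("need an ensemble of at least 2 randomizations")
    n, edges = _directed_edges(view)
    observed = _census_from_edges(n, edges)
    child_seeds = np.random.SeedSequence(seed).generate_state(R) % (2**31)
    ensemble = np.empty((R, 13), dtype=np.int64)
    for k in range(R):
        rng = random.Random(int(child_seeds[k]))
        sample = _rewire_edges(edges, n_switch_per_edge, rng)
        ensemble[k] = _census_from_edges(n, sample).counts
    mean = ensemble.mean(axis=0)
    std = ensemble.std(axis=0, ddof=1)
    z = np.full(13, np.nan)
    ok = std > 0
    z[ok] = (observed.counts[ok] - mean[ok]) / std[ok]
    return TriadZScores(
        z=z, counts=observed, ensemble_mean=mean, ensemble_std=std, n_ensemble=R
    )


def normalize_tsp(zs: TriadZScores) -> TSP:
    """Divide defined Z entries by their Euclidean norm; NaN propagates.

    An all-undefined or all-zero profile has no direction and is an
    error.
    """
    z = zs.z.copy()
    defined = ~np.isnan(z)
    norm = float(np.sqrt(np.nansum(z**2)))
    if not defined.any() or norm == 0.0:
        raise ValueError("TSP undefined: no defined, nonzero Z-score entries")
    z[defined] = z[defined] / norm
    return TSP(values=z)


def tsp_correlation(p1: TSP, p2: TSP) -> Optional[float]:
    """Pearson correlation over the mutually defined triad indices.

    Returns ``None`` when fewer than 3 indices are defined in both
    profiles (the correlation would be meaningless).
    """
    both = p1.defined() & p2.defined()
    if both.sum() < 3:
        return None
    x, y = p1.values[both], p2.values[both]
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
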