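"""Synthetic TRN generator with planted ground truth.

The generator emulates the large-scale statistics of bacterial
transcriptional regulatory networks:

* a small fraction of nodes are regulators and only they emit edges;
* regulator out-degrees are heterogeneous (truncated power law:
  a few global hubs send most links);
* in-degrees are compact, concentrated around a characteristic mean;
* edges carry +/-1 signs, with a tunable fraction of inhibitions;
* nodes belong to planted modules and regulators preferentially target
  their own module (``p_in`` vs ``p_out``);
* exact feed-forward loops, cascades and mutual dyads are planted on
  top of the random background;
* every link carries experimental-evidence tags (BA / TELC), with a
  planted deficit of well-characterized links (WCLs) inside the
  topologically suspicious subset.

The planted structures are returned as :class:`GroundTruth` so that
community detection, motif statistics and the evidence-bias pipeline
can be tested for parameter recovery without any external dataset.

Out-degree draws are rescaled so that the expected number of links is
``mean_in_degree * n_nodes``; ``p_in``/``p_out`` then act as relative
target weights, which preserves both the degree heterogeneity and the
planted module assortativity (the three constraints cannot all hold
verbatim at once).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import networkx as nx
import numpy as np

from .bias import find_suspicious
from .mesoscale import Partition
from .model import (
    EdgeRecord,
    EvidenceTag,
    NetworkView,
    NodeRecord,
    RegulatoryNetwork,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_topology",
    "assign_signs",
    "assign_evidence",
    "generate",
    "planted_partition_benchmark",
    "write_ground_truth",
    "read_ground_truth",
]

_BA_TAGS = ("chip", "emsa", "footprinting")
_TELC_TAGS = ("microarray", "rtpcr", "mutant_expression")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic TRN; defaults give an E. coli-scale
    network (~1000 nodes, mean in-degree 2.5, ~26% WCL background)."""

    n_nodes: int = 1000
    regulator_fraction: float = 0.08
    out_degree_exponent: float = 2.0
    #: largest out-degree, as a fraction of n_nodes: even global regulator
    #: hubs control only a minority of the genome
    out_degree_cap_fraction: float = 0.25
    mean_in_degree: float = 2.5
    n_modules: int = 5
    p_in: float = 0.3
    p_out: float = 0.01
    negative_sign_fraction: float = 0.35
    n_planted_ffl: int = 250
    n_planted_cascades: int = 100
    n_planted_mutual: int = 12
    wcl_background_rate: float = 0.26
    wcl_suspicious_deficit: float = 0.10
    functional_mixing: float = 0.10
    sigma_fraction: float = 0.15  # fraction of regulators that are sigma factors
    forbid_feedback: bool = False  # emit a strictly feedback-free topology
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "regulator_fraction",
            "negative_sign_fraction",
            "wcl_background_rate",
            "wcl_suspicious_deficit",
            "functional_mixing",
            "sigma_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.regulator_fraction < 1.0:
            raise ValueError("regulator_fraction must be in (0, 1)")
        if self.wcl_background_rate - self.wcl_suspicious_deficit < 0:
            raise ValueError("wcl_background_rate - wcl_suspicious_deficit < 0")
        if not self.p_in > self.p_out:
            raise ValueError("need p_in > p_out")
        if self.n_nodes < 3 or self.mean_in_degree <= 0 or self.n_modules < 1:
            raise ValueError("degenerate spec")
        if self.forbid_feedback and self.n_planted_mutual > 0:
            raise ValueError("cannot plant mutual dyads in a feedback-free network")


@dataclass
class GroundTruth:
    """Planted structures of one synthetic network."""

    planted_partition: Partition
    planted_functional_partition: Partition
    ffl_triples: tuple[tuple[str, str, str], ...]
    cascade_triples: tuple[tuple[str, str, str], ...]
    mutual_pairs: tuple[tuple[str, str], ...]
    wcl_flags: dict[tuple[str, str], bool] = field(default_factory=dict)
    seed: int = 0


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _power_law_degrees(
    rng: np.random.Generator, n: int, alpha: float, k_max: int
) -> np.ndarray:
    """Continuous inverse-CDF power-law draws (k >= 1), floored, truncated."""
    u = rng.random(n)
    if alpha == 1.0:
        k = np.exp(u * np.log(k_max))
    else:
        a = 1.0 - alpha
        k = (1.0 + u * (k_max**a - 1.0)) ** (1.0 / a)
    return np.minimum(np.floor(k).astype(int), k_max)


def generate_topology(spec: SyntheticSpec) -> tuple[RegulatoryNetwork, GroundTruth]:
    """Random module-structured topology plus planted motifs.

    Deterministic for a fixed spec (including its seed).
    """
    n = spec.n_nodes
    rng = _rng(spec.seed, 0)
    width = len(str(n - 1))
    ids = [f"g{i:0{width}d}" for i in range(n)]

    n_reg = max(2, round(spec.regulator_fraction * n))
    reg_idx = np.sort(rng.choice(n, size=n_reg, replace=False))
    is_reg = np.zeros(n, dtype=bool)
    is_reg[reg_idx] = True
    n_sigma = round(spec.sigma_fraction * n_reg)
    sigma_idx = set(rng.choice(reg_idx, size=n_sigma, replace=False).tolist())

    modules = rng.integers(0, spec.n_modules, size=n)

    # -- random background: rescaled power-law out-degrees, module-biased targets
    l_target = round(spec.mean_in_degree * n)
    k_cap = max(2, min(n - 1, int(spec.out_degree_cap_fraction * n)))
    raw = _power_law_degrees(rng, n_reg, spec.out_degree_exponent, k_cap)
    # rescale to the target link count, redistributing any mass the cap
    # cuts off the hubs (water-filling keeps the expected total at l_target)
    expected = raw * (l_target / raw.sum())
    for _ in range(100):
        over = expected > k_cap
        excess = float((expected[over] - k_cap).sum())
        expected[over] = k_cap
        free = ~over
        if excess < 1e-9 or not free.any():
            break
        expected[free] *= 1.0 + excess / expected[free].sum()
    k_out = np.floor(expected).astype(int)
    k_out += rng.random(n_reg) < (expected - k_out)
    k_out = np.minimum(k_out, k_cap)

    edges: set[tuple[int, int]] = set()
    for r_pos, i in enumerate(reg_idx):
        k = int(k_out[r_pos])
        if k == 0:
            continue
        w = np.where(modules == modules[i], spec.p_in, spec.p_out).astype(float)
        w[i] = 0.0
        w /= w.sum()
        targets = rng.choice(n, size=k, replace=False, p=w)
        for t in targets:
            if spec.forbid_feedback and (int(t), int(i)) in edges:
                continue
            edges.add((int(i), int(t)))

    def _can_add(triple_edges: tuple[tuple[int, int], ...]) -> bool:
        if not spec.forbid_feedback:
            return True
        return all((v, u) not in edges and (v, u) not in triple_edges
                   for u, v in triple_edges)

    # -- planted motifs (exact subgraphs added on top of the background)
    def _sample_triples(count: int, kind: str) -> list[tuple[int, int, int]]:
        if count == 0:
            return []
        if n_reg < 2 or n < 3:
            raise ValueError(f"spec cannot plant {kind}: too few regulators/nodes")
        if count > n_reg * (n_reg - 1) * (n - 2) // 4:
            raise ValueError(f"requested {count} planted {kind}, not enough triples")
        seen: set[tuple[int, int, int]] = set()
        out: list[tuple[int, int, int]] = []
        guard = 0
        while len(out) < count:
            guard += 1
            if guard > 100 * count + 1000:
                raise ValueError(f"could not place {count} planted {kind}")
            u, v = rng.choice(reg_idx, size=2, replace=False)
            w = int(rng.integers(0, n))
            if w in (u, v):
                continue
            trip = (int(u), int(v), int(w))
            if trip in seen:
                continue
            if kind == "FFLs":
                trip_edges = ((trip[0], trip[1]), (trip[0], trip[2]), (trip[1], trip[2]))
            else:
                trip_edges = ((trip[0], trip[1]), (trip[1], trip[2]))
            if not _can_add(trip_edges):
                continue
            seen.add(trip)
            out.append(trip)
            edges.update(trip_edges)
        return out

    ffl_triples = _sample_triples(spec.n_planted_ffl, "FFLs")
    cascade_triples = _sample_triples(spec.n_planted_cascades, "cascades")

    # Mutual dyads are planted among a small pool of hub regulators:
    # feedback loops in real TRNs concentrate on globally acting,
    # mutually cross-regulating regulators, and the sharing of endpoints
    # is what lets the 2-mutual and 3-mutual triad classes fluctuate in
    # the switching null ensemble.
    mutual_pairs: list[tuple[int, int]] = []
    if spec.n_planted_mutual:
        pool_size = spec.n_planted_mutual
        while pool_size * (pool_size - 1) // 2 < spec.n_planted_mutual:
            pool_size += 1
        pool_size = max(4, min(pool_size, n_reg))
        if pool_size * (pool_size - 1) // 2 < spec.n_planted_mutual:
            raise ValueError("too many planted mutual dyads for the regulator set")
        by_degree = reg_idx[np.argsort(-k_out)]
        pool = by_degree[:pool_size]
        seen_pairs: set[tuple[int, int]] = set()
        guard = 0
        while len(mutual_pairs) < spec.n_planted_mutual:
            guard += 1
            if guard > 100 * spec.n_planted_mutual + 1000:
                raise ValueError("could not place planted mutual dyads")
            u, v = rng.choice(pool, size=2, replace=False)
            pair = (int(min(u, v)), int(max(u, v)))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            mutual_pairs.append(pair)
        for u, v in mutual_pairs:
            edges.update({(u, v), (v, u)})

    # -- functional categories: one per module, corrupted with prob mixing;
    #    regulators get a transversal regulatory label (excluded downstream)
    categories = np.array([f"cat_{m}" for m in modules], dtype=object)
    flip = rng.random(n) < spec.functional_mixing
    if spec.n_modules > 1:
        for i in np.flatnonzero(flip):
            alt = int(rng.integers(0, spec.n_modules - 1))
            if alt >= modules[i]:
                alt += 1
            categories[i] = f"cat_{alt}"

    nodes = []
    for i in range(n):
        if is_reg[i]:
            role = "sigma_factor" if i in sigma_idx else "transcription_factor"
            cat = "regulatory_proteins"
        else:
            role = "target_only"
            cat = str(categories[i])
        nodes.append(NodeRecord(ids[i], role=role, functional_category=cat))

    net = RegulatoryNetwork(
        nodes,
        (EdgeRecord(ids[u], ids[v]) for u, v in sorted(edges)),
        name=f"synthetic(seed={spec.seed})",
    )
    non_reg = [ids[i] for i in range(n) if not is_reg[i]]
    truth = GroundTruth(
        planted_partition=Partition({ids[i]: int(modules[i]) for i in range(n)}),
        planted_functional_partition=Partition(
            {i_: f"cat_{modules[k]}" for k, i_ in enumerate(ids) if i_ in set(non_reg)}
        ),
        ffl_triples=tuple((ids[u], ids[v], ids[w]) for u, v, w in ffl_triples),
        cascade_triples=tuple((ids[u], ids[v], ids[w]) for u, v, w in cascade_triples),
        mutual_pairs=tuple((ids[u], ids[v]) for u, v in mutual_pairs),
        seed=spec.seed,
    )
    return net, truth


def assign_signs(
    net: RegulatoryNetwork,
    spec: SyntheticSpec,
    truth: Optional[GroundTruth] = None,
) -> RegulatoryNetwork:
    """Draw +/-1 signs; planted FFLs are made sign-coherent.

    Each edge is independently inhibitory with probability
    ``negative_sign_fraction``; the direct edge of every planted FFL is
    then overwritten with the product of its two path-edge signs, so
    planted FFLs land in the topologically suspicious subset.
    """
    rng = _rng(spec.seed, 1)
    keys = sorted(net.edges)
    signs = {
        k: -1 if rng.random() < spec.negative_sign_fraction else 1 for k in keys
    }
    if truth is not None:
        for u, v, w in truth.ffl_triples:
            signs[(u, w)] = signs[(u, v)] * signs[(v, w)]
    return RegulatoryNetwork(
        net.nodes.values(),
        (
            EdgeRecord(e.source, e.target, sign=signs[(e.source, e.target)],
                       evidence=e.evidence)
            for e in net
        ),
        name=net.name,
    )


def assign_evidence(
    net: RegulatoryNetwork,
    spec: SyntheticSpec,
    truth: Optional[GroundTruth] = None,
) -> RegulatoryNetwork:
    """Attach BA/TELC evidence tags with a WCL deficit on suspicious links.

    A link is made a WCL (one tag of each category) with probability
    ``wcl_background_rate``, reduced by ``wcl_suspicious_deficit``
    inside the suspicious set; otherwise it gets a single tag of one
    random category, so every link carries at least one tag.
    """
    rng = _rng(spec.seed, 2)
    suspicious = find_suspicious(net).edges
    if not suspicious and spec.wcl_suspicious_deficit > 0:
        warnings.warn(
            "suspicious set is empty; background WCL rate applied everywhere",
            stacklevel=2,
        )
    rate_in = spec.wcl_background_rate - spec.wcl_suspicious_deficit
    new_edges = []
    for key in sorted(net.edges):
        e = net.edges[key]
        rate = rate_in if key in suspicious else spec.wcl_background_rate
        wcl = bool(rng.random() < rate)
        if truth is not None:
            truth.wcl_flags[key] = wcl
        if wcl:
            tags = frozenset(
                {
                    EvidenceTag(str(rng.choice(_BA_TAGS)), "BA"),
                    EvidenceTag(str(rng.choice(_TELC_TAGS)), "TELC"),
                }
            )
        elif rng.random() < 0.5:
            tags = frozenset({EvidenceTag(str(rng.choice(_BA_TAGS)), "BA")})
        else:
            tags = frozenset({EvidenceTag(str(rng.choice(_TELC_TAGS)), "TELC")})
        new_edges.append(EdgeRecord(e.source, e.target, sign=e.sign, evidence=tags))
    return RegulatoryNetwork(net.nodes.values(), new_edges, name=net.name)


def generate(spec: SyntheticSpec) -> tuple[RegulatoryNetwork, GroundTruth]:
    """Full pipeline: topology, signs, evidence.  Seed-deterministic."""
    net, truth = generate_topology(spec)
    net = assign_signs(net, spec, truth)
    net = assign_evidence(net, spec, truth)
    return net, truth


def planted_partition_benchmark(
    n_modules: int = 4,
    module_size: int = 25,
    p_in: float = 0.3,
    p_out: float = 0.01,
    seed: int = 0,
) -> tuple[NetworkView, Partition]:
    """Undirected planted-partition benchmark graph and its planted partition.

    The standard community-recovery benchmark: ``n_modules`` groups of
    ``module_size`` nodes, within-group edge probability ``p_in``,
    between-group ``p_out``.
    """
    g = nx.planted_partition_graph(n_modules, module_size, p_in, p_out, seed=seed)
    n = n_modules * module_size
    width = len(str(n - 1))
    ids = tuple(f"v{i:0{width}d}" for i in range(n))
    m = np.zeros((n, n))
    for u, v in g.edges():
        m[u, v] = m[v, u] = 1.0
    planted = Partition({ids[i]: i // module_size for i in range(n)})
    return NetworkView(level="UU", nodes=ids, matrix=m), planted


# ---------------------------------------------------------------------------
# ground-truth sidecar (structured text)
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "planted_partition": {k: v for k, v in truth.planted_partition.assignment.items()},
        "planted_functional_partition": {
            k: v for k, v in truth.planted_functional_partition.assignment.items()
        },
        "ffl_triples": [list(t) for t in truth.ffl_triples],
        "cascade_triples": [list(t) for t in truth.cascade_triples],
        "mutual_pairs": [list(p) for p in truth.mutual_pairs],
        "wcl_flags": {f"{u}\t{v}": flag for (u, v), flag in truth.wcl_flags.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_partition=Partition(payload["planted_partition"]),
        planted_functional_partition=Partition(payload["planted_functional_partition"]),
        ffl_triples=tuple(tuple(t) for t in payload["ffl_triples"]),
        cascade_triples=tuple(tuple(t) for t in payload["cascade_triples"]),
        mutual_pairs=tuple(tuple(p) for p in payload["mutual_pairs"]),
        wcl_flags={
            tuple(k.split("\t")): v for k, v in payload["wcl_flags"].items()
        },
        seed=payload["seed"],
    )
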