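"""Mesoscale analysis: signed/directed modularity at multiple resolutions.

The quality of a partition is measured with the signed generalization of
modularity,

    Q = w+/(w+ + w-) * Q+  -  w-/(w+ + w-) * Q-,

where ``w+`` (``w-``) is the total positive (negative) weight and ``Q+``
(``Q-``) accumulates, over same-community ordered node pairs, the
deviation of the positive (negative) weights from a strength-preserving
null model.  Positive links pull nodes into common modules; negative
links push them apart.  For directed views the null term for a pair
(i, j) is out-strength(i) * in-strength(j) / w; for undirected
(symmetric) views this reduces to the familiar k_i k_j / 2w form.

Multi-resolution screening follows the uniform self-loop prescription:
the adjacency is rescaled as ``A_r = A + I r`` and modularity is
optimized for each ``r`` on a grid.  Small (or negative) ``r`` exposes
coarse structure, large ``r`` fine structure; ranges of ``r`` with a
stable number of modules ("plateaus") mark robust topological scales.

Partitions are compared with the Asymmetric Wallace index
``AW(A, B) = sum_ab M_ab (M_ab - 1) / sum_a M_a. (M_a. - 1)``,
the probability that two nodes co-clustered in A are co-clustered in B
— i.e. how strongly A is embedded in B, which tolerates the two
partitions living at different resolution scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .model import NetworkView, RegulatoryNetwork

__all__ = [
    "Partition",
    "RescaledAdjacency",
    "ModularityValue",
    "MesoscaleScreen",
    "ConfusionMatrix",
    "Plateau",
    "modularity",
    "rescale",
    "optimize_partition",
    "screen_resolution",
    "detect_plateaus",
    "confusion_matrix",
    "asymmetric_wallace",
    "functional_node_filter",
    "EXCLUDED_FUNCTIONAL_CATEGORIES",
]

#: Functional labels excluded from topology-vs-function comparisons:
#: unannotated genes and genes with transversal regulatory roles.
EXCLUDED_FUNCTIONAL_CATEGORIES = frozenset(
    {
        "conserved_hypothetical",
        "unknown",
        "regulatory_proteins",
        "information_pathways",
    }
)


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one community."""

    assignment: Mapping[str, object]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def nodes(self) -> set[str]:
        return set(self.assignment)

    def communities(self) -> dict[object, set[str]]:
        out: dict[object, set[str]] = {}
        for node, comm in self.assignment.items():
            out.setdefault(comm, set()).add(node)
        return out

    def restrict(self, nodes: Iterable[str]) -> "Partition":
        keep = set(nodes)
        return Partition({n: c for n, c in self.assignment.items() if n in keep})

    def labels_for(self, order: Sequence[str]) -> np.ndarray:
        """Integer labels (0..C-1) following ``order``."""
        ids = {c: k for k, c in enumerate(dict.fromkeys(self.assignment[n] for n in order))}
        return np.array([ids[self.assignment[n]] for n in order], dtype=int)

    @staticmethod
    def from_labels(order: Sequence[str], labels: Sequence[int]) -> "Partition":
        return Partition({n: int(c) for n, c in zip(order, labels)})


@dataclass(frozen=True)
class RescaledAdjacency:
    """Adjacency with a uniform self-loop ``r`` added: ``A_r = A + I r``."""

    base: NetworkView
    r: float
    matrix: np.ndarray

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.base.nodes


@dataclass(frozen=True)
class ModularityValue:
    q_total: float
    q_pos: float
    q_neg: float
    w_pos: float
    w_neg: float


@dataclass(frozen=True)
class ScreenPoint:
    r: float
    normalized_r: float
    partition: Partition
    modularity: ModularityValue

    @property
    def n_communities(self) -> int:
        return self.partition.n_communities


@dataclass(frozen=True)
class MesoscaleScreen:
    points: tuple[ScreenPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    def n_communities(self) -> list[int]:
        return [p.n_communities for p in self.points]


@dataclass(frozen=True)
class Plateau:
    r_start: float
    r_end: float
    start_index: int
    end_index: int  # inclusive
    n_communities: int

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts M_ab of nodes shared by community a of A and b of B."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

MatrixSource = Union[NetworkView, RescaledAdjacency]


def _matrix_and_nodes(src: MatrixSource) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(src, RescaledAdjacency):
        return src.matrix, src.nodes
    return src.matrix, src.nodes


def _signed_parts(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = np.clip(matrix, 0.0, None)
    neg = np.clip(-matrix, 0.0, None)
    return pos, neg


def _q_one_sign(w_s: np.ndarray, labels: np.ndarray) -> float:
    """Q for one sign component (weights >= 0); 0 if the component is empty."""
    total = w_s.sum()
    if total <= 0:
        return 0.0
    n_comm = labels.max() + 1
    onehot = np.zeros((len(labels), n_comm))
    onehot[np.arange(len(labels)), labels] = 1.0
    internal = float(np.einsum("ic,ij,jc->", onehot, w_s, onehot))
    s_out = onehot.T @ w_s.sum(axis=1)
    s_in = onehot.T @ w_s.sum(axis=0)
    return internal / total - float(s_out @ s_in) / total**2


def modularity(src: MatrixSource, part: Partition) -> ModularityValue:
    """Signed, directed modularity of a partition on a (rescaled) view.

    Self-loop and rescaling weights sit on the diagonal and enter both
    the strengths and the same-community sums.  Raises ``KeyError`` if
    the partition misses a node of the view.
    """
    matrix, nodes = _matrix_and_nodes(src)
    missing = set(nodes) - part.nodes
    if missing:
        raise KeyError(f"partition misses nodes of the view: {sorted(missing)[:5]}")
    labels = part.labels_for(nodes)
    return _modularity_from_labels(matrix, labels)


def _modularity_from_labels(matrix: np.ndarray, labels: np.ndarray) -> ModularityValue:
    pos, neg = _signed_parts(matrix)
    w_pos, w_neg = float(pos.sum()), float(neg.sum())
    q_pos = _q_one_sign(pos, labels)
    q_neg = _q_one_sign(neg, labels)
    w_tot = w_pos + w_neg
    q_total = 0.0 if w_tot == 0 else (w_pos * q_pos - w_neg * q_neg) / w_tot
    return ModularityValue(q_total, q_pos, q_neg, w_pos, w_neg)


def rescale(view: NetworkView, r: float) -> RescaledAdjacency:
    """``A_r = A + I r``: add a uniform self-loop of strength r to every node."""
    matrix = view.matrix + r * np.eye(view.n_nodes)
    return RescaledAdjacency(base=view, r=float(r), matrix=matrix)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


class _QState:
    """Incremental bookkeeping for single-node moves and pair merges."""

    def __init__(self, matrix: np.ndarray, labels: np.ndarray):
        self.pos, self.neg = _signed_parts(matrix)
        self.w_pos = float(self.pos.sum())
        self.w_neg = float(self.neg.sum())
        self.w_tot = self.w_pos + self.w_neg
        self.out_p = self.pos.sum(axis=1)
        self.in_p = self.pos.sum(axis=0)
        self.out_n = self.neg.sum(axis=1)
        self.in_n = self.neg.sum(axis=0)
        self.labels = labels.copy()
        self.n = len(labels)
        self._rebuild_aggregates()

    def _rebuild_aggregates(self) -> None:
        n_comm = self.labels.max() + 1
        self.So_p = np.bincount(self.labels, weights=self.out_p, minlength=n_comm)
        self.Si_p = np.bincount(self.labels, weights=self.in_p, minlength=n_comm)
        self.So_n = np.bincount(self.labels, weights=self.out_n, minlength=n_comm)
        self.Si_n = np.bincount(self.labels, weights=self.in_n, minlength=n_comm)
        self.sizes = np.bincount(self.labels, minlength=n_comm)

    # -- quality ------------------------------------------------------
    def q(self) -> float:
        return _modularity_from_labels(
            self.pos - self.neg, _compress_labels(self.labels)
        ).q_total

    # -- single-node moves --------------------------------------------
    def move_gains(self, i: int) -> tuple[np.ndarray, int]:
        """Gain in Q for moving node i into each community (plus one empty slot).

        Returns (gains, current_community); gains[current] == 0.
        """
        c0 = self.labels[i]
        n_comm = len(self.sizes)
        n_slots = n_comm + 1  # trailing slot = fresh empty community
        lo_p = np.bincount(self.labels, weights=self.pos[i], minlength=n_comm)
        li_p = np.bincount(self.labels, weights=self.pos[:, i], minlength=n_comm)
        lo_n = np.bincount(self.labels, weights=self.neg[i], minlength=n_comm)
        li_n = np.bincount(self.labels, weights=self.neg[:, i], minlength=n_comm)
        gains = np.zeros(n_slots)
        if self.w_tot == 0:
            return gains, c0

        def one_sign(lo, li, diag, so_i, si_i, So, Si, w_s):
            if w_s <= 0:
                return np.zeros(n_slots)
            lo = np.append(lo, 0.0)
            li = np.append(li, 0.0)
            So_t = np.append(So, 0.0)
            Si_t = np.append(Si, 0.0)
            # internal-weight change: leave c0, join c
            d_w = (lo + li + diag) - (lo[c0] + li[c0] - diag)
            d_null = (
                -So_t[c0] * si_i
                - so_i * Si_t[c0]
                + So_t * si_i
                + so_i * Si_t
                + 2.0 * so_i * si_i
            )
            d_q = d_w / w_s - d_null / w_s**2
            d_q[c0] = 0.0
            return d_q * w_s  # weighted by w_s, combined below

        g_p = one_sign(
            lo_p, li_p, self.pos[i, i], self.out_p[i], self.in_p[i],
            self.So_p, self.Si_p, self.w_pos,
        )
        g_n = one_sign(
            lo_n, li_n, self.neg[i, i], self.out_n[i], self.in_n[i],
            self.So_n, self.Si_n, self.w_neg,
        )
        gains = (g_p - g_n) / self.w_tot
        gains[c0] = 0.0
        return gains, c0

    def apply_move(self, i: int, c_new: int) -> None:
        c0 = self.labels[i]
        if c_new == len(self.sizes):  # fresh community
            for arr_name in ("So_p", "Si_p", "So_n", "Si_n"):
                setattr(self, arr_name, np.append(getattr(self, arr_name), 0.0))
            self.sizes = np.append(self.sizes, 0)
        self.labels[i] = c_new
        self.So_p[c0] -= self.out_p[i]; self.So_p[c_new] += self.out_p[i]
        self.Si_p[c0] -= self.in_p[i]; self.Si_p[c_new] += self.in_p[i]
        self.So_n[c0] -= self.out_n[i]; self.So_n[c_new] += self.out_n[i]
        self.Si_n[c0] -= self.in_n[i]; self.Si_n[c_new] += self.in_n[i]
        self.sizes[c0] -= 1
        self.sizes[c_new] += 1

    def node_fitness(self) -> np.ndarray:
        """Per-node contribution to Q within its own community (lower = worse)."""
        onehot = np.zeros((self.n, len(self.sizes)))
        onehot[np.arange(self.n), self.labels] = 1.0
        fit = np.zeros(self.n)
        member = onehot[:, self.labels].T  # member[i, j] = 1 if j in comm(i)
        if self.w_pos > 0:
            obs = (self.pos * member).sum(axis=1) + (self.pos.T * member).sum(axis=1)
            exp = (
                self.out_p * self.Si_p[self.labels] + self.in_p * self.So_p[self.labels]
            ) / self.w_pos
            fit += (obs - exp) / self.w_tot
        if self.w_neg > 0:
            obs = (self.neg * member).sum(axis=1) + (self.neg.T * member).sum(axis=1)
            exp = (
                self.out_n * self.Si_n[self.labels] + self.in_n * self.So_n[self.labels]
            ) / self.w_neg
            fit -= (obs - exp) / self.w_tot
        return fit


def _compress_labels(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _greedy_agglomeration(matrix: np.ndarray) -> np.ndarray:
    """Newman-style fast agglomeration: merge the best community pair while
    the merge improves Q.  Ties break toward the lowest community index."""
    n = len(matrix)
    pos, neg = _signed_parts(matrix)
    w_pos, w_neg = float(pos.sum()), float(neg.sum())
    w_tot = w_pos + w_neg
    if w_tot == 0:
        return np.zeros(n, dtype=int)
    # community-aggregated quantities; start from singletons
    Cp = pos.copy()
    Cn = neg.copy()
    So_p, Si_p = pos.sum(axis=1), pos.sum(axis=0)
    So_n, Si_n = neg.sum(axis=1), neg.sum(axis=0)
    alive = np.ones(n, dtype=bool)
    parent = np.arange(n)

    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        gain = np.full((len(idx), len(idx)), -np.inf)
        if w_pos > 0:
            cross = Cp[np.ix_(idx, idx)] + Cp[np.ix_(idx, idx)].T
            null = np.outer(So_p[idx], Si_p[idx]) + np.outer(Si_p[idx], So_p[idx])
            gain = (cross - null / w_pos) / w_tot
        else:
            gain = np.zeros((len(idx), len(idx)))
        if w_neg > 0:
            cross_n = Cn[np.ix_(idx, idx)] + Cn[np.ix_(idx, idx)].T
            null_n = np.outer(So_n[idx], Si_n[idx]) + np.outer(Si_n[idx], So_n[idx])
            gain -= (cross_n - null_n / w_neg) / w_tot
        np.fill_diagonal(gain, -np.inf)
        best_flat = int(np.argmax(gain))
        a_loc, b_loc = divmod(best_flat, len(idx))
        if gain[a_loc, b_loc] <= 1e-12:
            break
        a, b = int(idx[min(a_loc, b_loc)]), int(idx[max(a_loc, b_loc)])
        # merge b into a (lowest index wins)
        Cp[a] += Cp[b]; Cp[:, a] += Cp[:, b]
        Cn[a] += Cn[b]; Cn[:, a] += Cn[:, b]
        So_p[a] += So_p[b]; Si_p[a] += Si_p[b]
        So_n[a] += So_n[b]; Si_n[a] += Si_n[b]
        alive[b] = False
        parent[parent == b] = a
    return _compress_labels(parent)


def optimize_partition(
    src: MatrixSource,
    seed: int = 0,
    n_restarts: int = 3,
    eo_rounds: Optional[int] = None,
    tol: float = 1e-12,
) -> tuple[Partition, ModularityValue]:
    """Heuristic maximization of signed/directed modularity.

    Greedy agglomeration seeds each restart; an extremal-optimization
    style refinement (repeatedly relocating low-fitness nodes to their
    best community) and a final exhaustive single-node sweep improve it.
    The returned partition is a local optimum: no single-node move to
    any neighboring or empty community increases Q.  Deterministic for
    a fixed seed.
    """
    matrix, nodes = _matrix_and_nodes(src)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot partition an empty network")
    if eo_rounds is None:
        eo_rounds = 4 * n
    rng = np.random.default_rng(seed)
    best_labels: Optional[np.ndarray] = None
    best_q = -np.inf

    for restart in range(max(1, n_restarts)):
        if restart == 0:
            labels = _greedy_agglomeration(matrix)
        else:
            # random initial grouping, then agglomerated by the sweep
            labels = rng.integers(0, max(2, int(np.sqrt(n))), size=n)
            labels = _compress_labels(labels)
        state = _QState(matrix, labels)

        # EO-style refinement: target low-fitness nodes first
        fails = 0
        for _ in range(eo_rounds):
            fitness = state.node_fitness()
            order = np.argsort(fitness + 1e-9 * rng.random(n))
            # rank-biased pick from the worst end
            pick = order[min(int(rng.exponential(scale=max(1.0, n / 8))), n - 1)]
            gains, _c0 = state.move_gains(int(pick))
            c_best = int(np.argmax(gains))
            if gains[c_best] > tol:
                state.apply_move(int(pick), c_best)
                fails = 0
            else:
                fails += 1
                if fails > 2 * n:
                    break

        # final sweeps: guarantee single-node local optimality
        improved = True
        while improved:
            improved = False
            for i in rng.permutation(n):
                gains, _c0 = state.move_gains(int(i))
                c_best = int(np.argmax(gains))
                if gains[c_best] > tol:
                    state.apply_move(int(i), c_best)
                    improved = True
        q = state.q()
        if q > best_q + tol:
            best_q = q
            best_labels = _compress_labels(state.labels)

    part = Partition.from_labels(nodes, best_labels)
    return part, _modularity_from_labels(matrix, best_labels)


def screen_resolution(
    view: NetworkView,
    r_min: float,
    r_max: float,
    n_points: int = 200,
    seed: int = 0,
    n_restarts: int = 2,
) -> MesoscaleScreen:
    """Optimize modularity of ``A + I r`` on an r-grid of ``n_points`` values.

    Each grid point gets its own deterministic child seed of ``seed``.
    ``normalized_r`` maps the grid to [0, 1] for cross-topology plots.
    """
    if not r_min < r_max:
        raise ValueError("need r_min < r_max")
    grid = np.linspace(r_min, r_max, n_points)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_points) % (2**31)
    points = []
    for r, s in zip(grid, child_seeds):
        resc = rescale(view, float(r))
        part, qval = optimize_partition(resc, seed=int(s), n_restarts=n_restarts)
        points.append(
            ScreenPoint(
                r=float(r),
                normalized_r=float((r - r_min) / (r_max - r_min)),
                partition=part,
                modularity=qval,
            )
        )
    return MesoscaleScreen(points=tuple(points))


def detect_plateaus(screen: MesoscaleScreen, min_run: Optional[int] = None) -> list[Plateau]:
    """Maximal runs of >= min_run consecutive grid points with identical N_c.

    ``min_run`` defaults to 5% of the grid (at least 2 points):
    persistence of the module count across a range of resolutions marks
    a robust topological scale.
    """
    if len(screen) == 0:
        raise ValueError("empty screen")
    if min_run is None:
        min_run = max(2, len(screen) // 20)
    ncs = screen.n_communities()
    plateaus: list[Plateau] = []
    start = 0
    for i in range(1, len(ncs) + 1):
        if i == len(ncs) or ncs[i] != ncs[start]:
            if i - start >= min_run:
                plateaus.append(
                    Plateau(
                        r_start=screen.points[start].r,
                        r_end=screen.points[i - 1].r,
                        start_index=start,
                        end_index=i - 1,
                        n_communities=ncs[start],
                    )
                )
            start = i
    return plateaus


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------


def confusion_matrix(a: Partition, b: Partition) -> ConfusionMatrix:
    """M_ab = number of common nodes in community a of A and b of B.

    Restricted to the node intersection; disjoint node sets are an error.
    """
    common = sorted(a.nodes & b.nodes)
    if not common:
        raise ValueError("partitions share no nodes")
    rows = sorted({a.assignment[n] for n in common}, key=str)
    cols = sorted({b.assignment[n] for n in common}, key=str)
    r_idx = {c: i for i, c in enumerate(rows)}
    c_idx = {c: i for i, c in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for n in common:
        counts[r_idx[a.assignment[n]], c_idx[b.assignment[n]]] += 1
    return ConfusionMatrix(counts=counts, row_labels=tuple(rows), col_labels=tuple(cols))


def asymmetric_wallace(a: Partition, b: Partition) -> Optional[float]:
    """Probability that a pair co-clustered in A is co-clustered in B.

    ``AW(A, B) = sum_ab M_ab (M_ab - 1) / sum_a M_a. (M_a. - 1)``.
    Returns ``None`` (undefined) when every cluster of A restricted to
    the common node set is a singleton — A then has no co-clustered
    pairs to test.
    """
    cm = confusion_matrix(a, b)
    m = cm.counts.astype(float)
    denom = float((cm.row_sums * (cm.row_sums - 1)).sum())
    if denom == 0:
        return None
    return float((m * (m - 1)).sum() / denom)


def functional_node_filter(net: RegulatoryNetwork) -> set[str]:
    """Nodes usable in topology-vs-function comparisons.

    Drops unannotated nodes and the four excluded labels (conserved
    hypotheticals, unknowns, regulatory proteins, information pathways),
    which either carry no functional signal or join the network
    transversally.
    """
    if all(n.functional_category is None for n in net.nodes.values()):
        raise ValueError("no functional annotations present")
    return {
        i
        for i, n in net.nodes.items()
        if n.functional_category is not None
        and n.functional_category not in EXCLUDED_FUNCTIONAL_CATEGORIES
    }
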