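"""Suspicious links, WCL contingency analysis, and the deletion correction.

Expression-based inference techniques cannot distinguish a direct
regulation u -> w from an indirect influence mediated by a secondary
pathway u -> v -> w.  A link u -> w is therefore *topologically
suspicious* when a sign-coherent two-link cascade parallels it:
sign(u->v) * sign(v->w) == sign(u->w).  Links supported by at least one
binding assay (BA) and at least one expression comparison (TELC) are
*well-characterized links* (WCLs) and can be trusted as direct.

If spurious indirect links contaminate the data, the suspicious subset
should be depleted of WCLs relative to the background.  The 2x2 table

            WCL    not WCL
    SL       a        b
    not SL   c        d

is tested with a one-sided Fisher's exact test (alternative: WCL
under-representation among suspicious links).  The correction deletes
the largest number x of poorly characterized suspicious links such that
the WCL fraction among the remaining suspicious links, a / (a+b-x),
still does not exceed the network-wide fraction (a+c) / (a+b+c+d);
deleted links are drawn uniformly at random from the non-WCL suspicious
set, and triad Z-scores / TSPs are recomputed on the corrected network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .model import EdgeRecord, RegulatoryNetwork, remove_sigma_factors
from . import motifs as _motifs

__all__ = [
    "SuspiciousSet",
    "ContingencyTable",
    "FisherResult",
    "CorrectionResult",
    "SigmaExcludedReport",
    "find_suspicious",
    "is_wcl",
    "contingency",
    "fisher_one_sided",
    "correction_count",
    "apply_correction",
    "sigma_excluded_analysis",
]


@dataclass(frozen=True)
class SuspiciousSet:
    """Edges paralleled by a sign-coherent two-link secondary pathway.

    ``witnesses[(u, w)]`` lists the mediating nodes v with coherent
    u -> v -> w cascades.
    """

    edges: frozenset[tuple[str, str]]
    witnesses: dict[tuple[str, str], tuple[str, ...]]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.edges

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of (suspicious vs not) x (WCL vs not)."""

    a: int  # WCL and suspicious
    b: int  # not WCL, suspicious
    c: int  # WCL, not suspicious
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_suspicious(self) -> int:
        return self.a + self.b

    @property
    def n_wcl(self) -> int:
        return self.a + self.c

    @property
    def wcl_fraction_suspicious(self) -> float:
        return self.a / self.n_suspicious if self.n_suspicious else math.nan

    @property
    def wcl_fraction_rest(self) -> float:
        n = self.c + self.d
        return self.c / n if n else math.nan

    @property
    def wcl_fraction_overall(self) -> float:
        return self.n_wcl / self.total if self.total else math.nan


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    degenerate: bool = False  # a zero margin: the test carries no information


@dataclass(frozen=True)
class CorrectionResult:
    n_deleted: int
    deleted_edges: tuple[tuple[str, str], ...]
    corrected_network: RegulatoryNetwork
    z_before: "_motifs.TriadZScores"
    z_after: "_motifs.TriadZScores"
    tsp_before: Optional["_motifs.TSP"]  # None when the profile is undefined
    tsp_after: Optional["_motifs.TSP"]
    seed: int


@dataclass(frozen=True)
class SigmaExcludedReport:
    table: ContingencyTable
    fisher: FisherResult
    wcl_fraction_suspicious: float
    wcl_fraction_rest: float
    n_signed_links: int
    conclusive: bool  # False when the suspicious set is (nearly) empty


def _signed_non_loop_edges(net: RegulatoryNetwork) -> list[EdgeRecord]:
    return [e for e in net if e.sign is not None and not e.is_self_loop]


def find_suspicious(net: RegulatoryNetwork) -> SuspiciousSet:
    """Flag every signed link paralleled by a coherent 2-link cascade.

    Only two-link secondary pathways are considered; unknown-sign edges
    are neither flagged nor used as cascade legs; self-loops are never
    flagged and never serve as legs; the mediating node must differ
    from both endpoints.
    """
    sign: dict[tuple[str, str], int] = {}
    out_adj: dict[str, set[str]] = {}
    in_adj: dict[str, set[str]] = {}
    for e in _signed_non_loop_edges(net):
        sign[(e.source, e.target)] = e.sign
        out_adj.setdefault(e.source, set()).add(e.target)
        in_adj.setdefault(e.target, set()).add(e.source)

    flagged: dict[tuple[str, str], tuple[str, ...]] = {}
    for (u, w), s_direct in sign.items():
        mediators = out_adj.get(u, set()) & in_adj.get(w, set())
        witnesses = tuple(
            sorted(
                v
                for v in mediators
                if v not in (u, w) and sign[(u, v)] * sign[(v, w)] == s_direct
            )
        )
        if witnesses:
            flagged[(u, w)] = witnesses
    return SuspiciousSet(edges=frozenset(flagged), witnesses=flagged)


def is_wcl(edge: EdgeRecord) -> bool:
    """True iff the edge has >= 1 BA tag and >= 1 TELC tag."""
    cats = {t.category for t in edge.evidence}
    return "BA" in cats and "TELC" in cats


def contingency(
    net: RegulatoryNetwork, suspicious: Optional[SuspiciousSet] = None
) -> ContingencyTable:
    """Cross-classify every signed, non-self-loop link by (SL, WCL)."""
    if suspicious is None:
        suspicious = find_suspicious(net)
    a = b = c = d = 0
    for e in _signed_non_loop_edges(net):
        sl = (e.source, e.target) in suspicious
        wcl = is_wcl(e)
        if sl and wcl:
            a += 1
        elif sl:
            b += 1
        elif wcl:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_one_sided(t: ContingencyTable) -> FisherResult:
    """Exact hypergeometric tail P(X <= a) given the table margins.

    The alternative is WCL *under*-representation among suspicious
    links.  A zero margin makes the test degenerate: p = 1 with a flag.
    """
    if min(t.n_suspicious, t.c + t.d, t.n_wcl, t.b + t.d) == 0:
        return FisherResult(p_value=1.0, degenerate=True)
    # log-space hypergeometric CDF: numerically exact for large tables
    logcdf = stats.hypergeom.logcdf(t.a, t.total, t.n_wcl, t.n_suspicious)
    return FisherResult(p_value=float(np.exp(logcdf)))


def correction_count(t: ContingencyTable) -> int:
    """Largest x <= b with a/(a+b-x) <= (a+c)/(a+b+c+d), in exact integers.

    This is the number of poorly characterized suspicious links whose
    deletion pairs the WCL fraction among the remaining suspicious
    links to the whole-network background level.
    """
    if t.n_suspicious == 0:
        raise ValueError("no suspicious links: nothing to correct")
    if t.a == 0:
        return t.b
    if t.n_wcl == 0:
        raise ValueError("background WCL fraction is 0 but a > 0: unreachable")
    # a * total <= (a+c) * (a+b-x)  <=>  a+b-x >= ceil(a*total / (a+c))
    need = -((-t.a * t.total) // t.n_wcl)
    x = t.n_suspicious - need
    return max(0, min(t.b, x))


def apply_correction(
    net: RegulatoryNetwork,
    x: int,
    seed: int = 0,
    R: int = 200,
    n_switch_per_edge: int = 20,
) -> CorrectionResult:
    """Delete x random non-WCL suspicious links; recompute Z-scores/TSPs.

    The ensemble size ``R`` and switching effort apply to both the
    before and after Z-score computations (same master seed, distinct
    streams).
    """
    suspicious = find_suspicious(net)
    candidates = sorted(
        k for k in suspicious.edges if not is_wcl(net.edges[k])
    )
    if x > len(candidates):
        raise ValueError(
            f"asked to delete {x} links but only {len(candidates)} "
            "poorly characterized suspicious links exist"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    chosen_idx = rng.choice(len(candidates), size=x, replace=False) if x else []
    deleted = tuple(candidates[int(i)] for i in sorted(chosen_idx))
    corrected = net.drop_edges(deleted, name=f"{net.name}|corrected")

    seeds = np.random.SeedSequence([seed, 11]).generate_state(2) % (2**31)
    z_before = _motifs.zscores(
        net.project("DU"), R=R, n_switch_per_edge=n_switch_per_edge, seed=int(seeds[0])
    )
    z_after = _motifs.zscores(
        corrected.project("DU"), R=R, n_switch_per_edge=n_switch_per_edge,
        seed=int(seeds[1]),
    )
    def _tsp(z):
        try:
            return _motifs.normalize_tsp(z)
        except ValueError:  # degenerate ensemble on tiny networks
            return None

    return CorrectionResult(
        n_deleted=x,
        deleted_edges=deleted,
        corrected_network=corrected,
        z_before=z_before,
        z_after=z_after,
        tsp_before=_tsp(z_before),
        tsp_after=_tsp(z_after),
        seed=seed,
    )


def sigma_excluded_analysis(
    net: RegulatoryNetwork, min_suspicious: int = 1
) -> SigmaExcludedReport:
    """Re-run the contingency analysis with sigma factors removed.

    Reports the WCL fractions inside and outside the suspicious set on
    the TF-only network; flagged non-conclusive when the suspicious set
    shrinks below ``min_suspicious`` links.
    """
    reduced = remove_sigma_factors(net)
    suspicious = find_suspicious(reduced)
    table = contingency(reduced, suspicious)
    fisher = fisher_one_sided(table)
    return SigmaExcludedReport(
        table=table,
        fisher=fisher,
        wcl_fraction_suspicious=table.wcl_fraction_suspicious,
        wcl_fraction_rest=table.wcl_fraction_rest,
        n_signed_links=table.total,
        conclusive=table.n_suspicious >= min_suspicious,
    )
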