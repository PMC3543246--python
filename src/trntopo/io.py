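"""Plain-text I/O for regulatory networks, annotations and partitions.

Formats (all TSV, UTF-8, ``#``-prefixed comment lines ignored):

* edge list -- header ``source target sign evidence role_source``;
  sign tokens ``+`` / ``-`` / ``?``; evidence serialized as
  comma-separated ``tag:category`` pairs (category ``BA`` or ``TELC``);
  ``role_source`` annotates the source node.
* node annotations -- header ``node_id functional_category role``;
  ``functional_category`` may be ``-`` (absent).
* partition -- header ``node_id community_id``.

Duplicate (source, target) rows in an edge list are merged by unioning
their evidence tags; two duplicate rows with conflicting explicit signs
are a consistency error.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Union

from .model import (
    EdgeRecord,
    EvidenceTag,
    NodeRecord,
    RegulatoryNetwork,
    ROLES,
)

__all__ = [
    "read_network",
    "write_network",
    "read_annotations",
    "write_annotations",
    "apply_annotations",
    "read_partition",
    "write_partition",
    "ParseError",
]

PathLike = Union[str, "os.PathLike[str]"]

_SIGN_TOKENS = {
    "+": 1, "1": 1, "+1": 1,
    "-": -1, "-1": -1,
    "?": None, "unknown": None, "na": None, "": None,
}


class ParseError(ValueError):
    """Malformed row in a TSV input; message names the line number."""


def _sign_token(sign: Optional[int]) -> str:
    return {1: "+", -1: "-", None: "?"}[sign]


def _parse_sign(token: str, path: PathLike, lineno: int) -> Optional[int]:
    try:
        return _SIGN_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(
            f"{path}:{lineno}: bad sign token {token!r} "
            "(expected +, -, 1, -1 or ?)"
        ) from None


def _parse_evidence(token: str, path: PathLike, lineno: int) -> frozenset[EvidenceTag]:
    token = token.strip()
    if token in ("", "-"):
        return frozenset()
    tags = []
    for item in token.split(","):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise ParseError(
                f"{path}:{lineno}: evidence entry {item!r} is not tag:category"
            )
        name, cat = item.rsplit(":", 1)
        try:
            tags.append(EvidenceTag(name, cat))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return frozenset(tags)


def _iter_rows(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_network(
    path: PathLike,
    nodes_path: Optional[PathLike] = None,
    name: Optional[str] = None,
) -> RegulatoryNetwork:
    """Read an edge-list TSV (and optional node-annotation TSV).

    Rows need at least source and target columns; sign, evidence and
    source-role columns are optional.  Source nodes default to role
    ``transcription_factor``, pure targets to ``target_only``; an
    annotation file overrides both.
    """
    net = RegulatoryNetwork(name=name if name is not None else str(path))
    merged: dict[tuple[str, str], dict] = {}
    roles: dict[str, str] = {}
    header_seen = False
    for lineno, cols in _iter_rows(path):
        if not header_seen and cols[0].strip().lower() in ("source", "regulator"):
            header_seen = True
            continue
        if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
            raise ParseError(
                f"{path}:{lineno}: expected at least source and target columns"
            )
        src, tgt = cols[0].strip(), cols[1].strip()
        sign = _parse_sign(cols[2], path, lineno) if len(cols) > 2 else None
        evidence = _parse_evidence(cols[3], path, lineno) if len(cols) > 3 else frozenset()
        if len(cols) > 4 and cols[4].strip() not in ("", "-"):
            role = cols[4].strip()
            if role not in ROLES:
                raise ParseError(
                    f"{path}:{lineno}: unknown role {role!r} (expected one of {ROLES})"
                )
            prev_role = roles.get(src)
            if prev_role is not None and prev_role != role:
                raise ParseError(
                    f"{path}:{lineno}: conflicting roles for {src!r}: "
                    f"{prev_role!r} vs {role!r}"
                )
            roles[src] = role
        key = (src, tgt)
        if key in merged:
            rec = merged[key]
            if rec["sign"] is not None and sign is not None and rec["sign"] != sign:
                raise ParseError(
                    f"{path}:{lineno}: conflicting signs for duplicate edge "
                    f"{src}->{tgt}"
                )
            if sign is not None:
                rec["sign"] = sign
            rec["evidence"] |= evidence
        else:
            merged[key] = {"sign": sign, "evidence": set(evidence)}

    for (src, tgt) in merged:
        net.ensure_node(src, role=roles.get(src, "transcription_factor"))
    for (src, tgt) in merged:
        net.ensure_node(tgt, role=roles.get(tgt, "target_only"))
    for (src, tgt), rec in merged.items():
        net.add_edge(
            EdgeRecord(src, tgt, sign=rec["sign"], evidence=frozenset(rec["evidence"]))
        )
    if nodes_path is not None:
        apply_annotations(net, read_annotations(nodes_path))
    return net


def write_network(
    net: RegulatoryNetwork,
    path: PathLike,
    nodes_path: Optional[PathLike] = None,
) -> None:
    """Write the edge-list TSV (and, if requested, node annotations).

    ``read_network(path, nodes_path)`` on the result reproduces the
    network exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsign\tevidence\trole_source\n")
        for (src, tgt) in sorted(net.edges):
            e = net.edges[(src, tgt)]
            ev = ",".join(f"{t.name}:{t.category}" for t in sorted(e.evidence)) or "-"
            fh.write(
                f"{src}\t{tgt}\t{_sign_token(e.sign)}\t{ev}\t{net.nodes[src].role}\n"
            )
    if nodes_path is not None:
        write_annotations(net, nodes_path)


def read_annotations(path: PathLike) -> dict[str, NodeRecord]:
    records: dict[str, NodeRecord] = {}
    for lineno, cols in _iter_rows(path):
        if cols[0].strip().lower() == "node_id":
            continue
        if len(cols) < 3:
            raise ParseError(
                f"{path}:{lineno}: expected node_id, functional_category, role"
            )
        node_id = cols[0].strip()
        category = cols[1].strip()
        role = cols[2].strip()
        if role not in ROLES:
            raise ParseError(f"{path}:{lineno}: unknown role {role!r}")
        records[node_id] = NodeRecord(
            node_id,
            role=role,
            functional_category=None if category in ("", "-") else category,
        )
    return records


def write_annotations(net: RegulatoryNetwork, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tfunctional_category\trole\n")
        for node_id in net.node_ids():
            n = net.nodes[node_id]
            cat = n.functional_category if n.functional_category is not None else "-"
            fh.write(f"{node_id}\t{cat}\t{n.role}\n")


def apply_annotations(
    net: RegulatoryNetwork, records: Mapping[str, NodeRecord]
) -> None:
    """Overwrite node records in-place with annotation-file records."""
    for node_id, rec in records.items():
        net.add_node(rec)


def read_partition(path: PathLike) -> dict[str, str]:
    assignment: dict[str, str] = {}
    for lineno, cols in _iter_rows(path):
        if cols[0].strip().lower() == "node_id":
            continue
        if len(cols) < 2:
            raise ParseError(f"{path}:{lineno}: expected node_id, community_id")
        assignment[cols[0].strip()] = cols[1].strip()
    return assignment


def write_partition(assignment: Mapping[str, object], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tcommunity_id\n")
        for node_id in sorted(assignment):
            fh.write(f"{node_id}\t{assignment[node_id]}\n")
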