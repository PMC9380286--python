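"""Weighted protein-interaction network construction.

Edge weights combine two evidence channels: gene co-expression (Pearson
correlation over m sampling points) and GO semantic similarity of the two
endpoints' annotation sets. The product ``Sim_GO(u,v) * PCC+(u,v)`` measures
the association degree of an interacting pair, where ``PCC+`` applies a
configurable negative-correlation policy (default: clamp to 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from imepp.errors import ImeppError, ParseError
from imepp.ontology import GODag, sim_proteins

logger = logging.getLogger(__name__)

#: accepted negative-correlation policies for the expression channel
PCC_POLICIES = ("clamp", "absolute", "raw")


@dataclass(frozen=True, eq=False)
class ExpressionProfile:
    """Per-protein vector of expression levels over m sampling points."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("expression profile must be a 1-D vector")
        if self.m < 2:
            raise ValueError(f"profile for {self.protein_id} has m={self.m} < 2 sampling points")

    @property
    def m(self) -> int:
        return int(self.values.size)


def compute_pcc(u: ExpressionProfile, v: ExpressionProfile) -> float:
    """Pearson correlation of two expression profiles, in [-1, 1].

    Uses the sample standard deviation (divisor m-1), consistent with the
    1/(m-1) prefactor, so identical profiles score exactly 1. A profile with
    zero variance carries no co-expression signal and scores 0.
    """
    if u.m != v.m:
        raise ValueError(f"profiles have different sampling counts: {u.m} != {v.m}")
    m = u.m
    du = u.values - u.values.mean()
    dv = v.values - v.values.mean()
    su = math.sqrt(float(du @ du) / (m - 1))
    sv = math.sqrt(float(dv @ dv) / (m - 1))
    if su == 0.0 or sv == 0.0:
        return 0.0
    r = float(du @ dv) / ((m - 1) * su * sv)
    # guard FP overshoot so downstream [-1,1] contracts hold exactly
    return min(1.0, max(-1.0, r))


def apply_pcc_policy(pcc: float, policy: str = "clamp") -> float:
    """Map a raw correlation onto the non-negative influence scale."""
    if policy == "clamp":
        return max(0.0, pcc)
    if policy == "absolute":
        return abs(pcc)
    if policy == "raw":
        return pcc
    raise ValueError(f"unknown PCC policy {policy!r}; expected one of {PCC_POLICIES}")


def edge_weight(
    u: str,
    v: str,
    expression: Mapping[str, ExpressionProfile],
    annotations: Mapping[str, set[str]],
    dag: GODag,
    pcc_policy: str = "clamp",
) -> float:
    """Weight of the interaction (u, v): ``Sim_GO(u,v) * PCC+(u,v)``.

    Missing expression or annotation for either endpoint zeroes the
    corresponding factor (no evidence contributes no weight); the edge itself
    is retained by the caller.
    """
    pu, pv = expression.get(u), expression.get(v)
    if pu is None or pv is None:
        pcc = 0.0
    else:
        pcc = apply_pcc_policy(compute_pcc(pu, pv), pcc_policy)
    if pcc == 0.0:
        return 0.0
    sim = sim_proteins(annotations.get(u, ()), annotations.get(v, ()), dag)
    return sim * pcc


def build_weighted_pin(
    edges: Iterable[tuple[str, str]],
    expression: Mapping[str, ExpressionProfile],
    annotations: Mapping[str, set[str]],
    dag: GODag,
    pcc_policy: str = "clamp",
) -> nx.Graph:
    """Construct the weighted PIN over all proteins in the edge list.

    Every input edge is kept (weight may be 0); proteins missing from the
    expression or annotation tables stay in the graph so that orthology can
    still rank them.
    """
    edge_list = list(edges)
    if not edge_list:
        raise ImeppError("empty PPI edge list")
    g = nx.Graph()
    sim_cache: dict[tuple[frozenset, frozenset], float] = {}
    for u, v in edge_list:
        if u == v:
            continue
        pu, pv = expression.get(u), expression.get(v)
        if pu is None or pv is None:
            pcc = 0.0
        else:
            pcc = apply_pcc_policy(compute_pcc(pu, pv), pcc_policy)
        if pcc == 0.0:
            w = 0.0
        else:
            tu = frozenset(annotations.get(u, ()))
            tv = frozenset(annotations.get(v, ()))
            key = (tu, tv) if tu <= tv else (tv, tu)
            sim = sim_cache.get(key)
            if sim is None:
                sim = sim_proteins(tu, tv, dag)
                sim_cache[key] = sim
            w = sim * pcc
        g.add_edge(u, v, weight=w)
    return g


def weighted_degree(g: nx.Graph, node: str) -> float:
    """Sum of incident edge weights (the node's topological influence mass)."""
    return float(g.degree(node, weight="weight"))


# -- plain-text readers / writers -------------------------------------------


def read_ppi_edgelist(path: str) -> list[tuple[str, str]]:
    """Read a two-column PPI edge list (TSV/whitespace, ``#`` comments).

    Self-interactions are dropped; duplicate pairs (in either orientation)
    collapse to one, with each pair normalized lexicographically.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError("PPI line needs two protein IDs", path=path, line=lineno)
            a, b = fields[0], fields[1]
            if a == b:
                continue
            pair = (a, b) if a < b else (b, a)
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        raise ParseError("no usable interactions in PPI file", path=path)
    return pairs


def _detect_delimiter(first_line: str) -> str | None:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # any whitespace


def read_expression(path: str) -> dict[str, ExpressionProfile]:
    """Read an expression matrix: first column protein ID, m numeric columns.

    Delimiter (tab/comma/whitespace) and an optional header row are
    auto-detected; all rows must share the same m >= 2.
    """
    profiles: dict[str, ExpressionProfile] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError("empty expression file", path=path)
    delim = _detect_delimiter(lines[0])

    def split(line: str) -> list[str]:
        return [f.strip() for f in (line.split(delim) if delim else line.split())]

    first = split(lines[0])
    has_header = False
    try:
        [float(x) for x in first[1:]]
    except ValueError:
        has_header = True
        logger.info("expression file %s: header row detected and skipped", path)
    m: int | None = None
    for lineno, raw in enumerate(lines[1:] if has_header else lines, 2 if has_header else 1):
        fields = split(raw)
        if len(fields) < 3:
            raise ParseError("expression row needs an ID and >= 2 values", path=path, line=lineno)
        try:
            values = np.array([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric expression value ({exc})", path=path, line=lineno) from exc
        if m is None:
            m = values.size
        elif values.size != m:
            raise ParseError(
                f"inconsistent sampling count: expected {m}, got {values.size}", path=path, line=lineno
            )
        profiles[fields[0]] = ExpressionProfile(fields[0], values)
    return profiles


def write_weighted_edgelist(g: nx.Graph, path: str) -> None:
    """Write ``u<TAB>v<TAB>weight`` with 6-decimal fixed weights, sorted for stable diffs."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# u\tv\tweight\n")
        for u, v in sorted((min(a, b), max(a, b)) for a, b in g.edges):
            fh.write(f"{u}\t{v}\t{g[u][v]['weight']:.6f}\n")


def read_weighted_edgelist(path: str) -> nx.Graph:
    """Read back the TSV produced by :func:`write_weighted_edgelist`."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("weighted edge line needs u, v, weight", path=path, line=lineno)
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError("non-numeric weight", path=path, line=lineno) from exc
            g.add_edge(fields[0], fields[1], weight=w)
    if g.number_of_edges() == 0:
        raise ParseError("no edges in weighted PIN file", path=path)
    return g
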