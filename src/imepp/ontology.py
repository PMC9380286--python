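"""Gene Ontology DAG, Wang-style S-values and semantic similarity.

The similarity of two terms is the Wang measure: each term ``t`` induces
S-values over its ancestor closure ``T_t`` (itself included), decaying by an
edge-type contribution factor along child->parent links, taking the maximum
over paths; two terms are compared by the overlap of their S-value mass.
"""

from __future__ import annotations

import logging
from graphlib import TopologicalSorter
from typing import Iterable, Mapping

from imepp.errors import ImeppError, ParseError

logger = logging.getLogger(__name__)

#: default decay factor per edge type (strictly inside (0,1) for convergence)
DEFAULT_EDGE_CONTRIBUTION = {"is_a": 0.8, "part_of": 0.6}


class GODag:
    """Directed acyclic graph of ontology terms with typed child->parent edges.

    Parameters
    ----------
    edge_contribution:
        Map from edge type (``is_a``, ``part_of``) to a decay factor in (0, 1).
    """

    def __init__(self, edge_contribution: Mapping[str, float] | None = None):
        self._parents: dict[str, list[tuple[str, str]]] = {}
        self._aspect: dict[str, str | None] = {}
        contrib = dict(edge_contribution or DEFAULT_EDGE_CONTRIBUTION)
        for rel, f in contrib.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"edge contribution for {rel!r} must be in (0,1), got {f}")
        self.edge_contribution = contrib
        self._svalue_cache: dict[str, dict[str, float]] = {}

    # -- construction -------------------------------------------------------

    def add_term(self, term: str, aspect: str | None = None) -> None:
        if term not in self._parents:
            self._parents[term] = []
        if aspect is not None:
            self._aspect[term] = aspect
        else:
            self._aspect.setdefault(term, None)

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        """Add a typed child->parent link, creating missing terms."""
        if relation not in self.edge_contribution:
            raise ValueError(f"unknown edge relation {relation!r}")
        self.add_term(child)
        self.add_term(parent)
        self._parents[child].append((parent, relation))
        self._svalue_cache.clear()

    # -- queries ------------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    @property
    def terms(self) -> set[str]:
        return set(self._parents)

    def aspect(self, term: str) -> str | None:
        return self._aspect.get(term)

    def parents(self, term: str) -> list[tuple[str, str]]:
        return self._parents[term]

    def validate_acyclic(self) -> None:
        """Raise :class:`ImeppError` if the term graph has a cycle."""
        ts = TopologicalSorter({t: [p for p, _ in ps] for t, ps in self._parents.items()})
        try:
            ts.prepare()
        except Exception as exc:  # CycleError
            raise ImeppError(f"ontology graph is cyclic: {exc}") from exc

    def ancestors(self, term: str) -> set[str]:
        """Ancestor closure of ``term`` including the term itself."""
        if term not in self._parents:
            raise KeyError(f"unknown term {term!r}")
        seen = {term}
        stack = [term]
        while stack:
            for parent, _ in self._parents[stack.pop()]:
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    # -- Wang S-values and similarities -------------------------------------

    def s_values(self, term: str) -> dict[str, float]:
        """S-value of every term in the ancestor closure of ``term``.

        ``S_term(term) = 1``; for an ancestor ``a``,
        ``S_term(a) = max over child edges (contribution * S_term(child))``,
        the max running over all paths from ``term`` up to ``a``.
        """
        if term not in self._parents:
            raise KeyError(f"unknown term {term!r}")
        cached = self._svalue_cache.get(term)
        if cached is not None:
            return cached

        closure = self.ancestors(term)
        # child-before-parent order within the closure
        ts = TopologicalSorter({t: [p for p, _ in self._parents[t] if p in closure] for t in closure})
        order = list(ts.static_order())
        # static_order yields dependencies (parents) first; walk reversed so
        # each child is final before its parents are relaxed
        s = {t: 0.0 for t in closure}
        s[term] = 1.0
        for t in reversed(order):
            st = s[t]
            if st == 0.0:
                continue
            for parent, rel in self._parents[t]:
                if parent in closure:
                    cand = self.edge_contribution[rel] * st
                    if cand > s[parent]:
                        s[parent] = cand
        self._svalue_cache[term] = s
        return s

    def sim_terms(self, t1: str, t2: str) -> float:
        """Wang semantic similarity of two terms, in [0, 1].

        Terms from different ontology aspects (namespaces) are incomparable
        and score 0.
        """
        if t1 not in self._parents:
            raise KeyError(f"unknown term {t1!r}")
        if t2 not in self._parents:
            raise KeyError(f"unknown term {t2!r}")
        a1, a2 = self._aspect.get(t1), self._aspect.get(t2)
        if a1 is not None and a2 is not None and a1 != a2:
            return 0.0
        s1 = self.s_values(t1)
        s2 = self.s_values(t2)
        common = s1.keys() & s2.keys()
        if not common:
            return 0.0
        num = sum(s1[t] + s2[t] for t in common)
        den = sum(s1.values()) + sum(s2.values())
        # num <= den analytically; guard the ulp overshoot of FP summation
        return min(1.0, num / den)


def sim_term_protein(term: str, annotation: Iterable[str], dag: GODag) -> float:
    """Best similarity between ``term`` and any term annotating a protein."""
    terms = list(annotation)
    if not terms:
        raise ValueError("protein annotation set is empty; apply the unannotated policy first")
    return max(dag.sim_terms(term, t) for t in terms)


def sim_proteins(
    terms_u: Iterable[str],
    terms_v: Iterable[str],
    dag: GODag,
) -> float:
    """Semantic similarity of two proteins from their GO annotation sets.

    Averages the best-match similarity of every term of one protein against
    the other protein's set, in both directions. An unannotated protein has
    no semantic evidence and scores 0 against anything.
    """
    tu, tv = list(terms_u), list(terms_v)
    if not tu or not tv:
        return 0.0
    total = sum(sim_term_protein(t, tv, dag) for t in tu)
    total += sum(sim_term_protein(t, tu, dag) for t in tv)
    return total / (len(tu) + len(tv))


def filter_annotations(
    annotations: Mapping[str, set[str]], dag: GODag
) -> dict[str, set[str]]:
    """Drop annotated terms absent from the DAG (obsolete/unknown), warning once per term."""
    dropped: set[str] = set()
    out: dict[str, set[str]] = {}
    for prot, terms in annotations.items():
        kept = {t for t in terms if t in dag}
        dropped |= terms - kept
        out[prot] = kept
    for t in sorted(dropped):
        logger.warning("annotation term %s not in ontology; dropped", t)
    return out


# -- OBO / GAF / TSV parsing -------------------------------------------------

_NAMESPACE_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


def read_obo(path: str, edge_contribution: Mapping[str, float] | None = None) -> GODag:
    """Parse an OBO 1.2 ontology file into a :class:`GODag`.

    Only ``[Term]`` stanzas are read; ``is_a`` tags and
    ``relationship: part_of`` lines become typed edges. Obsolete terms are
    skipped entirely.
    """
    dag = GODag(edge_contribution=edge_contribution)
    term_id: str | None = None
    in_term = False
    obsolete = False
    aspect: str | None = None
    edges: list[tuple[str, str, str]] = []
    pending: list[tuple[str, str, str]] = []

    def flush() -> None:
        nonlocal term_id, obsolete, aspect
        if in_term and term_id is not None and not obsolete:
            dag.add_term(term_id, aspect=aspect)
            edges.extend(pending)
        term_id = None
        obsolete = False
        aspect = None
        pending.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line:
                continue
            if ":" not in line:
                raise ParseError("malformed OBO tag line", path=path, line=lineno)
            tag, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            tag = tag.strip()
            if tag == "id":
                term_id = value
            elif tag == "namespace":
                aspect = _NAMESPACE_ASPECT.get(value, value)
            elif tag == "is_obsolete" and value == "true":
                obsolete = True
            elif tag == "is_a" and term_id is not None:
                pending.append((term_id, value, "is_a"))
            elif tag == "relationship" and term_id is not None:
                parts = value.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    pending.append((term_id, parts[1], "part_of"))
    flush()
    for child, parent, rel in edges:
        if parent in dag:
            dag.add_edge(child, parent, rel)
        else:
            logger.warning("OBO edge %s -> %s skipped (parent missing or obsolete)", child, parent)
    dag.validate_acyclic()
    return dag


def read_gaf(path: str, exclude_evidence: Iterable[str] = ()) -> dict[str, set[str]]:
    """Parse a GAF 2.x annotation file into protein -> set of GO term IDs.

    Only the DB-object-ID (column 2) and GO-ID (column 5) are used; rows with
    an evidence code (column 7) in ``exclude_evidence`` are skipped.
    """
    excluded = set(exclude_evidence)
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            if raw.startswith("!") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 5:
                raise ParseError("GAF row has fewer than 5 columns", path=path, line=lineno)
            if excluded and len(cols) > 6 and cols[6] in excluded:
                continue
            out.setdefault(cols[1], set()).add(cols[4])
    return out


def read_annotations_tsv(path: str) -> dict[str, set[str]]:
    """Parse the simplified two-column annotation format: ``protein<TAB>GO-ID``."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError("annotation line needs protein and term", path=path, line=lineno)
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def read_annotations(path: str, exclude_evidence: Iterable[str] = ()) -> dict[str, set[str]]:
    """Dispatch on extension: ``.gaf`` -> GAF parser, otherwise simple TSV."""
    if str(path).endswith(".gaf"):
        return read_gaf(path, exclude_evidence=exclude_evidence)
    return read_annotations_tsv(path)
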