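"""Influence scores and the independent-cascade influence discount.

Each protein's influence score (IS) is a convex blend of two normalized
channels:

* ``IS_topo`` — weighted degree over the max weighted degree in the network;
* ``IS_OS`` — orthologous score ``n_u / N`` over the max orthologous score.

``IS = lambda * IS_OS + (1 - lambda) * IS_topo``.

When a node is selected as a seed, each non-seed neighbor v has its
topological channel discounted via

``ID(v) = (Inf_topo(v) - tt(v) - (Inf_topo(v) - tt(v)) * t(v) * p) * p``

the first-order expansion of the exact independent-cascade expectation
``(1-p)^t(v) * (Inf_topo(v) - tt(v)) * p``, where t(v) counts v's seed
neighbors and tt(v) sums the weights of v's edges to seeds. The normalizer
``max Inf_topo`` is frozen at initialization and never recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx

from imepp.errors import DegenerateInputError, ParseError

logger = logging.getLogger(__name__)

TIE_BREAK_POLICIES = ("lexicographic", "insertion")


def quantize_score(x: float) -> float:
    """Round a blended score to 12 decimals.

    Scores that are analytically equal can differ by a few ulps depending on
    the order edge weights were accumulated in; quantizing makes such ties
    exact so the tie-break policy, not rounding noise, decides the ranking.
    """
    return round(x, 12)


@dataclass(frozen=True)
class Params:
    """Run parameters for scoring and selection."""

    lam: float = 0.2
    p: float = 0.001
    k: int = 100
    tie_break: str = "lexicographic"
    pcc_policy: str = "clamp"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0,1], got {self.lam}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"spread probability must be in (0,1), got {self.p}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.tie_break not in TIE_BREAK_POLICIES:
            raise ValueError(f"unknown tie-break policy {self.tie_break!r}")

    def with_(self, **kwargs) -> "Params":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OrthologyTable:
    """Ortholog counts: protein -> number of reference species with an ortholog."""

    counts: dict[str, int]
    n_species: int

    def __post_init__(self):
        if self.n_species <= 0:
            raise ValueError("total reference species count must be positive")
        for prot, n in self.counts.items():
            if not 0 <= n <= self.n_species:
                raise ValueError(
                    f"ortholog count for {prot} out of range: {n} not in [0, {self.n_species}]"
                )

    def os(self, protein: str) -> float:
        """Orthologous score ``n_u / N``; proteins absent from the table score 0."""
        return self.counts.get(protein, 0) / self.n_species


@dataclass
class InfluenceState:
    """Mutable per-protein scoring state driven by seed selection."""

    inf_topo: dict[str, float]
    is_topo: dict[str, float]
    is_os: dict[str, float]
    score: dict[str, float]  # IS = lam*IS_OS + (1-lam)*IS_topo
    t: dict[str, int] = field(default_factory=dict)  # seed-neighbor counts
    tt: dict[str, float] = field(default_factory=dict)  # seed-edge weight sums
    seeds: set[str] = field(default_factory=set)
    max_inf_topo: float = 0.0  # frozen at init; never updated
    lam: float = 0.2
    p: float = 0.001

    def is_seed(self, v: str) -> bool:
        return v in self.seeds


def read_orthology(path: str, n_species: int | None = None) -> OrthologyTable:
    """Read an orthology TSV: ``protein<TAB>n_u`` rows.

    The total species count N is taken from a ``# N=<int>`` comment line if
    present; an explicit ``n_species`` argument overrides the file.
    """
    counts: dict[str, int] = {}
    file_n: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").replace(" ", "")
                if body.upper().startswith("N="):
                    try:
                        file_n = int(body[2:])
                    except ValueError as exc:
                        raise ParseError("bad N= header", path=path, line=lineno) from exc
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError("orthology line needs protein and count", path=path, line=lineno)
            try:
                counts[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError("non-integer ortholog count", path=path, line=lineno) from exc
    n = n_species if n_species is not None else file_n
    if n is None:
        raise ParseError("total species count N not given in file header or argument", path=path)
    return OrthologyTable(counts=counts, n_species=n)


def init_influence(pin: nx.Graph, orthology: OrthologyTable, params: Params) -> InfluenceState:
    """Compute initial influence scores for every protein in the network.

    Raises :class:`DegenerateInputError` when the channel that lambda gives
    nonzero mass to has an all-zero normalizer.
    """
    if pin.number_of_nodes() == 0:
        raise DegenerateInputError("empty network")
    inf_topo = {u: float(pin.degree(u, weight="weight")) for u in pin.nodes}
    max_inf = max(inf_topo.values())
    os_raw = {u: orthology.os(u) for u in pin.nodes}
    max_os = max(os_raw.values())

    if max_inf <= 0.0 and params.lam < 1.0:
        raise DegenerateInputError("all weighted degrees are zero: topology channel uninformative")
    if max_os <= 0.0 and params.lam > 0.0:
        raise DegenerateInputError("all orthologous scores are zero: orthology channel uninformative")

    is_topo = {u: (inf_topo[u] / max_inf if max_inf > 0 else 0.0) for u in pin.nodes}
    is_os = {u: (os_raw[u] / max_os if max_os > 0 else 0.0) for u in pin.nodes}
    lam = params.lam
    score = {u: quantize_score(lam * is_os[u] + (1.0 - lam) * is_topo[u]) for u in pin.nodes}
    return InfluenceState(
        inf_topo=inf_topo,
        is_topo=is_topo,
        is_os=is_os,
        score=score,
        t={u: 0 for u in pin.nodes},
        tt={u: 0.0 for u in pin.nodes},
        seeds=set(),
        max_inf_topo=max_inf,
        lam=lam,
        p=params.p,
    )


def influence_discount(v: str, state: InfluenceState) -> float:
    """Expected residual influence of non-seed node v given its seed neighbors.

    Floored at 0: the linearized form can go negative once ``t(v)*p``
    approaches 1, outside its validity regime.
    """
    if v in state.seeds:
        raise ValueError(f"influence discount undefined for seed node {v!r}")
    residual = state.inf_topo[v] - state.tt[v]
    # tt accumulates edge weights in selection order while inf_topo was summed
    # in adjacency order; snap the rounding dust so an exhausted node scores
    # exactly 0 regardless of summation order
    if residual < 1e-9 * state.inf_topo[v]:
        residual = 0.0
    discount = (residual - residual * state.t[v] * state.p) * state.p
    if discount < 0.0:
        logger.warning("influence discount for %s went negative (t=%d, p=%g); floored at 0",
                       v, state.t[v], state.p)
        return 0.0
    return discount


def influence_discount_exact(v: str, state: InfluenceState) -> float:
    """Exact independent-cascade form ``(1-p)^t * (Inf_topo - tt) * p`` (reference)."""
    if v in state.seeds:
        raise ValueError(f"influence discount undefined for seed node {v!r}")
    residual = state.inf_topo[v] - state.tt[v]
    return (1.0 - state.p) ** state.t[v] * residual * state.p


def update_after_seed(s_new: str, pin: nx.Graph, state: InfluenceState) -> InfluenceState:
    """Discount the topological channel of the non-seed neighbors of a new seed.

    Mutates and returns ``state``. Non-neighbors are untouched; the frozen
    ``max_inf_topo`` normalizer maps the discount back onto the IS scale.
    """
    if s_new not in state.seeds:
        raise ValueError(f"{s_new!r} must be marked as seed before updating neighbors")
    lam = state.lam
    for v in pin.neighbors(s_new):
        if v in state.seeds:
            continue
        state.t[v] += 1
        state.tt[v] += float(pin[s_new][v].get("weight", 0.0))
        discounted = influence_discount(v, state)
        if state.max_inf_topo > 0.0:
            state.is_topo[v] = (discounted / state.p) / state.max_inf_topo
        else:  # lam == 1: topology channel carries no mass anyway
            state.is_topo[v] = 0.0
        state.score[v] = quantize_score(lam * state.is_os[v] + (1.0 - lam) * state.is_topo[v])
    return state
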