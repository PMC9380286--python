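"""Greedy seed selection with an indexed priority queue, plus baselines.

The main loop repeats k times: extract the non-seed node with maximal
influence score, mark it as a seed, and discount the scores of its non-seed
neighbors. A lazy-deletion binary heap gives O(log |V|) amortized
extract/update; stale entries are recognized by comparing the stored score
against the live one.

Baselines: classic degree discount (unweighted degrees, spread probability
p) and plain degree centrality.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx

from imepp.errors import ImeppError
from imepp.influence import InfluenceState, Params, update_after_seed

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedCandidates:
    """Ordered selection result: (protein, score at selection, iteration)."""

    records: tuple[tuple[str, float, int], ...]
    method: str
    params: Params | None = None

    @property
    def proteins(self) -> list[str]:
        return [r[0] for r in self.records]

    def top(self, k: int) -> list[str]:
        return self.proteins[:k]

    def __len__(self) -> int:
        return len(self.records)

    def write_tsv(self, path: str) -> None:
        """``rank<TAB>protein<TAB>score<TAB>method`` rows, 1-based ranks."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# rank\tprotein\tscore\tmethod\n")
            for i, (prot, score, _) in enumerate(self.records, 1):
                fh.write(f"{i}\t{prot}\t{score:.6f}\t{self.method}\n")


def read_ranking_tsv(path: str) -> RankedCandidates:
    records: list[tuple[str, float, int]] = []
    method = "unknown"
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rank, prot, score, method = line.split("\t")[:4]
            records.append((prot, float(score), int(rank) - 1))
    return RankedCandidates(records=tuple(records), method=method)


def _tie_key(nodes: list[str], policy: str) -> Callable[[str], object]:
    if policy == "lexicographic":
        return lambda v: v
    if policy == "insertion":
        order = {v: i for i, v in enumerate(nodes)}
        return lambda v: order[v]
    raise ValueError(f"unknown tie-break policy {policy!r}")


class _MaxQueue:
    """Lazy-deletion max-heap keyed by (score desc, tie key asc)."""

    def __init__(self, scores: dict[str, float], tie_key: Callable[[str], object]):
        self._tie_key = tie_key
        self._live = dict(scores)
        self._heap = [(-s, tie_key(v), v) for v, s in scores.items()]
        heapq.heapify(self._heap)

    def update(self, v: str, score: float) -> None:
        self._live[v] = score
        heapq.heappush(self._heap, (-score, self._tie_key(v), v))

    def pop_max(self) -> tuple[str, float]:
        while self._heap:
            neg, _, v = heapq.heappop(self._heap)
            live = self._live.get(v)
            if live is None or -neg != live:
                continue  # stale or already extracted
            del self._live[v]
            return v, live
        raise IndexError("pop from empty queue")


def select_seeds(
    pin: nx.Graph, state: InfluenceState, k: int, tie_break: str = "lexicographic"
) -> RankedCandidates:
    """Greedily select k essential-protein candidates by maximal IS.

    Equal scores break by the lexicographically smallest protein ID by
    default; ``tie_break="insertion"`` uses graph insertion order instead.
    Mutates ``state`` (seeds marked, neighbor scores discounted).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not state.score:
        raise ImeppError("influence state is uninitialized")
    nodes = list(pin.nodes)
    if k > len(nodes):
        logger.warning("k=%d exceeds |V|=%d; truncating", k, len(nodes))
        k = len(nodes)
    tie_key = _tie_key(nodes, tie_break)
    queue = _MaxQueue(state.score, tie_key)
    records: list[tuple[str, float, int]] = []
    for it in range(k):
        s_new, score = queue.pop_max()
        state.seeds.add(s_new)
        records.append((s_new, score, it))
        update_after_seed(s_new, pin, state)
        for v in pin.neighbors(s_new):
            if v not in state.seeds:
                queue.update(v, state.score[v])
    return RankedCandidates(records=tuple(records), method="imepp")


def degree_discount_baseline(
    pin: nx.Graph, k: int, p: float = 0.001, tie_break: str = "lexicographic"
) -> RankedCandidates:
    """Classic degree-discount heuristic on the unweighted view of the network.

    Maintains ``dd(v) = d(v) - 2*t(v) - (d(v) - t(v))*t(v)*p`` where t(v)
    counts v's seed neighbors, extracting the max each iteration.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = list(pin.nodes)
    if not nodes:
        raise ImeppError("empty network")
    if k > len(nodes):
        logger.warning("k=%d exceeds |V|=%d; truncating", k, len(nodes))
        k = len(nodes)
    deg = {v: float(pin.degree(v)) for v in nodes}
    t = {v: 0 for v in nodes}
    queue = _MaxQueue(deg, _tie_key(nodes, tie_break))
    seeds: set[str] = set()
    records: list[tuple[str, float, int]] = []
    for it in range(k):
        s_new, score = queue.pop_max()
        seeds.add(s_new)
        records.append((s_new, score, it))
        for v in pin.neighbors(s_new):
            if v in seeds:
                continue
            t[v] += 1
            dd = deg[v] - 2.0 * t[v] - (deg[v] - t[v]) * t[v] * p
            queue.update(v, dd)
    return RankedCandidates(records=tuple(records), method="dd")


def degree_centrality_baseline(
    pin: nx.Graph, k: int, tie_break: str = "lexicographic"
) -> RankedCandidates:
    """Top-k by unweighted degree with the stable tie-break."""
    nodes = list(pin.nodes)
    if not nodes:
        raise ImeppError("empty network")
    tie_key = _tie_key(nodes, tie_break)
    ranked = sorted(nodes, key=lambda v: (-pin.degree(v), tie_key(v)))[: min(k, len(nodes))]
    records = tuple((v, float(pin.degree(v)), i) for i, v in enumerate(ranked))
    return RankedCandidates(records=records, method="dc")
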