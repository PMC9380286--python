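"""Top-k evaluation against a gold essential list, and lambda sweeps."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from imepp.errors import ImeppError
from imepp.influence import OrthologyTable, Params, init_influence
from imepp.seed_select import RankedCandidates, select_seeds


def count_correct(ranking: RankedCandidates | Sequence[str], gold: set[str], k: int) -> int:
    """Number of gold essentials among the top-k of a ranking."""
    if not gold:
        raise ImeppError("gold essential set is empty")
    proteins = ranking.proteins if isinstance(ranking, RankedCandidates) else list(ranking)
    if k > len(proteins):
        raise ValueError(f"k={k} exceeds ranking length {len(proteins)}")
    return len(set(proteins[:k]) & gold)


@dataclass
class EvaluationResult:
    """Grid of correct-hit counts, indexed by (lambda, k)."""

    counts: dict[tuple[float, int], int]
    recalls: dict[tuple[float, int], float]
    best_lambda: dict[int, float]  # per k, smallest argmax lambda
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Rows = k, columns = lambda, cells = hit counts."""
        lams = sorted({lam for lam, _ in self.counts})
        ks = sorted({k for _, k in self.counts})
        data = {lam: [self.counts[(lam, k)] for k in ks] for lam in lams}
        return pd.DataFrame(data, index=pd.Index(ks, name="k"))


def lambda_sweep(
    pin: nx.Graph,
    orthology: OrthologyTable,
    gold: set[str],
    lambdas: Iterable[float],
    ks: Iterable[int],
    p: float = 0.001,
    tie_break: str = "lexicographic",
) -> EvaluationResult:
    """Run the full scoring + selection pipeline per lambda and count hits.

    For each lambda a single selection of max(ks) seeds is made; counts for
    smaller k are prefixes of that ranking (selection is greedy-incremental,
    so prefixes coincide with smaller-k runs).
    """
    lam_grid = sorted(set(float(x) for x in lambdas))
    k_grid = sorted(set(int(x) for x in ks))
    if not lam_grid or not k_grid:
        raise ValueError("lambda and k grids must be non-empty")
    if not gold:
        raise ImeppError("gold essential set is empty")
    k_max = min(max(k_grid), pin.number_of_nodes())
    counts: dict[tuple[float, int], int] = {}
    recalls: dict[tuple[float, int], float] = {}
    for lam in lam_grid:
        params = Params(lam=lam, p=p, k=k_max, tie_break=tie_break)
        state = init_influence(pin, orthology, params)
        ranking = select_seeds(pin, state, k_max, tie_break=tie_break)
        for k in k_grid:
            kk = min(k, len(ranking))
            hits = count_correct(ranking, gold, kk)
            counts[(lam, k)] = hits
            recalls[(lam, k)] = hits / len(gold)
    best = {}
    for k in k_grid:
        best[k] = max(lam_grid, key=lambda lam: (counts[(lam, k)], -lam))
    return EvaluationResult(
        counts=counts,
        recalls=recalls,
        best_lambda=best,
        params={"p": p, "tie_break": tie_break, "n_gold": len(gold)},
    )


def read_gold_list(path: str) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        gold = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    if not gold:
        raise ImeppError(f"no proteins in gold list {path}")
    return gold


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
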