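"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (path enumeration, full rescans) and
shares no code with the package internals beyond data types.
"""

import numpy as np

from imepp.ontology import GODag


def brute_s_values(term: str, dag: GODag) -> dict[str, float]:
    """S-values by exhaustive enumeration of all upward paths."""
    out: dict[str, float] = {}

    def walk(node: str, value: float) -> None:
        if value > out.get(node, 0.0):
            out[node] = value
        for parent, rel in dag.parents(node):
            walk(parent, value * dag.edge_contribution[rel])

    walk(term, 1.0)
    return out


def brute_sim_terms(t1: str, t2: str, dag: GODag) -> float:
    if dag.aspect(t1) is not None and dag.aspect(t2) is not None and dag.aspect(t1) != dag.aspect(t2):
        return 0.0
    s1, s2 = brute_s_values(t1, dag), brute_s_values(t2, dag)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / (sum(s1.values()) + sum(s2.values()))


def brute_sim_proteins(terms_u, terms_v, dag: GODag) -> float:
    tu, tv = list(terms_u), list(terms_v)
    if not tu or not tv:
        return 0.0
    total = sum(max(brute_sim_terms(t, t2, dag) for t2 in tv) for t in tu)
    total += sum(max(brute_sim_terms(t, t1, dag) for t1 in tu) for t in tv)
    return total / (len(tu) + len(tv))


def textbook_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Sample correlation via numpy's covariance machinery."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def rescan_greedy(pin, inf_topo, is_os, lam, p, k, max_inf) -> list[str]:
    """From-scratch greedy oracle: recompute every score each iteration.

    For each non-seed node v, recompute t(v) and tt(v) directly from the
    current seed set, apply the linearized influence-discount formula
    (floored at 0), renormalize, blend with the orthology channel, and pick
    the max with lexicographic tie-break.
    """
    seeds: list[str] = []
    seed_set: set[str] = set()
    for _ in range(min(k, pin.number_of_nodes())):
        best = None
        best_score = -1.0
        for v in sorted(pin.nodes):
            if v in seed_set:
                continue
            t = sum(1 for nb in pin.neighbors(v) if nb in seed_set)
            tt = sum(pin[v][nb]["weight"] for nb in pin.neighbors(v) if nb in seed_set)
            residual = inf_topo[v] - tt
            if residual < 1e-9 * inf_topo[v]:  # same exhaustion snap as the package
                residual = 0.0
            discount = max(0.0, (residual - residual * t * p) * p)
            is_topo = (discount / p) / max_inf if max_inf > 0 else 0.0
            # same 12-decimal score quantization as the package contract
            score = round(lam * is_os[v] + (1 - lam) * is_topo, 12)
            if score > best_score:
                best, best_score = v, score
        seeds.append(best)
        seed_set.add(best)
    return seeds
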