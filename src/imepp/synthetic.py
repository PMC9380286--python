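"""Synthetic input bundles with planted essential proteins.

A bundle contains everything the pipeline consumes — PPI edge list,
expression matrix, ontology (OBO), annotations, orthology table and a gold
essential list — generated so that the planted essentials carry signal in
every channel:

* degree-biased placement in a preferential-attachment graph (hubs, but
  overlapping the background degree distribution);
* co-expression: each essential anchors a module sharing a latent
  expression factor with loading sqrt(rho), so within-module pairwise
  correlation is ~= rho;
* annotation: module members share deep ontology terms (high semantic
  similarity), background nodes get shallow near-root terms;
* orthology: ortholog counts drawn from a high-mean distribution for
  essentials and a low-mean one for the background.

Everything is driven by one seeded generator: the same seed yields
byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np

from imepp.errors import ImeppError
from imepp.influence import OrthologyTable
from imepp.ontology import GODag
from imepp.pin_build import ExpressionProfile


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for bundle generation; defaults give a 500-node benchmark."""

    n_nodes: int = 500
    attach_m: int = 3  # preferential-attachment edges per new node
    n_essential: int = 50
    m_samples: int = 12
    rho: float = 0.8  # within-module expression correlation
    dag_depth: int = 3
    dag_branching: int = 4
    n_species: int = 100
    ortho_high_mean: float = 80.0
    ortho_low_mean: float = 20.0
    ortho_sd: float = 8.0
    graph_model: str = "ba"  # "ba" (preferential attachment) or "er"
    er_p: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_essential >= self.n_nodes:
            raise ValueError("n_essential must be smaller than n_nodes")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0,1]")
        for name in ("n_nodes", "attach_m", "n_essential", "m_samples",
                     "dag_depth", "dag_branching", "n_species"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m_samples < 2:
            raise ValueError("m_samples must be >= 2")
        if self.graph_model == "ba" and self.attach_m >= self.n_nodes:
            raise ImeppError("attachment parameter exceeds simple-graph capacity")
        if self.graph_model not in ("ba", "er"):
            raise ValueError(f"unknown graph model {self.graph_model!r}")


@dataclass
class Bundle:
    """In-memory bundle: parsed-equivalent objects plus file writers."""

    edges: list[tuple[str, str]]
    expression: dict[str, ExpressionProfile]
    dag: GODag
    obo_text: str
    annotations: dict[str, set[str]]
    orthology: OrthologyTable
    gold: set[str]
    meta: dict = field(default_factory=dict)

    def write(self, outdir: str) -> dict[str, str]:
        """Write all five inputs plus a manifest; returns the path map."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "ppi": os.path.join(outdir, "ppi.tsv"),
            "expression": os.path.join(outdir, "expression.tsv"),
            "obo": os.path.join(outdir, "go.obo"),
            "annotations": os.path.join(outdir, "annotations.tsv"),
            "orthology": os.path.join(outdir, "orthology.tsv"),
            "gold": os.path.join(outdir, "essential.txt"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        with open(paths["ppi"], "w", encoding="utf-8") as fh:
            fh.write("# protein_a\tprotein_b\n")
            for u, v in sorted((min(a, b), max(a, b)) for a, b in self.edges):
                fh.write(f"{u}\t{v}\n")
        m = next(iter(self.expression.values())).m
        with open(paths["expression"], "w", encoding="utf-8") as fh:
            fh.write("protein\t" + "\t".join(f"s{i+1}" for i in range(m)) + "\n")
            for prot in sorted(self.expression):
                vals = "\t".join(f"{x:.6f}" for x in self.expression[prot].values)
                fh.write(f"{prot}\t{vals}\n")
        with open(paths["obo"], "w", encoding="utf-8") as fh:
            fh.write(self.obo_text)
        with open(paths["annotations"], "w", encoding="utf-8") as fh:
            fh.write("# protein\tterm\n")
            for prot in sorted(self.annotations):
                for term in sorted(self.annotations[prot]):
                    fh.write(f"{prot}\t{term}\n")
        with open(paths["orthology"], "w", encoding="utf-8") as fh:
            fh.write(f"# N={self.orthology.n_species}\n")
            for prot in sorted(self.orthology.counts):
                fh.write(f"{prot}\t{self.orthology.counts[prot]}\n")
        with open(paths["gold"], "w", encoding="utf-8") as fh:
            for prot in sorted(self.gold):
                fh.write(prot + "\n")
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(self.meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _make_tree_dag(depth: int, branching: int) -> tuple[GODag, str, list[str], list[str], dict[str, str]]:
    """Complete is_a tree: returns (dag, root, shallow terms, leaves, parent map)."""
    dag = GODag()
    root = _term_id(1)
    dag.add_term(root, aspect="BP")
    parent_of: dict[str, str] = {}
    level = [root]
    counter = 2
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                term = _term_id(counter)
                counter += 1
                dag.add_term(term, aspect="BP")
                dag.add_edge(term, parent, "is_a")
                parent_of[term] = parent
                nxt.append(term)
        level = nxt
    shallow = [t for t, p in parent_of.items() if p == root]
    leaves = level
    return dag, root, shallow, leaves, parent_of


def _dag_to_obo(dag: GODag, root: str) -> str:
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        lines.append("namespace: biological_process")
        for parent, rel in dag.parents(term):
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! synthetic term {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    return "\n".join(lines)


def _build_graph(config: SyntheticConfig) -> nx.Graph:
    if config.graph_model == "ba":
        return nx.barabasi_albert_graph(config.n_nodes, config.attach_m, seed=config.seed)
    g = nx.gnp_random_graph(config.n_nodes, config.er_p, seed=config.seed)
    # keep isolated nodes out of the PPI edge list domain
    return g


def generate_bundle_data(config: SyntheticConfig) -> Bundle:
    """Build the full bundle in memory (deterministic in ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    raw = _build_graph(config)
    name = {i: f"P{i:04d}" for i in raw.nodes}
    edges = [(name[a], name[b]) for a, b in raw.edges]
    nodes = sorted(name[i] for i in raw.nodes)
    degree = {name[i]: d for i, d in raw.degree}

    # planted essentials: degree-biased sample (hubs on average, not exactly
    # the top-degree set, so raw degree alone cannot recover them perfectly)
    probs = np.array([degree[v] for v in nodes], dtype=float)
    if probs.sum() <= 0:
        probs[:] = 1.0
    probs /= probs.sum()
    gold = {str(v) for v in rng.choice(nodes, size=config.n_essential, replace=False, p=probs)}

    # modules: each essential anchors itself plus its unclaimed neighbors
    adj = {name[i]: sorted(name[j] for j in raw.neighbors(i)) for i in raw.nodes}
    module_of: dict[str, int] = {}
    for idx, ess in enumerate(sorted(gold)):
        module_of.setdefault(ess, idx)
        for nb in adj[ess]:
            module_of.setdefault(nb, idx)

    # expression: shared latent factor per module, loading sqrt(rho)
    m = config.m_samples
    factors = rng.standard_normal((config.n_essential, m))
    sq_rho = float(np.sqrt(config.rho))
    sq_noise = float(np.sqrt(1.0 - config.rho))
    expression: dict[str, ExpressionProfile] = {}
    for v in nodes:
        noise = rng.standard_normal(m)
        if v in module_of:
            vals = sq_rho * factors[module_of[v]] + sq_noise * noise
        else:
            vals = noise
        expression[v] = ExpressionProfile(v, vals)

    # ontology: deep shared terms for modules, shallow scattered terms otherwise
    dag, root, shallow, leaves, parent_of = _make_tree_dag(config.dag_depth, config.dag_branching)
    annotations: dict[str, set[str]] = {}
    for i, v in enumerate(nodes):
        mod = module_of.get(v)
        if mod is not None:
            leaf = leaves[mod % len(leaves)]
            annotations[v] = {leaf, parent_of[leaf]}
        else:
            annotations[v] = {shallow[i % len(shallow)]}

    # orthology: high-mean counts for essentials, low-mean for background
    counts: dict[str, int] = {}
    for v in nodes:
        mu = config.ortho_high_mean if v in gold else config.ortho_low_mean
        n_u = int(round(rng.normal(mu, config.ortho_sd)))
        counts[v] = int(np.clip(n_u, 0, config.n_species))
    orthology = OrthologyTable(counts=counts, n_species=config.n_species)

    meta = {"config": asdict(config), "format_version": 1}
    return Bundle(
        edges=edges,
        expression=expression,
        dag=dag,
        obo_text=_dag_to_obo(dag, root),
        annotations=annotations,
        orthology=orthology,
        gold=gold,
        meta=meta,
    )


def generate_bundle(config: SyntheticConfig, outdir: str) -> dict[str, str]:
    """Generate and write a complete input bundle; returns the path map."""
    return generate_bundle_data(config).write(outdir)


def generate_toy_worked_example() -> Bundle:
    """Fixed 5-protein example with hand-computable scores at every stage.

    Graph: A-B, A-C, A-D, B-C, D-E. Annotation terms T1, T2 are both
    children of root R (is_a, contribution 0.8); E is unannotated. Chosen so
    that correlation, similarity, edge weights and the first three greedy
    picks can all be verified by hand (see the test suite for the arithmetic).
    """
    dag = GODag()
    dag.add_term("GO:0000001", aspect="BP")  # root R
    dag.add_edge("GO:0000002", "GO:0000001", "is_a")  # T1
    dag.add_edge("GO:0000003", "GO:0000001", "is_a")  # T2
    for t in ("GO:0000002", "GO:0000003"):
        dag.add_term(t, aspect="BP")

    expression = {
        "A": ExpressionProfile("A", np.array([1.0, 2.0, 3.0])),
        "B": ExpressionProfile("B", np.array([2.0, 4.0, 6.0])),
        "C": ExpressionProfile("C", np.array([6.0, 4.0, 2.0])),
        "D": ExpressionProfile("D", np.array([1.0, 2.0, 4.0])),
        "E": ExpressionProfile("E", np.array([2.0, 2.0, 5.0])),
    }
    annotations = {
        "A": {"GO:0000002"},
        "B": {"GO:0000002"},
        "C": {"GO:0000003"},
        "D": {"GO:0000002", "GO:0000003"},
        "E": set(),
    }
    orthology = OrthologyTable(
        counts={"A": 2, "B": 1, "C": 0, "D": 5, "E": 10}, n_species=10
    )
    edges = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("D", "E")]
    return Bundle(
        edges=edges,
        expression=expression,
        dag=dag,
        obo_text=_dag_to_obo(dag, "GO:0000001"),
        annotations=annotations,
        orthology=orthology,
        gold={"A", "D"},
        meta={"config": {"toy": True}, "format_version": 1},
    )
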