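import copy

import networkx as nx
import numpy as np
import pytest

from imepp.errors import DegenerateInputError, ParseError
from imepp.influence import (
    InfluenceState,
    OrthologyTable,
    Params,
    influence_discount,
    influence_discount_exact,
    init_influence,
    read_orthology,
    update_after_seed,
)


def star_graph(weights=(1.0, 1.0, 1.0)):
    g = nx.Graph()
    for i, w in enumerate(weights):
        g.add_edge("center", f"leaf{i}", weight=w)
    return g


def uniform_orthology(g, n=1, total=10):
    return OrthologyTable(counts={v: n for v in g.nodes}, n_species=total)


class TestParams:
    def test_defaults(self):
        p = Params()
        assert p.lam == 0.2 and p.p == 0.001

    @pytest.mark.parametrize("bad", [{"lam": -0.1}, {"lam": 1.1}, {"p": 0.0}, {"p": 1.0}, {"k": 0}])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            Params(**bad)


class TestOrthologyTable:
    def test_os(self):
        t = OrthologyTable(counts={"A": 5}, n_species=10)
        assert t.os("A") == 0.5
        assert t.os("missing") == 0.0  # absent proteins score 0

    def test_count_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            OrthologyTable(counts={"A": 11}, n_species=10)

    def test_read_orthology(self, tmp_path):
        f = tmp_path / "ortho.tsv"
        f.write_text("# N=10\nA\t5\nB\t0\n")
        t = read_orthology(str(f))
        assert t.n_species == 10 and t.counts == {"A": 5, "B": 0}

    def test_read_orthology_override(self, tmp_path):
        f = tmp_path / "ortho.tsv"
        f.write_text("# N=10\nA\t5\n")
        assert read_orthology(str(f), n_species=20).n_species == 20

    def test_read_orthology_missing_n(self, tmp_path):
        f = tmp_path / "ortho.tsv"
        f.write_text("A\t5\n")
        with pytest.raises(ParseError, match="species count"):
            read_orthology(str(f))


class TestInitInfluence:
    def test_star_normalization(self):
        g = star_graph()
        state = init_influence(g, uniform_orthology(g), Params(lam=0.0))
        assert state.is_topo["center"] == pytest.approx(1.0)
        assert state.is_topo["leaf0"] == pytest.approx(1 / 3)
        assert state.max_inf_topo == pytest.approx(3.0)

    def test_lambda_endpoints(self):
        g = star_graph()
        ortho = OrthologyTable(
            counts={"center": 1, "leaf0": 4, "leaf1": 2, "leaf2": 1}, n_species=10
        )
        s0 = init_influence(g, ortho, Params(lam=0.0))
        assert s0.score == pytest.approx(s0.is_topo)
        s1 = init_influence(g, ortho, Params(lam=1.0))
        assert s1.score == pytest.approx(s1.is_os)

    def test_blend_value(self):
        # IS = 0.2*0.5 + 0.8*1.0 = 0.9
        g = nx.Graph()
        g.add_edge("A", "B", weight=2.0)
        ortho = OrthologyTable(counts={"A": 5, "B": 10}, n_species=10)
        state = init_influence(g, ortho, Params(lam=0.2))
        assert state.score["A"] == pytest.approx(0.9)

    def test_normalizers_hit_one(self, small_bundle):
        from imepp.pin_build import build_weighted_pin

        pin = build_weighted_pin(
            small_bundle.edges, small_bundle.expression, small_bundle.annotations, small_bundle.dag
        )
        state = init_influence(pin, small_bundle.orthology, Params())
        assert max(state.is_topo.values()) == pytest.approx(1.0)
        assert max(state.is_os.values()) == pytest.approx(1.0)

    def test_zero_topology_error(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.0)
        with pytest.raises(DegenerateInputError, match="topology"):
            init_influence(g, uniform_orthology(g), Params(lam=0.5))

    def test_zero_orthology_error(self):
        g = star_graph()
        with pytest.raises(DegenerateInputError, match="orthology"):
            init_influence(g, uniform_orthology(g, n=0), Params(lam=0.5))

    def test_degenerate_channel_ok_when_unweighted(self):
        g = star_graph()
        # lam=0: all-zero orthology is fine
        state = init_influence(g, uniform_orthology(g, n=0), Params(lam=0.0))
        assert state.score == pytest.approx(state.is_topo)


class TestInfluenceDiscount:
    def make_state(self, inf=10.0, tt=0.0, t=0, p=0.001):
        return InfluenceState(
            inf_topo={"v": inf},
            is_topo={"v": 1.0},
            is_os={"v": 0.0},
            score={"v": 1.0},
            t={"v": t},
            tt={"v": tt},
            seeds=set(),
            max_inf_topo=inf,
            lam=0.0,
            p=p,
        )

    def test_no_seed_neighbors(self):
        assert influence_discount("v", self.make_state()) == pytest.approx(0.01)

    def test_derived_value(self):
        # (6 - 6*2*0.001) * 0.001
        state = self.make_state(tt=4.0, t=2)
        assert influence_discount("v", state) == pytest.approx(0.005988, abs=1e-12)

    def test_exact_form_and_bound(self):
        state = self.make_state(tt=4.0, t=2)
        exact = influence_discount_exact("v", state)
        assert exact == pytest.approx(0.998001 * 0.006, abs=1e-12)
        approx = influence_discount("v", state)
        # |approx - exact| <= (t*p)^2 * (Inf - tt) * p
        assert abs(approx - exact) <= (2 * 0.001) ** 2 * 6.0 * 0.001 + 1e-15

    def test_floor_at_zero(self, caplog):
        import logging

        state = self.make_state(t=2000, p=0.001)  # t*p = 2 -> negative
        with caplog.at_level(logging.WARNING):
            assert influence_discount("v", state) == 0.0
        assert any("floored" in r.message for r in caplog.records)

    def test_seed_raises(self):
        state = self.make_state()
        state.seeds.add("v")
        with pytest.raises(ValueError, match="seed"):
            influence_discount("v", state)

    def test_monotone_in_seed_additions(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            inf = float(rng.uniform(1, 20))
            state = self.make_state(inf=inf)
            prev = influence_discount("v", state)
            budget = inf
            for _ in range(int(rng.integers(1, 10))):
                w = float(rng.uniform(0, budget / 10))
                budget -= w
                state.t["v"] += 1
                state.tt["v"] += w
                cur = influence_discount("v", state)
                assert cur <= prev + 1e-12
                prev = cur


class TestUpdateAfterSeed:
    def build(self, lam=0.0):
        g = star_graph(weights=(2.0, 1.0, 0.0))
        ortho = uniform_orthology(g)
        state = init_influence(g, ortho, Params(lam=lam))
        return g, state

    def test_requires_seed_marked(self):
        g, state = self.build()
        with pytest.raises(ValueError, match="marked as seed"):
            update_after_seed("center", g, state)

    def test_neighbor_bookkeeping(self):
        g, state = self.build()
        state.seeds.add("center")
        update_after_seed("center", g, state)
        assert state.t["leaf0"] == 1
        assert state.tt["leaf0"] == pytest.approx(2.0)
        # leaf0's entire influence mass came from the seed edge -> discounted to 0
        assert state.is_topo["leaf0"] == pytest.approx(0.0)

    def test_zero_weight_edge_multiplies_by_one_minus_tp(self):
        g, state = self.build()
        before = state.is_topo["leaf2"]
        state.seeds.add("center")
        update_after_seed("center", g, state)
        # t=1, tt += 0: IS_topo scaled by (1 - t*p)
        assert state.is_topo["leaf2"] == pytest.approx(before * (1 - 1 * state.p))

    def test_non_neighbors_untouched(self):
        g = star_graph()
        g.add_edge("x", "y", weight=5.0)
        state = init_influence(g, uniform_orthology(g), Params(lam=0.0))
        snapshot = copy.deepcopy(state)
        state.seeds.add("center")
        update_after_seed("center", g, state)
        for v in ("x", "y"):
            assert state.score[v] == snapshot.score[v]
            assert state.t[v] == snapshot.t[v]
            assert state.tt[v] == snapshot.tt[v]

    def test_incremental_matches_from_scratch(self):
        rng = np.random.default_rng(11)
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        g = nx.relabel_nodes(g, {i: f"P{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0, 1))
        ortho = OrthologyTable(
            counts={v: int(rng.integers(0, 11)) for v in g.nodes}, n_species=10
        )
        lam, p = 0.3, 0.001
        state = init_influence(g, ortho, Params(lam=lam, p=p))
        seeds = []
        for s in sorted(g.nodes)[:5]:
            state.seeds.add(s)
            seeds.append(s)
            update_after_seed(s, g, state)
        # from-scratch recomputation with current t/tt maps
        for v in g.nodes:
            if v in state.seeds:
                continue
            t = sum(1 for nb in g.neighbors(v) if nb in state.seeds)
            tt = sum(g[v][nb]["weight"] for nb in g.neighbors(v) if nb in state.seeds)
            assert state.t[v] == t
            assert state.tt[v] == pytest.approx(tt, abs=1e-12)
            residual = state.inf_topo[v] - tt
            discount = max(0.0, (residual - residual * t * p) * p)
            is_topo = (discount / p) / state.max_inf_topo
            expected = lam * state.is_os[v] + (1 - lam) * is_topo
            assert state.score[v] == pytest.approx(expected, abs=1e-12)

    def test_invariants_tt_and_bounds(self):
        g, state = self.build()
        state.seeds.add("center")
        update_after_seed("center", g, state)
        for v in g.nodes:
            if v in state.seeds:
                continue
            assert state.tt[v] <= state.inf_topo[v] + 1e-12
            assert state.t[v] <= g.degree(v)
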