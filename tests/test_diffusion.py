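"""Diffusion core: seeds, PPR fixed point, permutation null, p-values."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dreamer.diffusion import (
    DiffusionConfig,
    EmptySeedError,
    SeedVector,
    TransitionOperator,
    bh_adjust,
    build_seed_vector,
    exponential_tail_pvalue,
    permutation_null,
    personalized_pagerank,
    significant_proteins,
)
from dreamer.kg import KnowledgeGraph


def dense_ppr_solve(graph, p0_dict, alpha):
    """Independent oracle: closed-form (I - aA)^-1 (1-a) p0 with dense algebra."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    A = np.zeros((n, n))
    idx = {u: i for i, u in enumerate(nodes)}
    for u, v in graph.edges():
        A[idx[u], idx[v]] = 1.0
        A[idx[v], idx[u]] = 1.0
    colsum = A.sum(axis=0)
    for j in range(n):
        if colsum[j] == 0:
            A[j, j] = 1.0
            colsum[j] = 1.0
    A = A / A.sum(axis=0, keepdims=True)
    p0 = np.array([p0_dict.get(u, 0.0) for u in nodes])
    sol = np.linalg.solve(np.eye(n) - alpha * A, (1 - alpha) * p0)
    return dict(zip(nodes, sol))


def _kg_two_proteins():
    kg = KnowledgeGraph()
    kg.proteins = {"Pa", "Pb"}
    kg.ppi.add_edge("Pa", "Pb", confidence=900.0)
    return kg


class TestSeedVector:
    def test_link_frequency_weights(self):
        kg = KnowledgeGraph()
        kg.drugs = {"D1", "D2"}
        kg.adrs = {"A1"}
        kg.proteins = {"P1", "P2"}
        kg.drug_adr = {("D1", "A1"), ("D2", "A1")}
        kg.drug_target = {("D1", "P1"), ("D1", "P2"), ("D2", "P2")}
        seed = build_seed_vector(kg, "A1", "adr")
        assert seed.scores == pytest.approx({"P1": 1 / 3, "P2": 2 / 3})

    def test_single_drug_single_target(self):
        kg = KnowledgeGraph()
        kg.drugs, kg.adrs, kg.proteins = {"D1"}, {"A1"}, {"P1"}
        kg.drug_adr = {("D1", "A1")}
        kg.drug_target = {("D1", "P1")}
        seed = build_seed_vector(kg, "A1", "adr")
        assert seed.scores == {"P1": 1.0}

    def test_untargeted_protein_absent_from_support(self):
        kg = KnowledgeGraph()
        kg.drugs, kg.adrs = {"D1"}, {"A1"}
        kg.proteins = {"P1", "P9"}
        kg.drug_adr = {("D1", "A1")}
        kg.drug_target = {("D1", "P1")}
        seed = build_seed_vector(kg, "A1", "adr")
        assert "P9" not in seed.scores

    def test_empty_seed_raises(self):
        kg = KnowledgeGraph()
        kg.adrs = {"A1"}
        with pytest.raises(EmptySeedError):
            build_seed_vector(kg, "A1", "adr")

    def test_asset_restriction(self):
        kg = KnowledgeGraph()
        kg.drugs, kg.adrs, kg.proteins = {"D1", "D2"}, {"A1"}, {"P1", "P2"}
        kg.drug_adr = {("D1", "A1"), ("D2", "A1")}
        kg.drug_target = {("D1", "P1"), ("D2", "P2")}
        seed = build_seed_vector(kg, "A1", "adr", assets={"D1"})
        assert seed.scores == {"P1": 1.0}


class TestPersonalizedPagerank:
    def test_two_node_fixed_point_by_hand(self):
        # p = aAp + (1-a)p0 on a single edge with seed (1, 0), a = 0.7:
        # p_a = 0.3/0.51, p_b = 0.21/0.51
        kg = _kg_two_proteins()
        seed = SeedVector({"Pa": 1.0})
        prof = personalized_pagerank(kg.ppi, seed, DiffusionConfig())
        assert prof.scores["Pa"] == pytest.approx(0.3 / 0.51, abs=1e-9)
        assert prof.scores["Pb"] == pytest.approx(0.21 / 0.51, abs=1e-9)

    def test_alpha_to_zero_limit_recovers_seed(self):
        kg = _kg_two_proteins()
        seed = SeedVector({"Pa": 0.25, "Pb": 0.75})
        prof = personalized_pagerank(
            kg.ppi, seed, DiffusionConfig(alpha=1e-6)
        )
        assert prof.scores["Pa"] == pytest.approx(0.25, abs=1e-5)
        assert prof.scores["Pb"] == pytest.approx(0.75, abs=1e-5)

    def test_complete_graph_uniform_seed_is_uniform(self):
        g = nx.complete_graph(6)
        seed = SeedVector({i: 1 / 6 for i in range(6)})
        prof = personalized_pagerank(g, seed, DiffusionConfig())
        assert np.allclose(list(prof.scores.values()), 1 / 6)

    def test_matches_dense_solve_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 51))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            support = rng.choice(n, size=min(4, n), replace=False)
            vals = rng.random(len(support))
            p0 = {int(i): float(v / vals.sum()) for i, v in zip(support, vals)}
            prof = personalized_pagerank(g, SeedVector(p0), DiffusionConfig())
            oracle = dense_ppr_solve(g, p0, 0.7)
            l1 = sum(abs(prof.scores[u] - oracle[u]) for u in g.nodes)
            assert l1 <= 1e-8

    def test_off_network_seed_mass_dropped_with_warning(self):
        kg = _kg_two_proteins()
        seed = SeedVector({"Pa": 0.5, "GHOST": 0.5})
        with pytest.warns(UserWarning, match="absent from the PPI"):
            prof = personalized_pagerank(kg.ppi, seed, DiffusionConfig())
        assert sum(prof.scores.values()) == pytest.approx(0.5, abs=1e-8)

    def test_fully_off_network_seed_raises(self):
        kg = _kg_two_proteins()
        with pytest.raises(EmptySeedError):
            personalized_pagerank(
                kg.ppi, SeedVector({"GHOST": 1.0}), DiffusionConfig()
            )

    def test_mass_conserved_on_network(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        seed = SeedVector({0: 0.5, 7: 0.5})
        prof = personalized_pagerank(g, seed, DiffusionConfig())
        assert sum(prof.scores.values()) == pytest.approx(1.0, abs=1e-8)

    def test_isolated_node_self_loop_keeps_mass(self):
        g = nx.Graph()
        g.add_edge("Pa", "Pb")
        g.add_node("Pc")  # isolated: operator must stay stochastic
        seed = SeedVector({"Pc": 1.0})
        prof = personalized_pagerank(g, seed, DiffusionConfig())
        assert prof.scores["Pc"] == pytest.approx(1.0, abs=1e-8)

    def test_seed_mass_monotonicity_on_small_graphs(self):
        # shifting seed mass onto a protein never lowers its own score
        for g in (nx.path_graph(5), nx.cycle_graph(6), nx.complete_graph(4)):
            base = SeedVector({0: 0.5, 1: 0.5})
            more = SeedVector({0: 0.7, 1: 0.3})
            cfg = DiffusionConfig()
            s_base = personalized_pagerank(g, base, cfg).scores[0]
            s_more = personalized_pagerank(g, more, cfg).scores[0]
            assert s_more >= s_base - 1e-12


class TestPermutationNull:
    def test_deterministic_under_seed(self, quiet):
        g = nx.gnp_random_graph(30, 0.2, seed=1)
        seed = SeedVector({0: 0.6, 3: 0.4})
        cfg = DiffusionConfig(n_permutations=2, rng_seed=5)
        a, _ = permutation_null(g, seed, cfg)
        b, _ = permutation_null(g, seed, cfg)
        assert np.array_equal(a, b)

    def test_each_null_profile_conserves_mass(self, quiet):
        g = nx.gnp_random_graph(30, 0.2, seed=1)
        seed = SeedVector({0: 0.6, 3: 0.4})
        null, _ = permutation_null(
            g, seed, DiffusionConfig(n_permutations=20, rng_seed=0)
        )
        assert np.allclose(null.sum(axis=1), 1.0, atol=1e-8)

    def test_null_means_equal_on_vertex_transitive_graph(self, quiet):
        # a cycle looks the same from every node, so per-protein null means
        # must agree up to Monte-Carlo error
        g = nx.cycle_graph(20)
        seed = SeedVector({0: 0.5, 1: 0.3, 2: 0.2})
        null, nodes = permutation_null(
            g, seed, DiffusionConfig(n_permutations=2000, rng_seed=2)
        )
        means = null.mean(axis=0)
        assert means.std() / means.mean() < 0.1

    def test_seeded_scope_keeps_support(self, quiet):
        g = nx.path_graph(10)
        seed = SeedVector({0: 0.7, 1: 0.3})
        cfg = DiffusionConfig(
            n_permutations=10, rng_seed=0, permute_scope="seeded"
        )
        op = TransitionOperator(g)
        null, nodes = permutation_null(op, seed, cfg)
        # mass only ever starts on the original support -> scores on far
        # nodes stay below what 'all' scope can produce at node 9
        assert null.shape == (10, 10)


class TestExponentialTailPvalue:
    def test_zero_observation_gives_one(self):
        assert exponential_tail_pvalue(0.0, [0.1, 0.2, 0.3]) == 1.0

    def test_closed_form_at_ln20(self):
        null = np.full(100, 0.2)
        assert exponential_tail_pvalue(
            0.2 * np.log(20), null
        ) == pytest.approx(0.05, rel=1e-12)

    def test_monotone_decreasing_in_observation(self):
        null = [0.1, 0.3, 0.2]
        ps = [exponential_tail_pvalue(x, null) for x in (0.0, 0.1, 1.0, 10.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_all_zero_null_handling(self):
        assert exponential_tail_pvalue(0.0, [0.0, 0.0]) == 1.0
        with pytest.warns(UserWarning, match="floored"):
            p = exponential_tail_pvalue(1.0, [0.0, 0.0])
        assert 0 < p < 1

    def test_vectorised_broadcast(self):
        null = np.tile([[0.1], [0.3]], (1, 4))  # (K=2, n=4)
        obs = np.array([0.0, 0.2, 0.4, 0.8])
        p = exponential_tail_pvalue(obs, null)
        assert p.shape == (4,)
        assert p[0] == 1.0


class TestBhAdjust:
    def test_step_up_by_hand(self):
        # p(i)*m/i then tail minimum: all collapse to 0.04
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestSignificantProteins:
    def _clique_kg(self):
        """A 5-clique floating beside a sparse 150-node background."""
        kg = KnowledgeGraph()
        g = nx.gnp_random_graph(150, 0.03, seed=4)
        g = nx.relabel_nodes(g, {i: f"B{i:03d}" for i in range(150)})
        clique = [f"C{i}" for i in range(5)]
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                g.add_edge(u, v)
        kg.ppi = g
        for u, v in kg.ppi.edges():
            kg.ppi[u][v]["confidence"] = 900.0
        kg.proteins = set(g.nodes)
        kg.adrs = {"A1"}
        kg.drugs = {"D1", "D2", "D3"}
        kg.drug_adr = {(d, "A1") for d in kg.drugs}
        kg.drug_target = {
            ("D1", "C0"), ("D1", "C1"), ("D2", "C2"), ("D2", "C3"),
            ("D3", "C4"), ("D3", "C0"),
        }
        return kg, clique

    def test_isolated_clique_recovered(self, quiet):
        kg, clique = self._clique_kg()
        res = significant_proteins(
            kg, "A1", "adr", DiffusionConfig(n_permutations=200, rng_seed=0)
        )
        assert set(clique) <= res.significant
        assert not any(p.startswith("B1") for p in res.significant)

    def test_uniform_seed_yields_no_significant(self, quiet):
        kg, _ = self._clique_kg()
        n = len(kg.proteins)
        seed = SeedVector({p: 1 / n for p in kg.proteins})
        res = significant_proteins(
            kg, "A1", "adr",
            DiffusionConfig(n_permutations=200, rng_seed=0), seed=seed,
        )
        assert len(res.significant) <= 0.05 * n

    def test_low_permutation_count_warns(self):
        kg, _ = self._clique_kg()
        with pytest.warns(UserWarning, match="low"):
            significant_proteins(
                kg, "A1", "adr", DiffusionConfig(n_permutations=2, rng_seed=0)
            )

    def test_table_invariants(self, quiet):
        kg, _ = self._clique_kg()
        res = significant_proteins(
            kg, "A1", "adr", DiffusionConfig(n_permutations=100, rng_seed=1)
        )
        t = res.table
        assert ((t.p_raw > 0) & (t.p_raw <= 1)).all()
        assert (t.p_adj >= t.p_raw - 1e-12).all()
        assert (t.significant == (t.p_adj < 0.05)).all()
        assert t.score.sum() == pytest.approx(1.0, abs=1e-8)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40
    )
)
def test_bh_adjust_is_a_valid_step_up_adjustment(ps):
    adj = bh_adjust(ps)
    assert (adj <= 1.0 + 1e-12).all()
    assert (adj >= np.asarray(ps) - 1e-12).all()
    # monotone in the ranks: sorting raw p sorts adjusted p the same way
    order = np.argsort(ps)
    assert (np.diff(adj[order]) >= -1e-12).all()


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.floats(min_value=0.0, max_value=100.0),
    st.lists(
        st.floats(min_value=1e-6, max_value=10.0), min_size=2, max_size=30
    ),
)
def test_exponential_tail_pvalue_is_a_survival_function(observed, null):
    p = exponential_tail_pvalue(observed, null)
    assert 0.0 < p <= 1.0
    assert exponential_tail_pvalue(observed + 1.0, null) <= p


def test_config_validation():
    with pytest.raises(ValueError):
        DiffusionConfig(alpha=1.0)
    with pytest.raises(ValueError):
        DiffusionConfig(n_permutations=1)
    with pytest.raises(ValueError):
        DiffusionConfig(permute_scope="bogus")
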