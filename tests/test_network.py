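"""Network construction, betweenness, hub calls, ORA and pathway impact."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ppmet.evaluation import brute_force_betweenness, enumerated_ora_pvalue
from ppmet.network import (
    HubCriteria,
    betweenness_centrality,
    build_network,
    identify_hubs,
    ora_enrich,
    pathway_impact,
    read_gmt,
    read_sif,
    write_gmt,
    write_sif,
)

TOY_EDGES = [("A", "R1"), ("B", "R1"), ("R1", "E1"), ("E1", "G1")]
TOY_ROLES = {"A": "compound", "B": "compound", "R1": "reaction", "E1": "enzyme", "G1": "gene"}


class TestBuildNetwork:
    def test_toy_base_counts(self):
        net = build_network(["A", "B"], TOY_EDGES, TOY_ROLES)
        assert (net.n_nodes, net.n_edges, net.n_components) == (5, 4, 1)
        assert net.graph.nodes["A"]["role"] == "input_compound"
        assert net.graph.nodes["E1"]["role"] == "enzyme"

    def test_empty_input_list_gives_empty_network(self):
        net = build_network([], TOY_EDGES, TOY_ROLES)
        assert net.n_nodes == 0 and net.n_components == 0

    def test_unknown_input_compound_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="not in knowledge base"):
            net = build_network(["A", "Zz"], TOY_EDGES, TOY_ROLES)
        assert net.input_compounds == ["A"]

    def test_empty_knowledge_base_rejected(self):
        with pytest.raises(ValueError):
            build_network(["A"], [], {})

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            build_network(["A"], [("A", "A")], TOY_ROLES)

    def test_untouched_components_excluded(self):
        edges = TOY_EDGES + [("X", "Y")]
        roles = dict(TOY_ROLES, X="compound", Y="compound")
        net = build_network(["A"], edges, roles)
        assert "X" not in net.graph


class TestBetweenness:
    def test_path_graph(self):
        bc = betweenness_centrality(nx.path_graph(3))
        assert bc == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_star_graph(self):
        bc = betweenness_centrality(nx.star_graph(4))
        assert bc[0] == 1.0
        assert all(bc[i] == 0.0 for i in range(1, 5))

    def test_complete_graph_all_zero(self):
        bc = betweenness_centrality(nx.complete_graph(5))
        assert all(v == 0.0 for v in bc.values())

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        G = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=seed)
        got = betweenness_centrality(G)
        want = brute_force_betweenness(G)
        assert all(abs(got[v] - want[v]) < 1e-12 for v in G.nodes)
        assert all(0.0 <= v <= 1.0 for v in got.values())


class TestHubs:
    def _metrics(self, rows):
        return pd.DataFrame(rows, columns=["node", "role", "degree", "bc"])

    def test_high_degree_high_bc_is_hub(self):
        m = self._metrics([("glycine-like", "input_compound", 27, 0.4155)])
        assert len(identify_hubs(None, HubCriteria(), metrics=m)) == 1

    def test_zero_bc_is_not_hub(self):
        m = self._metrics([("n", "compound", 50, 0.0)])
        assert identify_hubs(None, HubCriteria(), metrics=m).empty

    def test_boundary_node_flips_with_comparison(self):
        m = self._metrics([("glutamine-like", "input_compound", 10, 0.2181)])
        inc = identify_hubs(None, HubCriteria(comparison="inclusive"), metrics=m)
        strict = identify_hubs(None, HubCriteria(comparison="strict"), metrics=m)
        assert len(inc) == 1 and strict.empty

    def test_sorted_by_degree_descending(self):
        m = self._metrics([("a", "compound", 12, 0.5), ("b", "compound", 30, 0.5)])
        hubs = identify_hubs(None, HubCriteria(), metrics=m)
        assert hubs["node"].tolist() == ["b", "a"]

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            HubCriteria(comparison="sometimes").validate()


class TestORA:
    def test_enumerated_small_case(self):
        """Universe 10, pathway 4, draws 3, hits 2 -> P = 40/120 = 1/3."""
        universe = {f"u{i}" for i in range(10)}
        pathway = {"u0", "u1", "u2", "u3"}
        query = {"u0", "u1", "u9"}
        row = ora_enrich(query, {"pw": pathway}, universe=universe)
        assert row.loc[0, "p_raw"] == pytest.approx(1 / 3)
        assert row.loc[0, "p_raw"] == pytest.approx(enumerated_ora_pvalue(10, 4, 3, 2))

    def test_zero_hits_gives_p_one(self):
        universe = {f"u{i}" for i in range(8)}
        row = ora_enrich({"u7"}, {"pw": {"u0", "u1"}}, universe=universe)
        assert row.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_more_hits_never_larger_p(self):
        universe = {f"u{i}" for i in range(12)}
        pathway = {f"u{i}" for i in range(5)}
        ps = []
        for hits in (1, 2, 3):
            query = {f"u{i}" for i in range(hits)} | {f"u{11 - i}" for i in range(3 - hits)}
            ps.append(ora_enrich(query, {"pw": pathway}, universe=universe).loc[0, "p_raw"])
        assert ps[0] >= ps[1] >= ps[2]

    def test_pathway_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora_enrich({"a"}, {"pw": {"a", "zz"}}, universe={"a", "b"})

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            ora_enrich([], {"pw": {"a"}}, universe={"a"})

    def test_holm_vs_bh_adjustment(self):
        universe = {f"u{i}" for i in range(10)}
        lib = {
            "p1": {"u0", "u1"},                          # p_raw = 8/120
            "p2": {"u0", "u1", "u3", "u4"},              # p_raw = 1/3
            "p3": {"u0", "u1", "u3", "u4", "u5", "u6"},  # p_raw = 2/3
        }
        query = {"u0", "u1", "u2"}
        holm = ora_enrich(query, lib, universe=universe, adjust="holm_bonferroni")
        bh = ora_enrich(query, lib, universe=universe, adjust="bh")
        assert (holm["p_adjusted"] >= holm["p_raw"] - 1e-12).all()
        # step-down Holm is more conservative than step-up BH in the middle
        assert (holm["p_adjusted"] >= bh["p_adjusted"] - 1e-12).all()
        assert not np.allclose(holm["p_adjusted"], bh["p_adjusted"])

    def test_default_toy_library_mirrors_backend_scale(self):
        from ppmet.simulate import generate_pathway_library

        sets, graphs = generate_pathway_library(seed=0)
        assert len(sets) == 80 and len(graphs) == 80


class TestImpact:
    def test_full_coverage_is_one(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a")]  # clique: all bc zero
        assert pathway_impact(edges, {"a", "b", "c"}) == pytest.approx(1.0)

    def test_path_centre_holds_all_mass(self):
        edges = [("A", "B"), ("B", "C")]
        assert pathway_impact(edges, {"B"}) == pytest.approx(1.0)
        assert pathway_impact(edges, {"A"}) == pytest.approx(0.0)

    def test_no_hits_zero(self):
        assert pathway_impact([("A", "B"), ("B", "C")], set()) == 0.0

    def test_hit_absent_from_graph_rejected(self):
        with pytest.raises(ValueError):
            pathway_impact([("A", "B")], {"Q"})


class TestFormats:
    def test_sif_roundtrip(self, tmp_path):
        p = tmp_path / "net.sif"
        write_sif(TOY_EDGES, p)
        assert sorted(read_sif(p)) == sorted(TOY_EDGES)

    def test_gmt_roundtrip(self, tmp_path):
        lib = {"pw1": {"a", "b"}, "pw2": {"c"}}
        p = tmp_path / "lib.gmt"
        write_gmt(lib, p)
        assert read_gmt(p) == lib

    def test_edge_csv_and_role_sidecar(self, tmp_path):
        import pandas as pd

        from ppmet.network import read_edge_csv, read_roles_csv

        pd.DataFrame(TOY_EDGES, columns=["source", "target"]).to_csv(
            tmp_path / "edges.csv", index=False
        )
        pd.DataFrame(TOY_ROLES.items(), columns=["node", "role"]).to_csv(
            tmp_path / "roles.csv", index=False
        )
        assert read_edge_csv(tmp_path / "edges.csv") == TOY_EDGES
        assert read_roles_csv(tmp_path / "roles.csv") == TOY_ROLES
        (tmp_path / "bad.csv").write_text("node,role\nA,wizard\n")
        with pytest.raises(ValueError, match="wizard"):
            read_roles_csv(tmp_path / "bad.csv")

    def test_graphml_export(self, tmp_path):
        net = build_network(["A"], TOY_EDGES, TOY_ROLES)
        net.write_graphml(tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_nodes() == net.n_nodes
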