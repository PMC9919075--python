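"""Set intersection, graph statistics, enrichment and network assembly."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectrum_effect import (
    build_ctpd_network,
    gen_target_data,
    graph_stats,
    hypergeom_enrich,
    intersect_targets,
    top_degree,
)
from spectrum_effect.netpharm import read_edge_list, read_id_set, read_term_membership, write_sif


class TestIntersect:
    def test_basic_counts(self):
        ts = intersect_targets({"a", "b", "c"}, {"b", "c", "d"})
        assert set(ts.intersection) == {"b", "c"}
        assert ts.venn_counts == (1, 1, 2)

    def test_disjoint_and_normalization(self):
        ts = intersect_targets({" SRC ", "AKT1"}, {"SRC", "MAPK1"})
        assert set(ts.intersection) == {"SRC"}
        assert set(intersect_targets({"a"}, {"b"}).intersection) == set()

    def test_counts_match_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        ids = [f"g{i}" for i in range(60)]
        a = set(rng.choice(ids, 25, replace=False).tolist())
        b = set(rng.choice(ids, 30, replace=False).tolist())
        ts = intersect_targets(a, b)
        both = sum(1 for i in ids if i in a and i in b)
        assert ts.venn_counts == (len(a) - both, len(b) - both, both)


class TestGraphStats:
    def test_triangle(self):
        g = nx.cycle_graph(3)
        s = graph_stats(g)
        assert (s["n_nodes"], s["n_edges"], s["average_degree_1dp"]) == (3, 3, 2.0)

    def test_published_ppi_size_gives_4p4(self):
        """A graph with 223 nodes and 493 edges has average degree 4.4."""
        g = nx.gnm_random_graph(223, 493, seed=0)
        s = graph_stats(g)
        assert s["n_nodes"] == 223 and s["n_edges"] == 493
        assert s["average_degree_1dp"] == 4.4

    def test_handshake_lemma_and_order_invariance(self):
        g = nx.gnm_random_graph(40, 90, seed=1)
        s = graph_stats(g)
        assert sum(s["degree"].values()) == 2 * s["n_edges"]
        g2 = nx.Graph()
        g2.add_edges_from(reversed(list(g.edges())))
        assert graph_stats(g2)["degree"] == s["degree"]
        assert top_degree(g, 10) == top_degree(g2, 10)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            graph_stats(nx.Graph())


class TestTopDegree:
    def test_star_hub(self):
        g = nx.star_graph(5)  # node 0 is the hub
        assert top_degree(g, 1) == ["0"]

    def test_tie_broken_lexicographically(self):
        g = nx.Graph([("b", "x"), ("a", "y"), ("c", "z"), ("x", "y")])
        got = top_degree(g, g.number_of_nodes())
        want = [n for n, _ in sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))]
        assert got == want

    def test_k_exceeding_n_warns_and_returns_all(self):
        g = nx.path_graph(3)
        with pytest.warns(UserWarning):
            out = top_degree(g, 10)
        assert len(out) == 3


class TestEnrichment:
    def test_exhaustive_enumeration_small_case(self):
        # N=10, K=4, n=3, k=3: enumerate all C(10,3) draws
        universe = [f"g{i}" for i in range(10)]
        term = set(universe[:4])
        study = set(universe[:3])
        df = hypergeom_enrich(study, {"T": term}, universe, keep_all=True)
        assert df.loc[0, "p"] == pytest.approx(4 / 120, abs=1e-12)

    def test_tail_equals_enumeration_for_all_small_universes(self):
        """Closed-form upper tail vs complete enumeration, universes <= 20."""
        from math import comb

        rng = np.random.default_rng(7)
        for _ in range(40):
            N = int(rng.integers(4, 21))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            term = set(universe[:K])
            study = set(rng.choice(universe, n, replace=False).tolist())
            k = len(term & study)
            p_enum = sum(
                comb(K, j) * comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
            ) / comb(N, n)
            df = hypergeom_enrich(study, {"T": term}, universe, keep_all=True)
            assert df.loc[0, "p"] == pytest.approx(p_enum, abs=1e-12)

    def test_no_overlap_term_has_p_near_one(self):
        universe = [f"g{i}" for i in range(30)]
        df = hypergeom_enrich(set(universe[:5]), {"T": set(universe[25:])},
                              universe, keep_all=True)
        assert df.loc[0, "k"] == 0
        assert df.loc[0, "p"] >= 0.99

    def test_study_outside_universe_raises(self):
        with pytest.raises(ValueError, match="outside the universe"):
            hypergeom_enrich({"x"}, {}, {"a", "b"})

    def test_planted_term_smallest_p_adj(self):
        wins = 0
        for seed in range(100):
            uni, terms, study = gen_target_data(seed=seed)
            df = hypergeom_enrich(study, terms, uni, keep_all=True)
            if df.loc[0, "term"] == "T000":
                wins += 1
        assert wins >= 95

    def test_null_overlap_term_not_extreme(self):
        """A term overlapping the study only at chance expectation should
        not be among the smallest p-values."""
        in_decile = 0
        for seed in range(100):
            uni, terms, study = gen_target_data(
                seed=seed, planted_overlap=2, planted_term_size=20, study_size=20,
                universe_size=200,  # E[k] = 20*20/200 = 2: exactly at expectation
            )
            df = hypergeom_enrich(study, terms, uni, keep_all=True).reset_index()
            pos = df.index[df["term"] == "T000"][0]
            if pos < max(1, len(df) // 10):
                in_decile += 1
        assert in_decile <= 50  # planted-at-null term is not systematically extreme

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_bh_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        uni, terms, study = gen_target_data(seed=seed % 50, n_terms=12)
        df = hypergeom_enrich(study, terms, uni, keep_all=True)
        assert (df["p_adj"] >= df["p"] - 1e-15).all()
        assert (df["p_adj"] <= 1.0 + 1e-15).all()
        assert (df["p_adj"].diff().dropna() >= -1e-12).all()  # sorted by p


class TestCTPDNetwork:
    def _fixture(self, n_paths=30):
        targets = [f"T{i}" for i in range(10)]
        degree = {t: (10 if i < 4 else 1) for i, t in enumerate(targets)}
        enrich = pd.DataFrame({
            "term": [f"path{i}" for i in range(n_paths)],
            "p": np.linspace(1e-6, 0.04, n_paths),
        })
        members = {f"path{i}": set(targets[:4]) for i in range(n_paths)}
        diseases = {f"path{i}": {"infection"} for i in range(n_paths)}
        return targets, degree, enrich, members, diseases

    def test_single_path_chain(self):
        g = build_ctpd_network("compound", {"T1"}, {"T1": 2, "T2": 0},
                               pd.DataFrame({"term": ["p1"], "p": [0.01]}),
                               {"p1": {"T1"}}, {"p1": {"disease"}})
        assert g.number_of_edges() == 3
        assert nx.shortest_path(g, "compound", "disease") == ["compound", "T1", "p1", "disease"]

    def test_top20_pathways_retained(self):
        targets, degree, enrich, members, diseases = self._fixture(30)
        g = build_ctpd_network("c", targets, degree, enrich, members, diseases)
        paths = [n for n, d in g.nodes(data=True) if d["kind"] == "pathway"]
        assert len(paths) == 20

    def test_degree_filter_strictly_above_average(self):
        targets, degree, enrich, members, diseases = self._fixture()
        g = build_ctpd_network("c", targets, degree, enrich, members, diseases)
        kept = {n for n, d in g.nodes(data=True) if d["kind"] == "target"}
        avg = np.mean(list(degree.values()))
        assert kept == {t for t in targets if degree[t] > avg}
        # all-equal degrees: nothing is strictly above the mean
        g2 = build_ctpd_network("c", targets, {t: 3 for t in targets},
                                enrich, members, diseases)
        assert not [n for n, d in g2.nodes(data=True) if d["kind"] == "target"]

    def test_missing_annotation_warns_but_keeps_node(self):
        with pytest.warns(UserWarning, match="membership"):
            g = build_ctpd_network("c", {"T1"}, {"T1": 5, "T2": 0},
                                   pd.DataFrame({"term": ["p1"], "p": [0.01]}),
                                   {}, {})
        assert "p1" in g


def test_io_roundtrips(tmp_path):
    ids = tmp_path / "ids.txt"
    ids.write_text("# comment\nSRC\nAKT1\n\n")
    assert read_id_set(ids) == {"SRC", "AKT1"}

    edges = tmp_path / "edges.tsv"
    edges.write_text("a\tb\nb\tc\na\ta\na\tb\n")
    g = read_edge_list(edges)
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    terms = tmp_path / "terms.tsv"
    terms.write_text("t1\tx\nt1\ty\nt2\tz\n")
    assert read_term_membership(terms) == {"t1": {"x", "y"}, "t2": {"z"}}

    sif = tmp_path / "net.sif"
    write_sif(g, sif)
    lines = sif.read_text().strip().splitlines()
    assert len(lines) == 2 and all(len(l.split("\t")) == 3 for l in lines)
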