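"""Weight formulas, constrained shortest-path search, scoring and ranking."""

import math

import pytest

from pdrank import (DiseaseScore, ScoringParams, constrained_shortest_paths,
                    evidence_subnetwork, load_params, path_weight,
                    rank_diseases, score_candidates, score_disease,
                    specificity_weight)

from conftest import enumerate_constrained_paths, make_graph, random_small_graph

DEFAULTS = ScoringParams()


class TestSpecificityWeight:
    def test_zero_or_one_disease_gives_unit_weight(self):
        assert specificity_weight(0) == 1.0
        assert specificity_weight(1) == 1.0

    def test_ten_diseases_halves_the_weight(self):
        assert specificity_weight(10, b=1) == pytest.approx(0.5)

    def test_high_degree_phenotype(self):
        # direct formula evaluation at the largest degree seen in curated KBs
        expected = 1.0 / (1.0 + math.log10(1403))
        assert specificity_weight(1403) == pytest.approx(expected)
        assert specificity_weight(1403) < specificity_weight(100)

    def test_non_increasing_in_n(self):
        weights = [specificity_weight(n) for n in range(0, 200)]
        assert all(a >= b for a, b in zip(weights, weights[1:]))
        assert all(w == 1.0 for w in weights[:2])
        assert all(w < 1.0 for w in weights[2:])

    def test_rejects_negative_arguments(self):
        with pytest.raises(ValueError):
            specificity_weight(-1)
        with pytest.raises(ValueError):
            specificity_weight(5, b=-0.1)


class TestPathWeight:
    @pytest.mark.parametrize("L,expected", [(1, 1.0), (2, 0.75), (3, 0.5625),
                                            (4, 0.75 ** 3)])
    def test_default_decay(self, L, expected):
        assert path_weight(L) == pytest.approx(expected)

    def test_direct_link_exactly_one(self):
        assert path_weight(1) == 1.0
        assert path_weight(1, a=0.2) == 1.0

    def test_strictly_decreasing_below_one_flat_at_one(self):
        ws = [path_weight(L, a=0.75) for L in (1, 2, 3, 4)]
        assert all(x > y for x, y in zip(ws, ws[1:]))
        assert all(path_weight(L, a=1.0) == 1.0 for L in (1, 2, 3, 4))

    def test_rejects_out_of_range_lengths(self):
        with pytest.raises(ValueError):
            path_weight(0)
        with pytest.raises(ValueError):
            path_weight(5, max_path_length=4)


class TestParams:
    def test_defaults(self):
        p = ScoringParams()
        assert (p.a, p.b, p.max_path_length) == (0.75, 1.0, 4)
        assert (p.table_limit, p.variants_per_gene_limit) == (50, 5)

    def test_config_and_overrides(self, tmp_path):
        cfg = tmp_path / "params.yaml"
        cfg.write_text("a: 0.5\ntable_limit: 10\n")
        p = load_params(cfg, b=2.0)
        assert (p.a, p.b, p.table_limit) == (0.5, 2.0, 10)
        with pytest.raises(ValueError, match="unknown parameter"):
            cfg.write_text("bogus: 1\n")
            load_params(cfg)


def chain_graph(n_ph_hops):
    """phenotype -PH...-> t_k, terminal DP into the only disease; the path
    needs n_ph_hops + 1 edges."""
    nodes = [("p0", "p")] + [(f"t{i}", "p") for i in range(1, n_ph_hops + 1)]
    nodes += [("d", "d"), ("g", "g")]
    edges = [(f"t{i}", f"t{i+1}", "PH") for i in range(1, n_ph_hops)]
    edges += [("t1", "p0", "PH")] if n_ph_hops else []
    last = f"t{n_ph_hops}" if n_ph_hops else "p0"
    edges += [("d", last, "DP"), ("g", "d", "GD")]
    return make_graph(nodes, edges)


class TestConstrainedShortestPaths:
    def test_direct_link(self):
        g = make_graph([("p1", "p"), ("d1", "d")], [("d1", "p1", "DP")])
        res = constrained_shortest_paths(g, "p1", {"d1"}, DEFAULTS)
        L, paths = res["d1"]
        assert L == 1 and paths[0].nodes == ("p1", "d1")
        assert paths[0].edge_kinds == ("DP",)

    def test_one_hop_hierarchy(self):
        g = make_graph(
            [("p1", "p"), ("t", "p"), ("d1", "d")],
            [("t", "p1", "PH"), ("d1", "t", "DP")])
        res = constrained_shortest_paths(g, "p1", {"d1"}, DEFAULTS)
        L, paths = res["d1"]
        assert L == 2 and paths[0].nodes == ("p1", "t", "d1")

    @pytest.mark.parametrize("hops,reached", [(3, True), (4, False)])
    def test_path_length_cap(self, hops, reached):
        # hops PH edges + terminal DP = hops+1 total; cap is 4
        g = chain_graph(hops)
        res = constrained_shortest_paths(g, "p0", {"d"}, DEFAULTS)
        assert ("d" in res) is reached
        if reached:
            assert res["d"][0] == 4

    def test_candidate_disease_blocks_intermediate(self):
        # p1 -> dBlock (in D) -> p2 -> dTarget: dTarget unreachable when
        # dBlock is a candidate, reachable otherwise
        nodes = [("p1", "p"), ("p2", "p"), ("dBlock", "dp"), ("dTarget", "d")]
        edges = [("dBlock", "p1", "DP"), ("dBlock", "p2", "DP"),
                 ("dTarget", "dBlock", "DP")]
        # dBlock is dual-role: acts as phenotype of dTarget
        g = make_graph(nodes, edges)
        res = constrained_shortest_paths(g, "p1", {"dBlock", "dTarget"}, DEFAULTS)
        assert "dBlock" in res and "dTarget" not in res
        res2 = constrained_shortest_paths(g, "p1", {"dTarget"}, DEFAULTS)
        assert res2["dTarget"][0] == 2

    def test_phenotype_is_the_candidate_disease(self):
        nodes = [("px", "dp"), ("p2", "p"), ("d0", "d")]
        edges = [("px", "p2", "DP"), ("d0", "px", "DP")]
        g = make_graph(nodes, edges)
        res = constrained_shortest_paths(g, "px", {"px"}, DEFAULTS)
        L, paths = res["px"]
        assert L == 1 and paths[0].is_self

    def test_all_equal_length_paths_returned(self):
        # two parallel intermediates give two shortest paths
        nodes = [("p", "p"), ("t1", "p"), ("t2", "p"), ("d", "d")]
        edges = [("t1", "p", "PH"), ("t2", "p", "PH"),
                 ("d", "t1", "DP"), ("d", "t2", "DP")]
        g = make_graph(nodes, edges)
        L, paths = constrained_shortest_paths(g, "p", {"d"}, DEFAULTS)["d"]
        assert L == 2 and len(paths) == 2
        assert {p.nodes for p in paths} == {("p", "t1", "d"), ("p", "t2", "d")}

    def test_matches_brute_force_enumeration(self):
        for seed in range(40):
            g, phen, all_dis, _ = random_small_graph(seed)
            D = set(all_dis[: max(1, len(all_dis) // 2)])
            for p in phen:
                got = constrained_shortest_paths(g, p, D, DEFAULTS)
                want = enumerate_constrained_paths(g, p, D, lmax=4)
                assert {d: L for d, (L, _) in got.items()} == \
                       {d: L for d, (L, _) in want.items()}, (seed, p)
                for d in want:
                    assert sorted(pp.nodes for pp in got[d][1]) == want[d][1], (seed, p, d)


class TestScoreDisease:
    def test_single_direct_specific_phenotype_scores_one(self):
        g = make_graph([("p1", "p"), ("d1", "d")], [("d1", "p1", "DP")])
        paths = {"p1": constrained_shortest_paths(g, "p1", {"d1"}, DEFAULTS)}
        s = score_disease(g, "d1", paths, DEFAULTS)
        assert s.score == 1.0

    def test_hand_evaluated_two_phenotype_score(self):
        # p1: N=1, L=1 -> 1; p2: N=10, L=2 -> 0.5 * 0.75; S = 1.375
        nodes = [("p1", "p"), ("p2", "p"), ("t", "p"), ("d1", "d")]
        edges = [("d1", "p1", "DP"), ("t", "p2", "PH"), ("d1", "t", "DP")]
        # nine extra diseases attach to p2 so N(p2) = 10... they attach DP->p2
        for i in range(10):
            nodes.append((f"x{i}", "d"))
            edges.append((f"x{i}", "p2", "DP"))
        g = make_graph(nodes, edges)
        assert g.direct_disease_count("p2") == 10
        paths = {p: constrained_shortest_paths(g, p, {"d1"}, DEFAULTS)
                 for p in ("p1", "p2")}
        s = score_disease(g, "d1", paths, DEFAULTS)
        assert s.score == pytest.approx(1.0 + 0.5 * 0.75, abs=1e-12)
        by_p = {c.phenotype: c for c in s.contributions}
        assert by_p["p2"].specificity_weight == pytest.approx(0.5)
        assert by_p["p2"].path_weight == pytest.approx(0.75)

    def test_additional_connected_phenotype_strictly_increases_score(self):
        g = make_graph(
            [("p1", "p"), ("p2", "p"), ("d1", "d")],
            [("d1", "p1", "DP"), ("d1", "p2", "DP")])
        one = {"p1": constrained_shortest_paths(g, "p1", {"d1"}, DEFAULTS)}
        both = dict(one, p2=constrained_shortest_paths(g, "p2", {"d1"}, DEFAULTS))
        assert score_disease(g, "d1", both, DEFAULTS).score > \
               score_disease(g, "d1", one, DEFAULTS).score

    def test_phenotype_counted_once_despite_parallel_paths(self):
        nodes = [("p", "p"), ("t1", "p"), ("t2", "p"), ("d", "d")]
        edges = [("t1", "p", "PH"), ("t2", "p", "PH"),
                 ("d", "t1", "DP"), ("d", "t2", "DP")]
        g = make_graph(nodes, edges)
        paths = {"p": constrained_shortest_paths(g, "p", {"d"}, DEFAULTS)}
        s = score_disease(g, "d", paths, DEFAULTS)
        assert len(s.contributions) == 1
        assert s.score == pytest.approx(0.75)  # N=0 -> w_s=1, L=2
        assert len(s.evidence_paths) == 2  # both kept as evidence

    def test_contract_violation_when_unconnected(self, minimal_graph):
        with pytest.raises(ValueError, match="no connected phenotype"):
            score_disease(minimal_graph, "d1", {"p1": {}}, DEFAULTS)


class TestRankDiseases:
    @staticmethod
    def ds(d, score, n=1):
        contribs = [None] * n  # only the count matters for tie-breaking
        return DiseaseScore(disease=d, score=score, contributions=contribs,
                            implicating_genes=frozenset())

    def test_descending_by_score(self):
        ranked = rank_diseases([self.ds("d2", 1.0), self.ds("d1", 2.0)])
        assert [s.disease for s in ranked] == ["d1", "d2"]

    def test_tie_breaks_by_count_then_id(self):
        ranked = rank_diseases([self.ds("dB", 1.0, n=1), self.ds("dA", 1.0, n=2)])
        assert [s.disease for s in ranked] == ["dA", "dB"]
        ranked = rank_diseases([self.ds("dB", 1.0), self.ds("dA", 1.0)])
        assert [s.disease for s in ranked] == ["dA", "dB"]

    def test_permutation_invariant(self):
        import itertools
        scores = [self.ds("d1", 2.0), self.ds("d2", 2.0, n=2),
                  self.ds("d3", 0.5), self.ds("d4", 2.0)]
        orders = {tuple(s.disease for s in rank_diseases(list(perm)))
                  for perm in itertools.permutations(scores)}
        assert len(orders) == 1


class TestEvidenceSubnetwork:
    def test_single_direct_path_with_gene(self, minimal_graph):
        paths = {"p1": constrained_shortest_paths(minimal_graph, "p1", {"d1"},
                                                  DEFAULTS)}
        s = score_disease(minimal_graph, "d1", paths, DEFAULTS,
                          implicating_genes=frozenset({"g1"}))
        sub = evidence_subnetwork(s, minimal_graph)
        assert len(sub.nodes) == 3 and len(sub.edges) == 2
        assert sub.nodes == {"g1": "gene", "d1": "disease", "p1": "phenotype"}
        assert ("g1", "d1", "GD") in sub.edges and ("d1", "p1", "DP") in sub.edges

    def test_worked_case_intermediates_appear(self, worked_case_graph):
        g = worked_case_graph
        P = {"meningomyelocele", "renal_agenesis", "prominent_nose",
             "hirsutism", "retrognathia"}
        ranked = score_candidates(g, P, {"SYNDROME_X": {"GENE_A"}}, DEFAULTS)
        sub = evidence_subnetwork(ranked[0], g)
        intermediates = {n for n, role in sub.nodes.items() if role == "intermediate"}
        assert intermediates == {"dysgenesis", "unilateral_renal_dysgenesis"}

    def test_subnetwork_edges_subset_of_graph(self):
        for seed in range(6):
            g, phen, all_dis, genes = random_small_graph(seed)
            cands, _ = g.candidate_diseases(set(genes))
            stored = {(e.source, e.target, e.kind) for e in g.edges}
            for s in score_candidates(g, set(phen[:5]), cands, DEFAULTS):
                sub = evidence_subnetwork(s, g)
                assert set(sub.edges) <= stored


class TestScoreCandidates:
    def test_worked_case_disease_ranks_first_with_expected_breakdown(
            self, worked_case_graph):
        g = worked_case_graph
        P = {"meningomyelocele", "renal_agenesis", "prominent_nose",
             "hirsutism", "retrognathia"}
        cands, _ = g.candidate_diseases({"GENE_A", "GENE_B"})
        ranked = score_candidates(g, P, cands, DEFAULTS)
        assert [s.disease for s in ranked] == ["SYNDROME_X", "SYNDROME_Y"]
        top = ranked[0]
        by_p = {c.phenotype: c for c in top.contributions}
        # renal agenesis connects through two intermediate hierarchy terms
        assert by_p["renal_agenesis"].shortest_length == 3
        # hirsutism is shared with the competitor disease: N = 2
        assert by_p["hirsutism"].specificity_weight == pytest.approx(
            1 / (1 + math.log10(2)))
        expected = 3 * 1.0 + 1 / (1 + math.log10(2)) + 0.75 ** 2
        assert top.score == pytest.approx(expected, abs=1e-12)

    def test_score_equals_sum_of_breakdown(self):
        for seed in range(10):
            g, phen, _, genes = random_small_graph(seed)
            cands, _ = g.candidate_diseases(set(genes))
            for s in score_candidates(g, set(phen[:6]), cands, DEFAULTS):
                assert abs(s.score - sum(c.contribution for c in s.contributions)) < 1e-12

    def test_enlarging_phenotype_set_never_lowers_scores(self):
        for seed in range(10):
            g, phen, _, genes = random_small_graph(seed)
            cands, _ = g.candidate_diseases(set(genes))
            small = set(phen[:4])
            large = small | set(phen[4:8])
            s_small = {s.disease: s.score
                       for s in score_candidates(g, small, cands, DEFAULTS)}
            s_large = {s.disease: s.score
                       for s in score_candidates(g, large, cands, DEFAULTS)}
            for d, sc in s_small.items():
                assert s_large[d] >= sc - 1e-15
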