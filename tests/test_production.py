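"""Triphone-graph production: thinning, path search, candidate selection."""

import itertools

import numpy as np
import pytest

from ldlex import (CueInventory, LdlexError, LinearMapping, WordForm, aldc,
                   build_triphone_graph, encode_triplets, enumerate_candidates,
                   scpp, synthesis_by_analysis)
from ldlex.forms import cue_string, triphone_tuples
from ldlex.production import merge_path, path_cue_vector, speak


def make_inventory(cues):
    tuples = [tuple(c) for c in cues]
    return CueInventory(list(cues), kind="triphone", tuples=tuples)


@pytest.fixture()
def loks_fixture():
    """The [loks] walkthrough: six retained triphones, target form loks."""
    cues = ["#lo", "#ok", "lok", "oks", "ok#", "ks#"]
    supports = np.array([0.5, 0.4, 0.6, 0.3, 0.5, 0.2])
    return make_inventory(cues), supports


class TestBuildGraph:
    def test_mergeable_edges(self, loks_fixture):
        inv, sup = loks_fixture
        g = build_triphone_graph(sup, inv, threshold=0.1)
        edges = set(g.graph.edges)
        assert {("#lo", "lok"), ("lok", "ok#"), ("#ok", "oks"),
                ("oks", "ks#"), ("#ok", "ok#"), ("lok", "oks")} <= edges
        assert set(g.initial) == {"#lo", "#ok"}
        assert set(g.final) == {"ok#", "ks#"}

    def test_attested_mode_withholds_novel_transition(self, loks_fixture):
        inv, sup = loks_fixture
        attested = {("#lo", "lok"), ("lok", "ok#"), ("#ok", "oks"),
                    ("oks", "ks#"), ("#ok", "ok#")}
        g = build_triphone_graph(sup, inv, threshold=0.1,
                                 edges="attested", attested=attested)
        assert ("lok", "oks") not in g.graph.edges

    def test_all_below_threshold_empty_graph(self, loks_fixture):
        inv, sup = loks_fixture
        g = build_triphone_graph(np.full_like(sup, 0.01), inv, threshold=0.1)
        assert g.graph.number_of_nodes() == 0
        assert enumerate_candidates(g) == []

    def test_threshold_zero_keeps_strictly_positive(self, loks_fixture):
        inv, _ = loks_fixture
        sup = np.array([0.5, 0.0, -0.2, 0.3, 0.5, 0.2])
        g = build_triphone_graph(sup, inv, threshold=0.0)
        assert set(g.graph.nodes) == {"#lo", "oks", "ok#", "ks#"}
        # edge set equals a brute-force mergeability scan over retained nodes
        nodes = list(g.graph.nodes)
        oracle = {(u, v) for u, v in itertools.permutations(nodes, 2)
                  if tuple(u)[-2:] == tuple(v)[:2]}
        assert set(g.graph.edges) == oracle


class TestEnumerate:
    def test_loks_three_candidates_without_novel_edge(self, loks_fixture):
        inv, sup = loks_fixture
        attested = {("#lo", "lok"), ("lok", "ok#"), ("#ok", "oks"),
                    ("oks", "ks#"), ("#ok", "ok#")}
        g = build_triphone_graph(sup, inv, threshold=0.1,
                                 edges="attested", attested=attested)
        cands = enumerate_candidates(g)
        assert sorted("".join(c.phones) for c in cands) == ["lok", "ok", "oks"]
        assert "loks" not in {"".join(c.phones) for c in cands}

    def test_mergeable_mode_also_finds_target(self, loks_fixture):
        inv, sup = loks_fixture
        g = build_triphone_graph(sup, inv, threshold=0.1)
        phones = {"".join(c.phones) for c in enumerate_candidates(g)}
        assert phones == {"lok", "ok", "oks", "loks"}

    def test_single_chain(self):
        inv = make_inventory(["#ab", "abc", "bc#"])
        g = build_triphone_graph(np.array([1.0, 1.0, 1.0]), inv)
        cands = enumerate_candidates(g)
        assert len(cands) == 1 and cands[0].phones == ("a", "b", "c")

    def test_degenerate_one_phone_path(self):
        inv = make_inventory(["#a#"])
        g = build_triphone_graph(np.array([1.0]), inv)
        cands = enumerate_candidates(g)
        assert [c.phones for c in cands] == [("a",)]

    def test_random_dag_matches_dfs_oracle(self, rng):
        # build an inventory from random short words, enumerate on support 1
        words = ["".join(rng.choice(list("abc"), size=rng.integers(2, 5)))
                 for _ in range(6)]
        cues = {}
        for w in words:
            for t in triphone_tuples(WordForm(tuple(w))):
                cues.setdefault(cue_string(t), t)
        inv = CueInventory(list(cues), kind="triphone",
                           tuples=list(cues.values()))
        g = build_triphone_graph(np.ones(len(inv)), inv)

        # exhaustive DFS oracle over the same vertex/edge relation
        def dfs_paths():
            tuples = {c: tuple(c) for c in inv.cues}
            succ = {u: [v for v in inv.cues
                        if tuples[u][-2:] == tuples[v][:2] and u != v]
                    for u in inv.cues}
            out = set()

            def walk(path):
                node = path[-1]
                if tuples[node][-1] == "#" and len(path) >= 1:
                    out.add(tuple(path))
                for nxt in succ[node]:
                    if nxt not in path:
                        walk(path + [nxt])

            for s in inv.cues:
                if tuples[s][0] == "#":
                    walk([s])
            return out

        got = {c.triphones for c in enumerate_candidates(g, max_paths=10 ** 6)}
        assert got == dfs_paths()

    def test_merge_then_reencode_roundtrip(self, loks_fixture):
        inv, sup = loks_fixture
        g = build_triphone_graph(sup, inv, threshold=0.1)
        for cand in enumerate_candidates(g):
            assert encode_triplets(WordForm(cand.phones)) == list(cand.triphones)

    def test_truncation_at_max_paths(self, loks_fixture):
        inv, sup = loks_fixture
        g = build_triphone_graph(sup, inv, threshold=0.1)
        assert len(enumerate_candidates(g, max_paths=2)) == 2

    def test_non_overlapping_merge_rejected(self):
        with pytest.raises(LdlexError):
            merge_path([("p", "q", "r"), ("q", "z", "x")])


class TestSynthesisByAnalysis:
    def test_exact_reconstruction_selected(self, rng):
        inv = make_inventory(["#ab", "abc", "bc#", "#ac", "ac#"])
        H = LinearMapping("H_p", rng.normal(size=(5, 6)))
        g = build_triphone_graph(np.ones(5), inv)
        cands = enumerate_candidates(g)
        target_cand = next(c for c in cands if c.phones == ("a", "b", "c"))
        s_target = path_cue_vector(target_cand, inv) @ H.matrix
        cands, best = synthesis_by_analysis(cands, H, s_target, inv)
        assert best.phones == ("a", "b", "c")
        assert best.correlation_with_target == pytest.approx(1.0)

    def test_ranking_matches_bruteforce(self, rng):
        inv = make_inventory(["#ab", "abc", "bc#", "#ac", "ac#"])
        H = LinearMapping("H_p", rng.normal(size=(5, 6)))
        g = build_triphone_graph(np.ones(5), inv)
        cands = enumerate_candidates(g)
        s_target = rng.normal(size=6)
        cands, best = synthesis_by_analysis(cands, H, s_target, inv)
        assert best.correlation_with_target == pytest.approx(
            max(c.correlation_with_target for c in cands))

    def test_tiebreak_prefers_shorter_then_lexicographic(self):
        inv = make_inventory(["#ab", "ab#", "#ba", "ba#"])
        H = LinearMapping("H_p", np.zeros((4, 3)))  # all correlations 0
        g = build_triphone_graph(np.ones(4), inv)
        cands = enumerate_candidates(g)
        _, best = synthesis_by_analysis(cands, H, np.array([1.0, 2.0, 3.0]), inv)
        assert best.phones == ("a", "b")  # shortest set tie -> lexicographic

    def test_empty_candidates(self):
        inv = make_inventory(["#ab"])
        H = LinearMapping("H_p", np.zeros((1, 3)))
        cands, best = synthesis_by_analysis([], H, np.ones(3), inv)
        assert cands == [] and best is None


class TestMeasures:
    def test_aldc_loks_example_is_four_thirds(self):
        from ldlex.production import CandidatePath
        cands = [CandidatePath((), tuple(p)) for p in ("lok", "oks", "ok")]
        value = aldc(cands, WordForm(tuple("loks")))
        assert value == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_aldc_identical_candidate_zero(self):
        from ldlex.production import CandidatePath
        cands = [CandidatePath((), tuple("loks"))]
        assert aldc(cands, WordForm(tuple("loks"))) == 0.0

    def test_aldc_empty_is_phone_count(self):
        assert aldc([], WordForm(tuple("loks"))) == 4.0

    def test_scpp_is_maximum(self, rng):
        s = rng.normal(size=8)
        near = 0.9 * s + 0.1 * rng.normal(size=8)
        far = rng.normal(size=8)
        vecs = [far, near]
        from ldlex import pearson
        assert scpp(s, vecs) == pytest.approx(max(pearson(s, v) for v in vecs))

    def test_scpp_empty_zero(self, rng):
        assert scpp(rng.normal(size=5), []) == 0.0

    def test_scpp_self_candidate_one(self, rng):
        s = rng.normal(size=5)
        assert scpp(s, [s]) == pytest.approx(1.0)

    def test_scpp_affine_invariance(self, rng):
        s = rng.normal(size=6)
        v = rng.normal(size=6)
        assert scpp(s, [v]) == pytest.approx(scpp(s, [3.0 * v + 2.0]))


class TestSpeakPipeline:
    def test_training_words_recover_own_form(self, small_results):
        frac = small_results.recover_training_forms()
        assert frac >= 0.9

    def test_candidate_contract_on_outputs(self, small_results):
        m = small_results.model
        entry = m.lexicon[0]
        res = small_results.produce(m.space.S[0], entry.form)
        for c in res.candidates:
            assert c.triphones[0].startswith("#")
            assert c.triphones[-1].endswith("#")
            for u, v in zip(c.triphones, c.triphones[1:]):
                assert tuple(u)[-2:] == tuple(v)[:2]

    def test_zero_semantics_zero_support(self, small_results):
        from ldlex import predict_triphone_support
        sup = predict_triphone_support(
            np.zeros(small_results.model.space.dim), small_results.mappings["G"])
        assert np.allclose(sup, 0.0)

    def test_own_triphones_top_supported(self, small_results):
        from ldlex import predict_triphone_support
        m = small_results.model
        sup = predict_triphone_support(m.space.S[3], small_results.mappings["G"])
        own = np.flatnonzero(m.T_a.values[3])
        ranked = np.argsort(sup)[::-1][: len(own)]
        assert len(set(own) & set(ranked)) >= len(own) - 1
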