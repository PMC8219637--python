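"""Dual-route comprehension and the semantic-neighborhood measures."""

import numpy as np
import pandas as pd
import pytest

from ldlex import (LdlexError, LinearMapping, SemanticSpace, alc,
                   comprehend_direct, comprehend_indirect, drc, ednn,
                   inflectional_profile, nnc, pca_measures, pearson)


@pytest.fixture()
def space(rng):
    return SemanticSpace(rng.normal(size=(20, 6)),
                         [f"w{i}" for i in range(20)])


class TestRoutes:
    def test_zero_cue_zero_semantics(self, rng):
        F = LinearMapping("F", rng.normal(size=(7, 4)))
        assert np.allclose(comprehend_direct(np.zeros(7), F), 0.0)

    def test_indirect_associativity(self, rng):
        E = LinearMapping("E", rng.normal(size=(7, 5)))
        H = LinearMapping("H_c", rng.normal(size=(5, 4)))
        c = rng.normal(size=7)
        composed = LinearMapping("EH", E.matrix @ H.matrix)
        assert np.allclose(comprehend_indirect(c, E, H),
                           comprehend_direct(c, composed), atol=1e-10)

    def test_training_words_reconstructed(self, small_results):
        m = small_results.model
        c = m.C_o.values[5].astype(float)
        s1 = comprehend_direct(c, small_results.mappings["F"])
        assert pearson(s1, m.space.S[5]) > 0.99


class TestNeighborhoodMeasures:
    def test_ednn_zero_for_space_row(self, space):
        assert ednn(space.S[3], space) == 0.0

    def test_ednn_three_four_five(self):
        sp = SemanticSpace(np.zeros((1, 6)), ["w"])
        v = np.zeros(6)
        v[0], v[1] = 3.0, 4.0
        assert ednn(v, sp) == pytest.approx(5.0)

    def test_nnc_affine_invariance(self, space):
        v = 2.0 * space.S[4] + 1.0
        assert nnc(v, space) == pytest.approx(1.0)

    def test_nnc_negated_row(self, space):
        v = -space.S[0]
        r = [pearson(v, row) for row in space.S]
        assert nnc(v, space) == pytest.approx(max(r))
        assert min(r) == pytest.approx(-1.0)

    def test_alc_single_row_equals_nnc(self, rng):
        sp = SemanticSpace(rng.normal(size=(1, 6)), ["w"])
        v = rng.normal(size=6)
        assert alc(v, sp) == pytest.approx(nnc(v, sp))

    def test_bruteforce_oracles(self, rng):
        sp = SemanticSpace(rng.normal(size=(50, 10)),
                           [f"w{i}" for i in range(50)])
        for _ in range(10):
            v = rng.normal(size=10)
            dists = [np.linalg.norm(v - row) for row in sp.S]
            corrs = [pearson(v, row) for row in sp.S]
            assert ednn(v, sp) == pytest.approx(min(dists), abs=1e-10)
            assert nnc(v, sp) == pytest.approx(max(corrs), abs=1e-10)
            assert alc(v, sp) == pytest.approx(np.mean(corrs), abs=1e-10)

    def test_nnc_at_least_alc(self, space, rng):
        for _ in range(20):
            v = rng.normal(size=6)
            assert nnc(v, space) >= alc(v, space)

    def test_drc_symmetry_and_extremes(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert drc(a, b) == pytest.approx(drc(b, a))
        assert drc(a, a) == pytest.approx(1.0)
        assert drc(a, -a) == pytest.approx(-1.0)

    def test_drc_zero_variance_rejected(self):
        with pytest.raises(LdlexError):
            drc(np.ones(5), np.arange(5.0))


class TestInflectionalProfile:
    def test_identical_category_orthogonal_rest(self):
        v = np.eye(4)
        vecs = np.vstack([v[0], v[0], v[1], v[2]])
        labels = ["plural", "plural", "past", "uninflected"]
        prof = inflectional_profile(vecs, labels)
        cell = prof.set_index(["category", "comparison"])["mean_correlation"]
        assert cell[("plural", "Same")] == pytest.approx(1.0)
        assert abs(cell[("plural", "Different")]) < 0.5

    def test_cells_match_pairwise_loop_oracle(self, rng):
        vecs = rng.normal(size=(6, 5))
        labels = ["a", "a", "a", "b", "b", "uninflected"]
        prof = inflectional_profile(vecs, labels)
        cell = prof.set_index(["category", "comparison"])

        def loop(cat, kind):
            vals = []
            members = [i for i, l in enumerate(labels) if l == cat]
            for i in members:
                for j in range(6):
                    if j == i:
                        continue
                    if kind == "Same" and labels[j] == cat:
                        vals.append(pearson(vecs[i], vecs[j]))
                    elif kind == "Uninflected" and labels[j] == "uninflected":
                        vals.append(pearson(vecs[i], vecs[j]))
                    elif kind == "Different" and labels[j] not in (cat, "uninflected"):
                        vals.append(pearson(vecs[i], vecs[j]))
            return np.mean(vals), len(vals)

        for cat in ("a", "b"):
            for kind in ("Same", "Different", "Uninflected"):
                mean, n = loop(cat, kind)
                assert cell.loc[(cat, kind), "mean_correlation"] == \
                    pytest.approx(mean, abs=1e-10)
                assert cell.loc[(cat, kind), "n"] == n

    def test_dual_membership_counts_in_both(self, rng):
        vecs = rng.normal(size=(4, 5))
        labels = [("superlative", "past"), ("superlative",), ("past",),
                  ("uninflected",)]
        prof = inflectional_profile(vecs, labels)
        cell = prof.set_index(["category", "comparison"])["n"]
        assert cell[("superlative", "Same")] == 2  # pair (0,1) both directions
        assert cell[("past", "Same")] == 2

    def test_sparse_category_flagged(self, rng):
        vecs = rng.normal(size=(2, 4))
        prof = inflectional_profile(vecs, ["lonely", "uninflected"])
        same = prof.query("category == 'lonely' and comparison == 'Same'")
        assert int(same["n"].iloc[0]) == 0
        assert np.isnan(same["mean_correlation"].iloc[0])

    def test_two_set_mode_against_words(self, rng):
        pw = rng.normal(size=(3, 5))
        words = rng.normal(size=(4, 5))
        prof = inflectional_profile(pw, ["plural", "plural", "uninflected"],
                                    words, ["plural", "past", "uninflected",
                                            "uninflected"])
        cell = prof.set_index(["category", "comparison"])["n"]
        assert cell[("plural", "Same")] == 2
        assert cell[("plural", "Different")] == 2
        assert cell[("plural", "Uninflected")] == 4


class TestPCA:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_measures(df, ["a", "b"], k=1)
        assert res.variance_proportions[0] == pytest.approx(1.0)

    def test_loadings_match_eigendecomposition(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        res = pca_measures(df, list("abcd"), k=4)
        Z = (df - df.mean()) / df.std(ddof=1)
        eigval, eigvec = np.linalg.eigh(np.cov(Z.to_numpy().T))
        order = np.argsort(eigval)[::-1]
        eigvec = eigvec[:, order]
        for j in range(4):
            got = res.loadings.iloc[:, j].to_numpy()
            ref = eigvec[:, j]
            assert (np.allclose(got, ref, atol=1e-8)
                    or np.allclose(got, -ref, atol=1e-8))

    def test_full_rank_variance_sums_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz"))
        res = pca_measures(df, list("xyz"), k=3)
        assert res.variance_proportions.sum() == pytest.approx(1.0)

    def test_sign_convention(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz"))
        res = pca_measures(df, list("xyz"), k=3)
        for col in res.loadings.columns:
            load = res.loadings[col].to_numpy()
            assert load[np.abs(load).argmax()] > 0

    def test_constant_variable_rejected(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(LdlexError):
            pca_measures(df, ["a", "b"], k=1)
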