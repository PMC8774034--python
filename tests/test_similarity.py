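import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaelink.errors import DataError, DegenerateProfileError
from gaelink.similarity import (
    fuse_disease_similarity,
    fuse_mirna_similarity,
    gaussian_bandwidth,
    gaussian_profile_similarity,
    semantic_contribution_wang,
    semantic_contribution_xuan,
    semantic_similarity,
    semantic_similarity_matrix,
)
from gaelink.types import AssociationMatrix, DiseaseDAG, SimilarityMatrix

from .conftest import random_association


def assert_similarity_invariants(S):
    assert np.abs(S.values - S.values.T).max() <= 1e-9
    assert S.values.min() >= 0.0 and S.values.max() <= 1.0
    assert np.allclose(np.diag(S.values), 1.0)


class TestGaussianBandwidth:
    def test_identity_rows(self, identity_assoc):
        assert gaussian_bandwidth(identity_assoc, "mirna").value == 1.0

    def test_single_row(self):
        Y = AssociationMatrix(np.array([[1.0, 1.0]]), ["m0"], ["d0", "d1"])
        assert gaussian_bandwidth(Y, "mirna").value == 2.0

    def test_disease_axis(self, identity_assoc):
        assert gaussian_bandwidth(identity_assoc, "disease").value == 1.0

    def test_all_zero_rejected(self):
        Y = AssociationMatrix(np.zeros((2, 2)), ["a", "b"], ["c", "d"])
        with pytest.raises(DegenerateProfileError):
            gaussian_bandwidth(Y, "mirna")


class TestGaussianProfileSimilarity:
    def test_diagonal_is_one(self, identity_assoc):
        S = gaussian_profile_similarity(identity_assoc, "mirna")
        assert np.allclose(np.diag(S.values), 1.0)

    def test_golden_off_diagonal(self, identity_assoc):
        # theta = 1, squared distance between the two unit rows = 2
        S = gaussian_profile_similarity(identity_assoc, "mirna")
        assert S.values[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_identical_rows(self):
        Y = AssociationMatrix(
            np.array([[1.0, 0.0], [1.0, 0.0]]), ["a", "b"], ["c", "d"]
        )
        S = gaussian_profile_similarity(Y, "mirna")
        assert S.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariants_random(self, seed):
        rng = np.random.default_rng(seed)
        Y = random_association(rng, rng.integers(2, 8), rng.integers(2, 8))
        for axis in ("mirna", "disease"):
            assert_similarity_invariants(gaussian_profile_similarity(Y, axis))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        Y = random_association(rng, 6, 5)
        perm = rng.permutation(6)
        Yp = AssociationMatrix(
            Y.values[perm], [Y.mirna_ids[i] for i in perm], Y.disease_ids
        )
        S = gaussian_profile_similarity(Y, "mirna")
        Sp = gaussian_profile_similarity(Yp, "mirna")
        assert np.allclose(Sp.values, S.values[np.ix_(perm, perm)], atol=1e-12)


class TestFuseMirnaSimilarity:
    def _gms(self, rng, ids):
        Y = random_association(rng, len(ids), 4)
        Y = AssociationMatrix(Y.values, ids, Y.disease_ids)
        return gaussian_profile_similarity(Y, "mirna")

    def test_full_coverage_equals_curated(self):
        rng = np.random.default_rng(0)
        GMS = self._gms(rng, ["a", "b", "c"])
        curated = np.array([[1.0, 0.4, 0.3], [0.4, 1.0, 0.2], [0.3, 0.2, 1.0]])
        MS = SimilarityMatrix(curated, ["a", "b", "c"])
        fused = fuse_mirna_similarity(MS, GMS)
        assert np.allclose(fused.values, curated)
        assert fused.curated_mask.all()

    def test_no_coverage_equals_gaussian(self):
        rng = np.random.default_rng(1)
        GMS = self._gms(rng, ["a", "b", "c"])
        fused = fuse_mirna_similarity(None, GMS)
        assert np.allclose(fused.values, GMS.values)
        assert not fused.curated_mask.any()

    def test_partial_coverage_branches(self):
        rng = np.random.default_rng(2)
        GMS = self._gms(rng, ["a", "b", "c"])
        MS = SimilarityMatrix(np.array([[1.0, 0.7], [0.7, 1.0]]), ["a", "b"])
        fused = fuse_mirna_similarity(MS, GMS)
        assert fused.values[0, 1] == pytest.approx(0.7)
        assert fused.values[0, 2] == pytest.approx(GMS.values[0, 2])
        assert fused.values[1, 2] == pytest.approx(GMS.values[1, 2])
        assert fused.curated_mask[0, 1] and not fused.curated_mask[0, 2]

    def test_unknown_label_rejected(self):
        rng = np.random.default_rng(3)
        GMS = self._gms(rng, ["a", "b"])
        MS = SimilarityMatrix(np.eye(2), ["a", "zz"])
        with pytest.raises(DataError):
            fuse_mirna_similarity(MS, GMS)


class TestWangContribution:
    def test_self_contribution(self, chain_dag):
        assert semantic_contribution_wang(chain_dag, "D")["i"] == 1.0

    def test_chain_decay(self, chain_dag):
        sc = semantic_contribution_wang(chain_dag, "D")
        assert sc["p"] == pytest.approx(0.5, abs=1e-12)
        assert sc["g"] == pytest.approx(0.25, abs=1e-12)

    def test_diamond_max(self, diamond_dag):
        sc = semantic_contribution_wang(diamond_dag, "D")
        assert sc["g"] == pytest.approx(0.25, abs=1e-12)

    def test_unknown_disease_rejected(self, chain_dag):
        with pytest.raises(DataError):
            semantic_contribution_wang(chain_dag, "nope")

    @pytest.mark.parametrize("depth", [1, 3, 5, 7])
    def test_path_closed_form(self, depth):
        nodes = [f"n{k}" for k in range(depth + 1)]
        edges = {(nodes[k], nodes[k + 1]) for k in range(depth)}
        dag = DiseaseDAG(nodes, edges, {"D": nodes[0]})
        sc = semantic_contribution_wang(dag, "D")
        for k in range(depth + 1):
            assert sc[nodes[k]] == pytest.approx(0.5**k, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(2, 13))
        nodes = [f"t{k}" for k in range(n_nodes)]
        edges = set()
        for child in range(1, n_nodes):
            for parent in rng.choice(child, size=min(child, 2), replace=False):
                if rng.random() < 0.8:
                    edges.add((nodes[child], nodes[int(parent)]))
        leaf = nodes[-1]
        dag = DiseaseDAG(nodes, edges, {"D": leaf})
        sc = semantic_contribution_wang(dag, "D")
        children = {t: [] for t in nodes}
        for c, p in edges:
            children[p].append(c)

        def oracle(node):  # max over descending paths of 0.5^length
            if node == leaf:
                return 1.0
            best = 0.0
            for child in children[node]:
                down = oracle(child)
                if down > 0:
                    best = max(best, 0.5 * down)
            return best

        for node, value in sc.items():
            assert value == pytest.approx(oracle(node), abs=1e-12)


class TestXuanContribution:
    def test_shared_term(self, xuan_toy_dag):
        assert semantic_contribution_xuan(xuan_toy_dag, "p") == pytest.approx(
            -math.log(2 / 3), abs=1e-12
        )

    def test_ubiquitous_term_zero(self):
        dag = DiseaseDAG(
            nodes=["root", "x", "y"],
            parent_edges={("x", "root"), ("y", "root")},
            disease_roots={"Dx": "x", "Dy": "y"},
        )
        assert semantic_contribution_xuan(dag, "root") == pytest.approx(0.0, abs=1e-12)

    def test_rare_term(self):
        nodes = [f"v{k}" for k in range(10)]
        dag = DiseaseDAG(nodes, set(), {f"D{k}": nodes[k] for k in range(10)})
        assert semantic_contribution_xuan(dag, "v0") == pytest.approx(
            -math.log(0.1), abs=1e-12
        )

    def test_uncovered_term_rejected(self, xuan_toy_dag):
        with pytest.raises(DataError):
            semantic_contribution_xuan(xuan_toy_dag, "absent")


class TestSemanticSimilarity:
    def test_self_similarity_one(self, chain_dag):
        assert semantic_similarity(chain_dag, "D", "D", "wang") == pytest.approx(1.0)

    def test_sibling_golden(self, sibling_dag):
        value = semantic_similarity(sibling_dag, "Di", "Dj", "wang")
        assert value == pytest.approx(1 / 3, abs=1e-12)

    def test_disjoint_closures(self):
        dag = DiseaseDAG(["a", "b"], set(), {"Da": "a", "Db": "b"})
        assert semantic_similarity(dag, "Da", "Db", "wang") == 0.0
        assert semantic_similarity(dag, "Da", "Db", "xuan") == 0.0

    def test_symmetry(self, sibling_dag):
        for model in ("wang", "xuan"):
            assert semantic_similarity(
                sibling_dag, "Di", "Dj", model
            ) == pytest.approx(semantic_similarity(sibling_dag, "Dj", "Di", model))

    def test_monotone_in_shared_ancestors(self):
        # adding a common ancestor never decreases the similarity
        base = DiseaseDAG(
            ["i", "j", "p"], {("i", "p"), ("j", "p")}, {"Di": "i", "Dj": "j"}
        )
        extended = DiseaseDAG(
            ["i", "j", "p", "g"],
            {("i", "p"), ("j", "p"), ("p", "g")},
            {"Di": "i", "Dj": "j"},
        )
        assert semantic_similarity(extended, "Di", "Dj", "wang") >= semantic_similarity(
            base, "Di", "Dj", "wang"
        )

    def test_matrix_agrees_with_pairwise(self, sibling_dag):
        for model in ("wang", "xuan"):
            S = semantic_similarity_matrix(sibling_dag, ["Di", "Dj"], model)
            assert S.values[0, 1] == pytest.approx(
                semantic_similarity(sibling_dag, "Di", "Dj", model)
            )
            assert_similarity_invariants(S)


class TestFuseDiseaseSimilarity:
    def _setup(self, seed=0, n=4):
        rng = np.random.default_rng(seed)
        Y = random_association(rng, 5, n)
        return gaussian_profile_similarity(Y, "disease"), Y.disease_ids

    def test_full_coverage_is_mean(self, sibling_dag):
        GDS, ids = self._setup(n=2)
        DS1 = SimilarityMatrix(
            np.array([[1.0, 1 / 3], [1 / 3, 1.0]]), ids
        )
        DS2 = SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ids)
        fused = fuse_disease_similarity(DS1, DS2, GDS, set(ids))
        assert fused.values[0, 1] == pytest.approx(5 / 12, abs=1e-12)

    def test_no_coverage_is_gaussian(self):
        GDS, ids = self._setup(n=3)
        DS1 = SimilarityMatrix(np.eye(2), ids[:2])
        DS2 = SimilarityMatrix(np.eye(2), ids[:2])
        fused = fuse_disease_similarity(DS1, DS2, GDS, set())
        assert np.allclose(fused.values, GDS.values)

    def test_partial_coverage(self):
        GDS, ids = self._setup(n=3)
        two = ids[:2]
        DS1 = SimilarityMatrix(np.array([[1.0, 0.8], [0.8, 1.0]]), two)
        DS2 = SimilarityMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), two)
        fused = fuse_disease_similarity(DS1, DS2, GDS, set(two))
        assert fused.values[0, 1] == pytest.approx(0.6)
        assert fused.values[0, 2] == pytest.approx(GDS.values[0, 2])
        assert_similarity_invariants(fused)

    def test_label_mismatch_rejected(self):
        GDS, ids = self._setup(n=3)
        DS1 = SimilarityMatrix(np.eye(2), ["zzz", "yyy"])
        DS2 = SimilarityMatrix(np.eye(2), ["zzz", "yyy"])
        with pytest.raises(DataError):
            fuse_disease_similarity(DS1, DS2, GDS, {"zzz"})
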