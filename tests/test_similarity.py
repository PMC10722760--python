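"""Similarity kernels: hand-derived examples, brute-force oracle, properties."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdlink import (
    AssociationNetwork,
    DiseaseOntologyGraph,
    SimilarityConfig,
    build_similarity_bundle,
    cosine_similarity,
    disease_semantic_similarity,
    fuse,
    gip_similarity,
    microbe_functional_similarity,
    semantic_contributions,
    semantic_value,
    sigmoid_kernel_similarity,
)
from mdlink.synthetic import generate_random_dag

from .conftest import random_network


# --- independent oracle: path enumeration over the DAG ---------------------

def brute_force_contributions(dag: DiseaseOntologyGraph, d: str, FC: float) -> dict:
    """SC_d(k) = max over directed paths d -> k of FC^len(path), by full
    enumeration of simple upward paths."""
    best = {d: 1.0}
    stack = [(d, 0)]
    while stack:
        node, length = stack.pop()
        for p in dag.parents(node):
            val = FC ** (length + 1)
            if val > best.get(p, -1.0):
                best[p] = val
            stack.append((p, length + 1))
    return best


class TestSemanticContributions:
    def test_chain_values(self, chain_dag):
        sc = semantic_contributions(chain_dag, "C", FC=0.5)
        assert sc == {"C": 1.0, "B": 0.5, "A": 0.25}

    def test_isolated_term(self):
        dag = DiseaseOntologyGraph(frozenset({"X"}), {})
        assert semantic_contributions(dag, "X") == {"X": 1.0}

    def test_diamond_takes_max_over_paths(self):
        dag = DiseaseOntologyGraph.from_edges(
            [("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")]
        )
        sc = semantic_contributions(dag, "D", FC=0.5)
        assert sc["A"] == pytest.approx(0.25)

    def test_unknown_term_raises(self, chain_dag):
        with pytest.raises(KeyError):
            semantic_contributions(chain_dag, "Z")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_path_enumeration_oracle(self, seed):
        """Recursive DAG contributions equal brute-force path enumeration exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        dag = generate_random_dag(n, depth=int(rng.integers(1, 5)), branching=3,
                                  seed=seed)
        for d in sorted(dag.terms):
            assert semantic_contributions(dag, d, 0.5) == pytest.approx(
                brute_force_contributions(dag, d, 0.5)
            )


class TestSemanticValueAndDS:
    def test_semantic_value_sums(self):
        assert semantic_value({"C": 1.0, "B": 0.5, "A": 0.25}) == pytest.approx(1.75)
        assert semantic_value({"d": 1.0}) == 1.0
        with pytest.raises(ValueError):
            semantic_value({})

    def test_chain_pair_similarity(self, chain_dag):
        """(B, C) on the chain: shared {A, B}, DS = 2.25 / 3.25."""
        DS = disease_semantic_similarity(chain_dag, ["B", "C"])
        assert DS[0, 1] == pytest.approx(2.25 / 3.25)
        assert DS[0, 0] == DS[1, 1] == 1.0

    def test_disjoint_roots_are_dissimilar(self):
        dag = DiseaseOntologyGraph.from_edges([("b1", "a1"), ("b2", "a2")])
        DS = disease_semantic_similarity(dag, ["a1", "a2"])
        assert DS[0, 1] == 0.0

    def test_missing_disease_gets_neutral_row(self, chain_dag):
        DS = disease_semantic_similarity(chain_dag, ["B", "unknown-disease"])
        assert DS[1, 1] == 1.0
        assert DS[0, 1] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_fc_monotonicity_for_shared_ancestry(self, seed):
        """Raising the decay factor never lowers DS between diseases with
        identical proper-ancestor closures (there DS = s/(1+s), s increasing)."""
        dag = generate_random_dag(8, depth=3, branching=2, seed=seed)
        # attach two fresh sibling leaves under the same random parent
        parent = sorted(dag.terms)[int(np.random.default_rng(seed).integers(8))]
        edges = [
            (c, p) for c, ps in dag.child_to_parents.items() for p in ps
        ] + [("leafX", parent), ("leafY", parent)]
        from mdlink import DiseaseOntologyGraph

        dag2 = DiseaseOntologyGraph.from_edges(edges)
        lo = disease_semantic_similarity(dag2, ["leafX", "leafY"], SimilarityConfig(FC=0.2))
        hi = disease_semantic_similarity(dag2, ["leafX", "leafY"], SimilarityConfig(FC=0.8))
        assert hi[0, 1] >= lo[0, 1] - 1e-12

    def test_fc_non_monotone_in_general(self):
        """DS need not be monotone in FC: an ancestor-descendant pair where
        the descendant carries extra unshared ancestors loses similarity as
        FC grows (the unshared mass inflates the denominator faster)."""
        dag = DiseaseOntologyGraph.from_edges(
            [("j", "i"), ("j", "u"), ("u", "v")]
        )
        lo = disease_semantic_similarity(dag, ["i", "j"], SimilarityConfig(FC=0.2))
        hi = disease_semantic_similarity(dag, ["i", "j"], SimilarityConfig(FC=0.8))
        assert hi[0, 1] < lo[0, 1]


class TestGIP:
    def test_orthogonal_unit_profiles(self):
        K, gamma = gip_similarity(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert gamma == pytest.approx(1.0)
        assert K[0, 1] == pytest.approx(np.exp(-2.0))
        assert K[0, 0] == K[1, 1] == 1.0

    def test_all_zero_profiles_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            gip_similarity(np.zeros((3, 4)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        P = (rng.random((7, 5)) < 0.4).astype(float)
        P[0, 0] = 1  # keep non-degenerate
        K, _ = gip_similarity(P)
        perm = rng.permutation(7)
        K_perm, _ = gip_similarity(P[perm])
        assert np.allclose(K_perm, K[np.ix_(perm, perm)])


class TestCosineAndSigmoid:
    def test_cosine_examples(self):
        K = cosine_similarity(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        assert K[0, 1] == 0.0
        assert K[0, 2] == pytest.approx(1 / np.sqrt(2))

    def test_cosine_zero_profile_convention(self):
        K = cosine_similarity(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert K[0, 0] == 0.0 and K[0, 1] == 0.0

    def test_sigmoid_examples(self):
        P = np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0]])
        K = sigmoid_kernel_similarity(P, norm=4)
        assert K[0, 0] == pytest.approx(np.tanh(1.0))
        assert K[1, 1] == 0.0

    def test_sigmoid_norm_contract(self):
        with pytest.raises(ValueError):
            sigmoid_kernel_similarity(np.ones((2, 2)), norm=0)


class TestFunctionalSimilarity:
    def test_shared_single_disease(self):
        net = AssociationNetwork(("m1", "m2"), ("d1",), np.array([[1], [1]]))
        FMS = microbe_functional_similarity(net, np.eye(1))
        assert FMS[0, 1] == pytest.approx(1.0)

    def test_best_match_average(self):
        """D_i={d1}, D_j={d2,d3}, DS(d1,d2)=0.6, DS(d1,d3)=0.2 -> 1.4/3."""
        net = AssociationNetwork(
            ("m1", "m2"), ("d1", "d2", "d3"), np.array([[1, 0, 0], [0, 1, 1]])
        )
        DS = np.eye(3)
        DS[0, 1] = DS[1, 0] = 0.6
        DS[0, 2] = DS[2, 0] = 0.2
        FMS = microbe_functional_similarity(net, DS)
        assert FMS[0, 1] == pytest.approx((0.6 + 0.6 + 0.2) / 3)

    def test_isolated_microbe_zero_off_diagonal(self):
        net = AssociationNetwork(("m1", "m2"), ("d1",), np.array([[0], [1]]))
        FMS = microbe_functional_similarity(net, np.eye(1))
        assert FMS[0, 1] == 0.0 and FMS[0, 0] == 1.0


class TestFusion:
    def test_mean_of_identical_matrices(self):
        M = np.full((3, 3), 0.4)
        assert np.allclose(fuse([M, M, M, M]), M)

    def test_mean_of_constants(self):
        mats = [np.full((2, 2), v) for v in (0.1, 0.2, 0.3, 0.4)]
        assert np.allclose(fuse(mats), 0.25)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fuse([np.eye(2)] * 3)


class TestBundleProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_all_kernels_symmetric_bounded(self, seed):
        """All eight kernels + fusions: symmetric, in [0,1], correct diagonals."""
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_m=10, n_d=6)
        dag = generate_random_dag(6, depth=3, branching=2, seed=seed)
        # map some diseases onto DAG terms via renaming
        terms = sorted(dag.terms)
        net = AssociationNetwork(net.microbe_ids, tuple(terms), net.Y)
        b = build_similarity_bundle(net, dag)
        for name in ("DS", "GDS", "CDS", "SDS", "FMS", "GMS", "CMS", "SMS", "FuD", "FuM"):
            M = getattr(b, name)
            assert np.allclose(M, M.T, atol=1e-12), name
            assert M.min() >= -1e-12 and M.max() <= 1 + 1e-12, name
        for name in ("DS", "GDS", "GMS"):
            assert np.allclose(np.diag(getattr(b, name)), 1.0), name
        # cosine diagonal is 1 exactly where the profile is nonzero
        nz_d = net.Y.sum(axis=0) > 0
        assert np.allclose(np.diag(b.CDS)[nz_d], 1.0)
        assert np.allclose(np.diag(b.CDS)[~nz_d], 0.0)

    def test_mask_pairs_zeroes_before_profiles(self, tiny_net):
        b_masked = build_similarity_bundle(tiny_net, mask_pairs={(1, 1)})
        expected = tiny_net.with_masked_pairs({(1, 1)})
        b_direct = build_similarity_bundle(expected)
        assert np.allclose(b_masked.GMS, b_direct.GMS)
        assert np.allclose(b_masked.FuD, b_direct.FuD)

    def test_empty_mask_is_identity(self, tiny_net):
        a = build_similarity_bundle(tiny_net)
        c = build_similarity_bundle(tiny_net, mask_pairs=set())
        assert np.allclose(a.FuM, c.FuM) and np.allclose(a.FuD, c.FuD)

    def test_masking_everything_surfaces_gip_error(self, tiny_net):
        with pytest.raises(ValueError, match="degenerate"):
            build_similarity_bundle(tiny_net, mask_pairs={(0, 0), (1, 0), (1, 1)})
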