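"""Similarity builders: Jaccard, ontology hyponymy (with a brute-force
path-enumeration oracle), cosine views, and the learned attribute fusions."""

import networkx as nx
import numpy as np
import pytest

from adrfuse.autodiff import Tensor
from adrfuse.similarity import (
    DrugProjectionParams,
    OntologyDAG,
    SimilarityMatrix,
    ViewAttentionParams,
    attention_combine_views,
    build_ontology_dag,
    cosine_similarity_matrix,
    hyponymy_similarity,
    hyponymy_similarity_matrix,
    jaccard_similarity_matrix,
    project_drug_attributes,
    semantic_contributions,
    semantic_value,
    side_drug_profile_matrix,
)
from adrfuse.corpus import FrequencyMatrix


# ------------------------------------------------------------------ Jaccard
class TestJaccard:
    def test_hand_computed_value(self):
        m = np.array([[1, 0, 1, 0], [1, 1, 0, 0]])
        sim = jaccard_similarity_matrix(m, ["a", "b"])
        assert sim.values[0, 1] == pytest.approx(1 / 3)

    def test_identical_nonzero_rows(self):
        m = np.array([[1, 0, 1], [1, 0, 1]])
        sim = jaccard_similarity_matrix(m, ["a", "b"])
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_two_empty_profiles(self):
        m = np.array([[0, 0], [0, 0]])
        sim = jaccard_similarity_matrix(m, ["a", "b"])
        assert sim.values[0, 1] == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            jaccard_similarity_matrix(np.array([[0, 2]]), ["a"])


# --------------------------------------------------------------- DAG builder
class TestOntologyDAGConstruction:
    def test_four_level_chain(self):
        dag = build_ontology_dag({"polycythemia": ["14.12.01.002"]})
        assert dag.graph.number_of_nodes() == 4
        assert dag.graph.number_of_edges() == 3
        assert dag.ancestors_of_node("14.12.01.002") == {"14.12.01.002", "14.12.01", "14.12", "14"}

    def test_multi_id_term_spans_branches(self):
        dag = build_ontology_dag({"t": ["1.1", "2.1"]})
        anc = set()
        for n in dag.term_nodes("t"):
            anc |= dag.ancestors_of_node(n)
        assert anc == {"1.1", "1", "2.1", "2"}

    def test_single_segment_is_isolated_root(self):
        dag = build_ontology_dag({"t": ["7"]})
        assert dag.graph.number_of_nodes() == 1
        assert dag.graph.number_of_edges() == 0


# ------------------------------------------------- semantic contributions
def _chain_dag(n: int) -> OntologyDAG:
    """n-node chain: leaf 'n' up to root '1' (dotted prefixes)."""
    dotted = ".".join(str(i + 1) for i in range(n))
    return build_ontology_dag({"leaf": [dotted]})


def brute_force_contributions(graph: nx.DiGraph, base: set[str], mu: float) -> dict[str, float]:
    """Oracle: D(s) = max over directed paths from any base node up to s of
    mu^len, by explicit path enumeration."""
    out: dict[str, float] = {}
    for b in base:
        stack = [(b, 0)]
        while stack:
            node, length = stack.pop()
            val = mu**length
            if val > out.get(node, -1.0):
                out[node] = val
            for parent in graph.successors(node):
                stack.append((parent, length + 1))
    return out


class TestSemanticContributions:
    def test_target_contribution_is_one(self):
        dag = _chain_dag(3)
        d = semantic_contributions(dag, "1.2.3", mu=0.5)
        assert d["1.2.3"] == 1.0

    def test_chain_decay(self):
        dag = _chain_dag(3)
        d = semantic_contributions(dag, "1.2.3", mu=0.5)
        assert d["1.2"] == pytest.approx(0.5)
        assert d["1"] == pytest.approx(0.25)

    def test_diamond_takes_max_path(self):
        # two paths leaf->root, lengths 1 and 2: D(root) = max(0.5, 0.25)
        g = nx.DiGraph()
        g.add_edges_from([("A", "p"), ("p", "r"), ("A", "r")])
        dag = OntologyDAG(g, {"A": {"A"}})
        d = semantic_contributions(dag, "A", mu=0.5)
        assert d["r"] == pytest.approx(0.5)

    def test_nodes_outside_closure_absent(self):
        dag = build_ontology_dag({"a": ["1.1"], "b": ["2.2"]})
        d = semantic_contributions(dag, "1.1", mu=0.5)
        assert set(d) == {"1.1", "1"}

    def test_missing_target_raises(self):
        dag = _chain_dag(2)
        with pytest.raises(KeyError):
            semantic_contributions(dag, "9.9", mu=0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration_oracle_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        g = nx.DiGraph()
        g.add_nodes_from(str(i) for i in range(n))
        for i in range(1, n):  # edges child -> parent respect node order: acyclic
            for j in rng.choice(i, size=min(i, int(rng.integers(1, 4))), replace=False):
                g.add_edge(str(i), str(j))
        target = str(n - 1)
        dag = OntologyDAG(g, {target: {target}})
        mu = float(rng.uniform(0.2, 0.8))
        mine = semantic_contributions(dag, target, mu)
        oracle = brute_force_contributions(g, {target}, mu)
        assert set(mine) == set(oracle)
        for k in mine:
            assert mine[k] == pytest.approx(oracle[k], abs=1e-12)


class TestSemanticValue:
    def test_isolated_node(self):
        dag = build_ontology_dag({"t": ["3"]})
        assert semantic_value(dag, "3", mu=0.5) == 1.0

    def test_three_node_chain(self):
        assert semantic_value(_chain_dag(3), "1.2.3", 0.5) == pytest.approx(1.75)

    def test_four_level_chain(self):
        assert semantic_value(_chain_dag(4), "1.2.3.4", 0.5) == pytest.approx(1.875)


class TestHyponymySimilarity:
    @pytest.fixture
    def sibling_dag(self):
        return build_ontology_dag({"s1": ["1.1.1"], "s2": ["1.1.2"]})

    def test_self_similarity_is_one(self, sibling_dag):
        assert hyponymy_similarity(sibling_dag, "s1", "s1", 0.5) == pytest.approx(1.0)

    def test_sibling_fixture_value(self, sibling_dag):
        # shared ancestors {1.1, 1}: (0.5+0.5+0.25+0.25) / (1.75+1.75) = 3/7
        assert hyponymy_similarity(sibling_dag, "s1", "s2", 0.5) == pytest.approx(3 / 7)

    def test_disjoint_roots(self):
        dag = build_ontology_dag({"a": ["1.1"], "b": ["2.1"]})
        assert hyponymy_similarity(dag, "a", "b", 0.5) == 0.0

    def test_unmapped_term_is_zero_to_others(self, sibling_dag):
        assert hyponymy_similarity(sibling_dag, "s1", "ghost", 0.5) == 0.0
        assert hyponymy_similarity(sibling_dag, "ghost", "ghost", 0.5) == 1.0

    def test_symmetry_and_range_random(self):
        rng = np.random.default_rng(3)
        terms = {}
        for i in range(12):
            depth = int(rng.integers(1, 5))
            terms[f"t{i}"] = [".".join(str(int(rng.integers(1, 4))) for _ in range(depth))]
        dag = build_ontology_dag(terms)
        names = list(terms)
        for _ in range(40):
            a, b = rng.choice(names, 2)
            sab = hyponymy_similarity(dag, a, b, 0.5)
            sba = hyponymy_similarity(dag, b, a, 0.5)
            assert sab == pytest.approx(sba, abs=1e-12)
            assert -1e-12 <= sab <= 1 + 1e-12

    def test_similarity_decreases_with_lca_distance_on_chain(self):
        # deeper shared prefix => higher similarity
        dag = build_ontology_dag(
            {"x": ["1.1.1.1"], "near": ["1.1.1.2"], "mid": ["1.1.2.1"], "far": ["1.2.1.1"]}
        )
        s_near = hyponymy_similarity(dag, "x", "near", 0.5)
        s_mid = hyponymy_similarity(dag, "x", "mid", 0.5)
        s_far = hyponymy_similarity(dag, "x", "far", 0.5)
        assert s_near > s_mid > s_far

    def test_matrix_agrees_with_pairwise(self):
        terms = {"a": ["1.1.1"], "b": ["1.1.2"], "c": ["2.1"]}
        dag = build_ontology_dag(terms)
        m = hyponymy_similarity_matrix(dag, ["A", "B", "C"], ["a", "b", "c"], 0.5)
        for i, ti in enumerate("abc"):
            for j, tj in enumerate("abc"):
                assert m.values[i, j] == pytest.approx(hyponymy_similarity(dag, ti, tj, 0.5))


# -------------------------------------------------------------------- cosine
class TestCosine:
    def test_identical_rows(self):
        s = cosine_similarity_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]), ["a", "b"], "side-word")
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows(self):
        s = cosine_similarity_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ["a", "b"], "side-word")
        assert s.values[0, 1] == pytest.approx(0.0)

    def test_hand_value(self):
        s = cosine_similarity_matrix(np.array([[1.0, 1.0], [1.0, 0.0]]), ["a", "b"], "side-word")
        assert s.values[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_zero_rows(self):
        s = cosine_similarity_matrix(np.array([[0.0, 0.0], [1.0, 0.0]]), ["a", "b"], "side-word")
        assert s.values[0, 1] == 0.0
        assert s.values[0, 0] == 1.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            cosine_similarity_matrix(np.array([[np.nan, 1.0]]), ["a"], "side-word")


class TestSideDrugProfile:
    def _fm(self, values):
        values = np.asarray(values)
        return FrequencyMatrix(values, [f"D{i}" for i in range(values.shape[0])],
                               [f"S{j}" for j in range(values.shape[1])])

    def test_shared_all_drugs(self):
        s = side_drug_profile_matrix(self._fm([[1, 2], [3, 4]]))
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_shared_no_drugs(self):
        s = side_drug_profile_matrix(self._fm([[1, 0], [0, 4]]))
        assert s.values[0, 1] == pytest.approx(0.0)

    def test_hand_value(self):
        s = side_drug_profile_matrix(self._fm([[1, 2], [3, 0], [0, 0]]))
        assert s.values[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_invariant_to_test_fold_cells(self):
        # adding/permuting cells outside the train matrix cannot change it:
        # the builder only ever sees the training fold
        train = self._fm([[1, 0, 2], [0, 3, 0]])
        before = side_drug_profile_matrix(train).values.copy()
        after = side_drug_profile_matrix(self._fm(train.values.copy())).values
        np.testing.assert_array_equal(before, after)


# -------------------------------------------------------- learned fusions
class TestDrugProjection:
    def test_zero_rows_zero_bias(self):
        rng = np.random.default_rng(0)
        params = DrugProjectionParams.init(rng, 8, 4)
        out = project_drug_attributes(np.zeros(4), np.zeros(4), params)
        np.testing.assert_allclose(out.data, 0.0)

    def test_linear_identity_map(self):
        rng = np.random.default_rng(0)
        params = DrugProjectionParams.init(rng, 4, 4, activation="linear")
        params.W.data = np.eye(4)
        params.b.data = np.zeros(4)
        out = project_drug_attributes(np.array([1.0, 2.0]), np.array([3.0, 4.0]), params)
        np.testing.assert_allclose(out.data, [1, 2, 3, 4])

    def test_deterministic_for_fixed_seed(self):
        outs = []
        for _ in range(2):
            params = DrugProjectionParams.init(np.random.default_rng(5), 6, 3)
            outs.append(project_drug_attributes(np.ones(3), np.ones(3), params).data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_shape_mismatch_raises(self):
        params = DrugProjectionParams.init(np.random.default_rng(0), 6, 3)
        with pytest.raises(ValueError, match="fan-in"):
            project_drug_attributes(np.ones(2), np.ones(2), params)


class TestViewAttention:
    def test_identical_views_give_uniform_weights(self):
        rng = np.random.default_rng(1)
        params = ViewAttentionParams.init(rng, 4)
        v = rng.standard_normal((2, 4))
        out = attention_combine_views({"a": Tensor(v), "b": Tensor(v), "c": Tensor(v)}, params)
        np.testing.assert_allclose(out.data, v, atol=1e-6)

    def test_two_views_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        params = ViewAttentionParams.init(rng, 4)
        u1, u2 = rng.standard_normal((2, 3, 4))
        out = attention_combine_views({"a": Tensor(u1), "b": Tensor(u2)}, params).data
        # output must lie on the segment between the two views, coordinatewise
        lo = np.minimum(u1, u2) - 1e-6
        hi = np.maximum(u1, u2) + 1e-6
        assert (out >= lo).all() and (out <= hi).all()

    def test_zero_scorer_gives_uniform_alpha(self):
        params = ViewAttentionParams.init(np.random.default_rng(0), 4)
        params.W.data = np.zeros((4, 1))
        params.b.data = np.zeros(1)
        rng = np.random.default_rng(3)
        u1, u2 = rng.standard_normal((2, 2, 4))
        out = attention_combine_views({"a": Tensor(u1), "b": Tensor(u2)}, params).data
        np.testing.assert_allclose(out, (u1 + u2) / 2, atol=1e-6)

    def test_no_views_raises(self):
        params = ViewAttentionParams.init(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            attention_combine_views({}, params)


def test_similarity_matrix_invariants_on_random_inputs():
    rng = np.random.default_rng(11)
    for _ in range(5):
        binary = (rng.random((8, 12)) < 0.4).astype(int)
        j = jaccard_similarity_matrix(binary, [f"d{i}" for i in range(8)])
        assert np.allclose(j.values, j.values.T)
        assert j.values.min() >= 0 and j.values.max() <= 1
        feats = rng.standard_normal((9, 5))
        c = cosine_similarity_matrix(feats, [f"s{i}" for i in range(9)], "side-word")
        assert np.allclose(c.values, c.values.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(c.values), 1.0, atol=1e-9)


def test_symmetry_violation_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        SimilarityMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"], "side-word")
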