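import io
import itertools
import math
from math import factorial

import networkx as nx
import numpy as np
import pytest

from mtbn import (
    DagStructure,
    StructureError,
    add_demographic_level,
    condition_node,
    demographic_node,
    integrate_orderings,
    k2_family_score,
    k2_search,
    learn_structure,
    mwst_slice,
    pairwise_mutual_information,
    random_mtbn,
    read_edge_list,
    sample_cohort,
    structure_similarity,
    to_dot,
    va_like,
    write_edge_list,
)
from conftest import build_cohort


def mi_oracle(x, y):
    """Direct 2x2 joint tabulation, independent of the implementation."""
    n = len(x)
    total = 0.0
    for a in (0, 1):
        for b in (0, 1):
            pxy = np.mean((x == a) & (y == b))
            px, py = np.mean(x == a), np.mean(y == b)
            if pxy > 0:
                total += pxy * math.log(pxy / (px * py))
    return total


class TestMutualInformation:
    def test_perfectly_coupled_pair_gives_ln2(self, two_cond_cohort):
        mi = pairwise_mutual_information(two_cond_cohort, 0)
        assert mi[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_exactly_factorizing_counts_give_zero(self):
        # one patient per (x, y) combination: counts factorize exactly
        panel = np.array([[[0, 0]], [[0, 1]], [[1, 0]], [[1, 1]]])
        cohort = build_cohort(panel, ("X", "Y"))
        mi = pairwise_mutual_information(cohort, 0)
        assert mi[0, 1] == 0.0

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            panel = rng.integers(0, 2, (60, 1, 4))
            cohort = build_cohort(panel, ("A", "B", "C", "D"))
            mi = pairwise_mutual_information(cohort, 0)
            for i, j in itertools.combinations(range(4), 2):
                expected = mi_oracle(panel[:, 0, i], panel[:, 0, j])
                assert mi[i, j] == pytest.approx(expected, abs=1e-12)
                assert mi[j, i] == mi[i, j]
            assert (mi >= 0).all() and (np.diag(mi) == 0).all()


class TestMwst:
    def test_two_conditions(self):
        mi = np.array([[0.0, 0.3], [0.3, 0.0]])
        edges, ordering = mwst_slice(mi, ["A", "B"])
        assert edges == [("A", "B")]
        assert set(ordering) == {"A", "B"} and len(ordering) == 2

    def test_tree_weight_is_maximal_over_all_spanning_trees(self):
        rng = np.random.default_rng(7)
        names = ["A", "B", "C", "D", "E"]
        for _ in range(5):
            mi = rng.random((5, 5))
            mi = np.triu(mi, 1)
            mi = mi + mi.T
            edges, _ = mwst_slice(mi, names)
            weight = sum(mi[names.index(u), names.index(v)] for u, v in edges)
            best = -np.inf  # enumerate all 5^3 labelled trees via Pruefer sequences
            for seq in itertools.product(range(5), repeat=3):
                tree = nx.from_prufer_sequence(list(seq))
                w = sum(mi[u, v] for u, v in tree.edges)
                best = max(best, w)
            assert weight == pytest.approx(best, abs=1e-12)

    def test_dominant_chain_is_recovered_with_bfs_order(self):
        names = ["A", "B", "C", "D"]
        mi = np.full((4, 4), 0.01)
        np.fill_diagonal(mi, 0.0)
        for i in range(3):  # chain A-B-C-D with strong, decaying weights
            mi[i, i + 1] = mi[i + 1, i] = 1.0 - 0.1 * i
        edges, ordering = mwst_slice(mi, names)
        assert sorted(edges) == [("A", "B"), ("B", "C"), ("C", "D")]
        assert ordering in (["B", "A", "C", "D"], ["B", "C", "A", "D"])


class TestOrderingIntegration:
    def test_concatenates_by_slice(self):
        order = integrate_orderings([["A", "B"], ["B", "A"]])
        assert [str(n) for n in order] == ["A_y1", "B_y1", "B_y2", "A_y2"]

    def test_single_slice_identity(self):
        order = integrate_orderings([["C", "A", "B"]])
        assert [n.name for n in order] == ["C", "A", "B"]
        assert all(n.slice == 0 for n in order)

    def test_slice_monotonicity_for_random_inputs(self):
        rng = np.random.default_rng(3)
        names = ["A", "B", "C"]
        orderings = [list(rng.permutation(names)) for _ in range(4)]
        order = integrate_orderings(orderings)
        slices = [n.slice for n in order]
        assert slices == sorted(slices)

    def test_mismatched_name_sets_rejected(self):
        with pytest.raises(StructureError):
            integrate_orderings([["A", "B"], ["A", "C"]])


def ch_score_oracle(child, parent_configs, r=2):
    """Cooper-Herskovits score by direct factorial evaluation."""
    total = 1.0
    for j in set(parent_configs):
        sub = [c for c, p in zip(child, parent_configs) if p == j]
        nj = len(sub)
        num = factorial(r - 1)
        for k in range(r):
            num *= factorial(sum(1 for v in sub if v == k))
        total *= num / factorial(nj + r - 1)
    return math.log(total)


class TestK2Score:
    def test_three_observations_no_parents(self):
        score = k2_family_score(np.array([1, 1, 0]), np.zeros(3, dtype=int), 2)
        assert score == pytest.approx(math.log(1 / 12), abs=1e-12)

    def test_constant_child_two_observations(self):
        score = k2_family_score(np.array([0, 0]), np.zeros(2, dtype=int), 2)
        assert score == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_duplicating_data_strictly_decreases_score(self):
        child = np.array([1, 0, 1, 1])
        config = np.array([0, 0, 1, 1])
        once = k2_family_score(child, config, 2, 2)
        twice = k2_family_score(np.tile(child, 2), np.tile(config, 2), 2, 2)
        assert twice < once
        assert twice == pytest.approx(
            ch_score_oracle(np.tile(child, 2), np.tile(config, 2)), abs=1e-10
        )

    def test_matches_factorial_oracle_on_random_small_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(1, 11)
            child = rng.integers(0, 2, n)
            config = rng.integers(0, 3, n)
            got = k2_family_score(child, config, 2, 3)
            assert got == pytest.approx(ch_score_oracle(child, config), abs=1e-10)

    def test_empty_child_rejected(self):
        with pytest.raises(ValueError):
            k2_family_score(np.array([]), np.array([]), 2)


class TestK2Search:
    def test_single_node_has_no_parents(self):
        cohort = build_cohort(np.array([[[1]], [[0]], [[1]]]), ("A",))
        dag = k2_search([condition_node("A", 0)], cohort)
        assert dag.edges == set()

    def test_recovers_strong_pairwise_dependence(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 5000)
        b = np.where(rng.random(5000) < np.where(a == 1, 0.9, 0.1), 1, 0)
        cohort = build_cohort(np.stack([a, b], axis=1)[:, None, :], ("A", "B"))
        na, nb = condition_node("A", 0), condition_node("B", 0)
        dag = k2_search([na, nb], cohort)
        assert dag.edges == {(na, nb)}

    def test_greedy_family_scores_bounded_by_exhaustive_best(self):
        rng = np.random.default_rng(17)
        names = ("A", "B", "C", "D")
        panel = rng.integers(0, 2, (300, 1, 4))
        panel[:, 0, 3] = panel[:, 0, 0] ^ (rng.random(300) < 0.2)
        cohort = build_cohort(panel, names)
        ordering = [condition_node(c, 0) for c in names]
        dag = k2_search(ordering, cohort, max_parents=3)
        values = {c: panel[:, 0, i] for i, c in enumerate(names)}
        for i, node in enumerate(ordering):
            got_parents = dag.parents(node)
            got = ch_score_oracle(
                values[node.name],
                _joint_config([values[p.name] for p in got_parents], 300),
            )
            best = max(
                ch_score_oracle(
                    values[node.name],
                    _joint_config([values[p.name] for p in subset], 300),
                )
                for size in range(0, min(3, i) + 1)
                for subset in itertools.combinations(ordering[:i], size)
            )
            assert got <= best + 1e-9


def _joint_config(columns, n):
    if not columns:
        return [0] * n
    ids = np.zeros(n, dtype=int)
    for col in columns:
        ids = ids * 2 + col
    return ids.tolist()


@pytest.fixture(scope="module")
def cohort():
    net = random_mtbn(va_like(seed=2))
    return sample_cohort(net, 3000, seed=3)


class TestLearnStructure:

    def test_supervised_returns_expert_dag_unchanged(self, cohort):
        a = condition_node("TBI", 0)
        b = condition_node("TBI", 1)
        expert = DagStructure(
            nodes=[condition_node(c, t) for c in cohort.condition_names for t in range(5)],
            edges=[(a, b)],
        )
        out = learn_structure(cohort, "supervised", expert_dag=expert)
        assert out == expert and out is not expert

    def test_semi_supervised_with_unsupervised_ordering_matches(self, cohort):
        from mtbn.structure import integrate_orderings, mwst_slice, pairwise_mutual_information

        per_slice = []
        for t in range(cohort.n_years):
            _, ordering = mwst_slice(
                pairwise_mutual_information(cohort, t), cohort.condition_names
            )
            per_slice.append(ordering)
        ordering = integrate_orderings(per_slice)
        assert learn_structure(cohort, "semi_supervised", expert_ordering=ordering) == (
            learn_structure(cohort, "unsupervised")
        )

    def test_unsupervised_is_deterministic(self, cohort):
        assert learn_structure(cohort) == learn_structure(cohort)

    def test_learned_dag_satisfies_all_invariants(self, cohort):
        dag = learn_structure(cohort)
        dag.validate(window=1)  # raises on violation
        for u, v in dag.edges:
            assert v.slice - u.slice in (0, 1)

    def test_invalid_expert_input_rejected(self, cohort):
        a, b = condition_node("TBI", 1), condition_node("PTSD", 0)
        bad = DagStructure(nodes=[a, b], edges=[(a, b)])  # backwards in time
        with pytest.raises(StructureError):
            learn_structure(cohort, "supervised", expert_dag=bad)

    def test_recall_improves_with_sample_size_on_average(self):
        sizes = (1000, 5000, 20000)
        recalls = np.zeros(len(sizes))
        replicates = (1, 2, 3)
        for s in replicates:
            truth = random_mtbn(va_like(seed=s))
            true_edges = {
                (u, v)
                for u, v in truth.structure.edges
                if u.kind == "condition" and v.kind == "condition"
            }
            for i, n in enumerate(sizes):
                cohort = sample_cohort(truth, n, seed=100 + s)
                learned = learn_structure(cohort)
                recalls[i] += len(true_edges & learned.edges) / len(true_edges)
        recalls /= len(replicates)
        drops = np.maximum(recalls[:-1] - recalls[1:], 0)
        assert np.count_nonzero(drops) <= 1 and drops.max() <= 0.02


class TestDemographicLevel:
    schema = {"gender": ("M", "F"), "age_group": ("young", "old")}

    def make_dag(self):
        nodes = [condition_node(c, t) for c in ("A", "B") for t in range(2)]
        return DagStructure(nodes=nodes)

    def test_adds_one_edge_per_pair(self):
        out = add_demographic_level(self.make_dag(), self.schema)
        assert len(out.edges) == 8
        assert len(out.demographic_nodes) == 2

    def test_demographic_nodes_have_no_parents(self):
        out = add_demographic_level(self.make_dag(), self.schema)
        for d in out.demographic_nodes:
            assert out.parents(d) == ()
        out.validate()

    def test_double_application_rejected(self):
        out = add_demographic_level(self.make_dag(), self.schema)
        with pytest.raises(StructureError):
            add_demographic_level(out, self.schema)

    def test_name_collision_rejected(self):
        with pytest.raises(StructureError):
            add_demographic_level(self.make_dag(), {"A": ("x", "y")})


class TestStructureSimilarity:
    nodes = [condition_node(c, 0) for c in ("A", "B", "C")]

    def dag(self, edges):
        return DagStructure(nodes=self.nodes, edges=edges)

    def test_identical_dags(self):
        a = self.dag([(self.nodes[0], self.nodes[1])])
        cosine, pearson = structure_similarity(a, a)
        assert cosine == pytest.approx(100.0)
        assert pearson == pytest.approx(100.0)

    def test_edge_disjoint_dags_have_zero_cosine(self):
        a = self.dag([(self.nodes[0], self.nodes[1])])
        b = self.dag([(self.nodes[1], self.nodes[2])])
        cosine, _ = structure_similarity(a, b)
        assert cosine == 0.0

    def test_half_overlapping_edge_sets(self):
        # adjacency vectors [1,1,0,...] vs [1,0,...,1,...]: dot 1, norms sqrt(2)
        a = self.dag([(self.nodes[0], self.nodes[1]), (self.nodes[0], self.nodes[2])])
        b = self.dag([(self.nodes[0], self.nodes[1]), (self.nodes[1], self.nodes[2])])
        cosine, _ = structure_similarity(a, b)
        assert cosine == pytest.approx(50.0)

    def test_different_node_sets_rejected(self):
        b = DagStructure(nodes=self.nodes[:2])
        with pytest.raises(StructureError):
            structure_similarity(self.dag([]), b)


class TestGraphIO:
    def test_edge_list_round_trip(self):
        net = random_mtbn(va_like(seed=4))
        dag = net.structure
        buf = io.StringIO()
        write_edge_list(dag, buf)
        buf.seek(0)
        back = read_edge_list(
            buf, ("TBI", "PTSD", "BaPa", "SuAb", "Depr"),
            tuple(net.demographic_schema), nodes=dag.nodes,
        )
        assert back == dag

    def test_dot_export_mentions_every_edge(self):
        a, b = condition_node("A", 0), condition_node("A", 1)
        dag = DagStructure(nodes=[a, b, demographic_node("gender")],
                           edges=[(a, b)])
        dot = to_dot(dag)
        assert '"A_y1" -> "A_y2";' in dot
        assert '"gender" [shape=box];' in dot
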