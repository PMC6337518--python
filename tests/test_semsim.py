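import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from winmda.semsim import build_dag, contributions, semantic_similarity_matrix
from winmda.simulate import generate_fixture
from winmda.types import DiseaseDAG, OntologyTable, UNDEFINED


# ---------------------------------------------------------------------------
# brute-force oracle: dh(d) = beta(d) * sum over directed paths d -> focus
# of alpha ** path_length
# ---------------------------------------------------------------------------

def _brute_force_contribution(dag: DiseaseDAG, alpha: float):
    children = {t: [] for t in dag.nodes}
    for p, c in dag.edges:
        children[p].append(c)

    def paths(term):
        if term == dag.focus:
            yield 0
            return
        for c in children[term]:
            for length in paths(c):
                yield length + 1

    dh = {}
    for t in dag.nodes:
        if t == dag.focus:
            dh[t] = 1.0
        else:
            dh[t] = dag.beta[t] * sum(alpha ** L for L in paths(t))
    return dh, sum(dh.values())


def _random_dag(rng) -> DiseaseDAG:
    n = int(rng.integers(2, 9))
    edges = set()
    for i in range(1, n):
        k = int(rng.integers(1, i + 1))
        for c in rng.choice(i, size=k, replace=False):
            edges.add((f"n{i}", f"n{int(c)}"))  # more general -> more specific
    nodes = {f"n{i}" for i in range(n)}
    beta = {f"n{i}": int(rng.integers(1, 4)) for i in range(n)}
    return DiseaseDAG(focus="n0", nodes=nodes, edges=edges, beta=beta)


class TestBuildDag:
    def test_brain_neoplasms_has_eight_nodes(self, brain_ontology):
        dag = build_dag(brain_ontology, "brain neoplasms")
        assert len(dag.nodes) == 8
        assert dag.focus == "brain neoplasms"
        # the code-multiplicity weights the walkthrough relies on
        assert dag.beta["central nervous system neoplasms"] == 2
        assert dag.beta["nervous system neoplasms"] == 2
        assert dag.beta["brain diseases"] == 1

    def test_root_only_term(self):
        ont = OntologyTable({"root disease": frozenset({"C01"})})
        dag = build_dag(ont, "root disease")
        assert dag.nodes == {"root disease"} and not dag.edges

    def test_three_node_chain(self):
        ont = OntologyTable({
            "a": frozenset({"A"}),
            "b": frozenset({"A.B"}),
            "c": frozenset({"A.B.C"}),
        })
        dag = build_dag(ont, "c")
        assert dag.nodes == {"a", "b", "c"}
        assert dag.edges == {("a", "b"), ("b", "c")}

    def test_absent_disease_errors(self, brain_ontology):
        with pytest.raises(KeyError):
            build_dag(brain_ontology, "no such disease")

    def test_orphan_code_errors(self):
        ont = OntologyTable({"child": frozenset({"A.B.C"})})
        with pytest.raises(ValueError, match="orphan"):
            build_dag(ont, "child")


class TestContributions:
    def test_walkthrough_contribution_and_total(self, brain_ontology):
        dag = build_dag(brain_ontology, "brain neoplasms")
        table = contributions(dag, alpha=0.5)
        # two codes, one hierarchy level up: 2 * alpha * 1
        assert table.dh["central nervous system neoplasms"] == pytest.approx(1.0)
        assert table.ts == pytest.approx(3.6875)

    def test_chain_total(self):
        ont = OntologyTable({
            "a": frozenset({"A"}),
            "b": frozenset({"A.B"}),
            "c": frozenset({"A.B.C"}),
        })
        table = contributions(build_dag(ont, "c"), alpha=0.5)
        assert table.ts == pytest.approx(1.75)

    def test_focus_contribution_is_one(self, brain_ontology):
        table = contributions(build_dag(brain_ontology, "brain neoplasms"), 0.5)
        assert table.dh["brain neoplasms"] == 1.0
        assert all(v > 0 for v in table.dh.values())

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            dag = _random_dag(rng)
            alpha = float(rng.uniform(0.1, 0.9))
            dh_bf, ts_bf = _brute_force_contribution(dag, alpha)
            table = contributions(dag, alpha)
            assert table.ts == pytest.approx(ts_bf)
            for t in dag.nodes:
                assert table.dh[t] == pytest.approx(dh_bf[t])

    def test_invalid_alpha(self, brain_ontology):
        dag = build_dag(brain_ontology, "brain neoplasms")
        with pytest.raises(ValueError):
            contributions(dag, alpha=1.0)


class TestSemanticSimilarityMatrix:
    def test_self_similarity_is_one(self, brain_ontology):
        sdd = semantic_similarity_matrix(
            brain_ontology, ["brain neoplasms", "brain diseases"], 0.5
        )
        assert np.allclose(np.diag(sdd.values), 1.0)

    def test_uncovered_disease_gets_sentinel(self, brain_ontology):
        sdd = semantic_similarity_matrix(
            brain_ontology, ["brain neoplasms", "not annotated"], 0.5
        )
        assert sdd.values[1, 0] == UNDEFINED
        assert sdd.values[0, 1] == UNDEFINED
        assert sdd.values[1, 1] == UNDEFINED
        assert sdd.values[0, 0] == 1.0

    def test_two_chains_sharing_root(self):
        # each disease: 2-node chain to the shared root; TS = 1.5 each;
        # shared contribution 0.5 + 0.5 -> SDD = 1/3
        ont = OntologyTable({
            "a": frozenset({"R"}),
            "d1": frozenset({"R.1"}),
            "d2": frozenset({"R.2"}),
        })
        sdd = semantic_similarity_matrix(ont, ["d1", "d2"], 0.5)
        assert sdd.values[0, 1] == pytest.approx(1.0 / 3.0)

    def test_added_shared_ancestor_increases_similarity(self):
        shallow = OntologyTable({
            "a": frozenset({"R"}),
            "d1": frozenset({"R.1"}),
            "d2": frozenset({"R.2"}),
        })
        deep = OntologyTable({
            "a": frozenset({"R"}),
            "b": frozenset({"R.3"}),
            "d1": frozenset({"R.3.1"}),
            "d2": frozenset({"R.3.2"}),
        })
        s_shallow = semantic_similarity_matrix(shallow, ["d1", "d2"], 0.5)
        s_deep = semantic_similarity_matrix(deep, ["d1", "d2"], 0.5)
        assert s_deep.values[0, 1] > s_shallow.values[0, 1]

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_range_on_random_ontologies(self, seed):
        ont, assoc = generate_fixture(12, 6, 2, 0.5, 0.0, seed=seed)
        diseases = sorted({d for d, _ in assoc.records}) + ["uncovered term"]
        sdd = semantic_similarity_matrix(ont, diseases, 0.5)
        assert np.array_equal(sdd.values, sdd.values.T)
        defined = sdd.values[sdd.values != UNDEFINED]
        assert ((defined >= 0) & (defined <= 1)).all()
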