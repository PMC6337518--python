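import itertools

import numpy as np
import pytest

from winmda.network import (
    assemble,
    disease_mirna_weights,
    intra_weights,
    most_related,
    shortest_paths,
)
from winmda.types import AssocMatrix, MostRelatedSet, SimMatrix, WeightedGraph


def _sim(values, prefix="n"):
    values = np.asarray(values, dtype=float)
    return SimMatrix([f"{prefix}{i}" for i in range(values.shape[0])], values)


def _assoc(dmm):
    dmm = np.asarray(dmm, dtype=np.int8)
    D, M = dmm.shape
    return AssocMatrix([f"d{i}" for i in range(D)], [f"m{j}" for j in range(M)], dmm)


# ---------------------------------------------------------------------------
# brute-force shortest-path oracle: exhaustive simple-path enumeration
# ---------------------------------------------------------------------------

def _brute_force_apsp(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)
    adj = [
        [v for v in range(n) if weights[u, v] > 0 and v != u] for u in range(n)
    ]

    def dfs(u, target, dist, visited):
        nonlocal best
        if dist >= best[visited[0], target]:
            return
        if u == target:
            best[visited[0], target] = dist
            return
        for v in adj[u]:
            if v not in visited:
                dfs(v, target, dist + weights[u, v], visited + [v])

    for s, t in itertools.permutations(range(n), 2):
        dfs(s, t, 0.0, [s])
    return best


class TestMostRelated:
    def test_unique_argmax(self):
        fmm = _sim([[1.0, 0.9, 0.3], [0.9, 1.0, 0.2], [0.3, 0.2, 1.0]])
        mrm = most_related(fmm)
        assert mrm.mrm[0] == {1}
        assert mrm.mrm[2] == {0}

    def test_ties_retained_as_set(self):
        fmm = _sim([[1.0, 0.9, 0.9], [0.9, 1.0, 0.2], [0.9, 0.2, 1.0]])
        assert most_related(fmm).mrm[0] == {1, 2}

    def test_two_mirnas_mutual(self):
        fmm = _sim([[1.0, 0.4], [0.4, 1.0]])
        mrm = most_related(fmm)
        assert mrm.mrm[0] == {1} and mrm.mrm[1] == {0}

    def test_single_mirna_rejected(self):
        with pytest.raises(ValueError):
            most_related(_sim([[1.0]]))


class TestDiseaseMirnaWeights:
    def test_known_pair_weight_is_inverse_e(self):
        assoc = _assoc([[1, 0], [0, 1]])
        smm = _sim([[1.0, 0.5], [0.5, 1.0]], prefix="m")
        dmw = disease_mirna_weights(assoc, smm, most_related(smm))
        assert dmw[0, 0] == pytest.approx(1 / np.e)
        assert dmw[1, 1] == pytest.approx(1 / np.e)

    def test_inferred_edge_via_most_related(self):
        # m0 known to d0; m1's most related miRNA is m0 with SMM = 0.8
        assoc = _assoc([[1, 0]])
        smm = _sim([[1.0, 0.8], [0.8, 1.0]], prefix="m")
        mrm = MostRelatedSet({0: {1}, 1: {0}})
        dmw = disease_mirna_weights(assoc, smm, mrm)
        assert dmw[0, 1] == pytest.approx(np.exp(-0.8))

    def test_no_edge_when_most_related_unknown_to_disease(self):
        # d1 knows neither m1 nor m1's most-related miRNA m0
        assoc = _assoc([[1, 0], [0, 0]])
        smm = _sim([[1.0, 0.8], [0.8, 1.0]], prefix="m")
        dmw = disease_mirna_weights(assoc, smm, most_related(smm))
        assert dmw[1, 0] == 0.0 and dmw[1, 1] == 0.0

    def test_tie_takes_max_over_eligible(self):
        # m2's most-related set ties {m0, m1}; only m1 is known to d0
        assoc = _assoc([[0, 1, 0]])
        smm = _sim(
            [[1.0, 0.2, 0.9], [0.2, 1.0, 0.9], [0.9, 0.9, 1.0]], prefix="m"
        )
        dmw = disease_mirna_weights(assoc, smm, most_related(smm))
        assert dmw[0, 2] == pytest.approx(np.exp(-0.9))


class TestIntraWeightsAndAssemble:
    def test_forced_values_and_antitonicity(self):
        fdd = _sim([[1.0, 0.0], [0.0, 1.0]])
        fmm = _sim([[1.0, 0.3], [0.3, 1.0]], prefix="m")
        dw, mw = intra_weights(fdd, fmm)
        assert dw[0, 0] == pytest.approx(1 / np.e)  # similarity 1
        assert dw[0, 1] == pytest.approx(1.0)       # similarity 0
        lo, hi = np.exp(-0.2), np.exp(-0.8)
        assert hi < lo  # higher similarity -> smaller weight

    def test_block_placement_2_plus_2(self):
        dw = np.array([[0.1, 0.2], [0.2, 0.1]])
        mw = np.array([[0.3, 0.4], [0.4, 0.3]])
        dmw = np.array([[0.5, 0.6], [0.7, 0.8]])
        g = assemble(dw, mw, dmw)
        assert g.gfw.shape == (4, 4)
        assert np.array_equal(g.gfw[:2, :2], dw)
        assert np.array_equal(g.gfw[2:, 2:], mw)
        assert np.array_equal(g.gfw[:2, 2:], dmw)
        assert np.array_equal(g.gfw[2:, :2], dmw.T)
        assert np.array_equal(g.gfw, g.gfw.T)

    def test_minimal_1_plus_1(self):
        g = assemble(np.array([[0.1]]), np.array([[0.2]]), np.array([[0.9]]))
        assert g.gfw.shape == (2, 2) and g.gfw[0, 1] == 0.9

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            assemble(np.eye(2), np.eye(2), np.ones((3, 2)))


class TestShortestPaths:
    def test_two_hop_beats_direct_edge(self):
        gfw = np.array([
            [0.0, 0.9, 0.4],
            [0.9, 0.0, 0.4],
            [0.4, 0.4, 0.0],
        ])
        dist = shortest_paths(WeightedGraph(gfw, 2, 1))
        assert dist.spm[0, 1] == pytest.approx(0.8)

    def test_disconnected_pair_is_inf(self):
        gfw = np.zeros((3, 3))
        gfw[0, 1] = gfw[1, 0] = 0.5
        dist = shortest_paths(WeightedGraph(gfw, 2, 1))
        assert np.isinf(dist.spm[0, 2])
        assert dist.spm[0, 0] == 0.0

    def test_negative_weight_rejected(self):
        gfw = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(ValueError):
            shortest_paths(WeightedGraph(gfw, 1, 1))

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            p = float(rng.uniform(0.2, 0.6))
            w = np.triu(rng.uniform(0.05, 1.0, (n, n)), k=1)
            w[np.triu(rng.random((n, n)), k=1) >= p] = 0.0
            w = w + w.T
            dist = shortest_paths(WeightedGraph(w, n, 0))
            assert np.allclose(dist.spm, _brute_force_apsp(w))

    def test_metric_invariants(self, planted):
        from winmda import WINMDA

        ont, assoc = planted
        res = WINMDA(assoc, ont).fit()
        spm, dd = res.dist.spm, res.dist.dd
        assert np.allclose(spm, spm.T)
        assert (spm <= dd + 1e-12).all()
        assert np.allclose(np.diag(spm), 0.0)
        # triangle inequality via one min-plus product step
        relaxed = np.min(spm[:, :, None] + spm[None, :, :], axis=1)
        assert np.allclose(relaxed, spm)
        # every known association has a direct edge of weight 1/e
        a = res.model.assoc
        ij = np.argwhere(a.dmm == 1)
        for i, j in ij:
            assert spm[i, a.n_diseases + j] <= 1 / np.e + 1e-12
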