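"""Final association scoring from shortest paths and T nearest neighbors.

For a candidate pair (d_i, m_j) the score combines the direct shortest-path
distance with the average distance to the pair's T most similar neighbors:

    SDM(i, j) = sum over the T miRNAs most similar to m_j of SPM(d_i, .)
    SMD(i, j) = sum over the T diseases most similar to d_i of SPM(m_j, .)
    FPR(i, j) = w * (SDM + SMD) / (2 T) + (1 - w) * SPM(d_i, m_j)

with defaults T = 16 and w = 0.6.  Because distances shrink with similarity,
*smaller* scores indicate stronger predicted associations; candidate
rankings are therefore ascending by default (a descending option is exposed
for auditability).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .types import (
    AssocMatrix,
    DistanceMatrix,
    NeighborSets,
    ScoreMatrix,
    SimMatrix,
)


def _top_t(sim: np.ndarray, T: int) -> Dict[int, List[int]]:
    n = sim.shape[0]
    out: Dict[int, List[int]] = {}
    for i in range(n):
        others = np.delete(np.arange(n), i)
        vals = sim[i, others]
        # descending similarity, ties broken by lower index
        order = np.lexsort((others, -vals))
        out[i] = [int(others[k]) for k in order[: min(T, n - 1)]]
    return out


def neighbor_sets(fdd: SimMatrix, fmm: SimMatrix, T: int) -> NeighborSets:
    """Top-T most similar other nodes per disease and per miRNA.

    Lists are clamped to the population size minus one; ties at the cut are
    resolved toward the lower index.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    return NeighborSets(dk=_top_t(fdd.values, T), mk=_top_t(fmm.values, T), T=T)


def aggregate_scores(
    spm_or_dist: DistanceMatrix | np.ndarray,
    neighbors: NeighborSets,
    n_diseases: int,
    n_mirnas: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Neighbor-aggregated path sums SDM and SMD, both shaped (D, M).

    miRNA node k sits at matrix index ``D + k`` of the shortest-path matrix.
    """
    spm = spm_or_dist.spm if isinstance(spm_or_dist, DistanceMatrix) else spm_or_dist
    D, M = n_diseases, n_mirnas
    sdm = np.zeros((D, M))
    smd = np.zeros((D, M))
    for j in range(M):
        cols = [D + x for x in neighbors.mk[j]]
        sdm[:, j] = spm[:D, cols].sum(axis=1)
    for i in range(D):
        cols = [x for x in neighbors.dk[i]]
        smd[i, :] = spm[D:, cols].sum(axis=1)
    return sdm, smd


def final_scores(
    spm_or_dist: DistanceMatrix | np.ndarray,
    sdm: np.ndarray,
    smd: np.ndarray,
    diseases: List[str],
    mirnas: List[str],
    T: int,
    w: float,
) -> ScoreMatrix:
    """Convex combination of neighbor aggregates and the direct path."""
    if not 0 <= w <= 1:
        raise ValueError("w must be in [0, 1]")
    spm = spm_or_dist.spm if isinstance(spm_or_dist, DistanceMatrix) else spm_or_dist
    D, M = len(diseases), len(mirnas)
    direct = spm[:D, D:]
    with np.errstate(invalid="ignore"):
        fpr = w * (sdm + smd) / (2.0 * T) + (1.0 - w) * direct
    return ScoreMatrix(diseases, mirnas, fpr, T=T, w=w)


def rank_candidates(
    scores: ScoreMatrix,
    assoc: AssocMatrix,
    disease: str,
    rank_order: str = "asc",
) -> List[Tuple[str, float]]:
    """Rank the unknown miRNAs of one disease by prediction score.

    Only miRNAs without a known association to the disease are listed.  The
    default ascending order follows the distance semantics of the scores;
    infinite (unreachable) scores go last either way.
    """
    if rank_order not in ("asc", "desc"):
        raise ValueError("rank_order must be 'asc' or 'desc'")
    i = assoc.disease_index(disease)
    cand = np.flatnonzero(assoc.dmm[i] == 0)
    vals = scores.fpr_score[i, cand]
    finite = np.isfinite(vals)
    key = vals if rank_order == "asc" else -vals
    key = np.where(finite, key, np.inf)
    order = np.lexsort((cand, key))
    return [(assoc.mirnas[int(cand[k])], float(vals[k])) for k in order]
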