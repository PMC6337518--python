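"""Weighted heterogeneous disease–miRNA network and shortest paths.

Edge weights are ``1/exp(similarity)``, so higher similarity means a shorter
edge and a small shortest-path distance between two nodes means a strong
predicted relationship.  The network has three kinds of edges:

* disease–disease:  ``DW = 1/exp(FDD)`` (always present),
* miRNA–miRNA:      ``MW = 1/exp(FMM)`` (always present),
* disease–miRNA:    weight ``1/e`` for every known association; for an
  unknown pair (d_i, m_j) an *inferred* edge of weight
  ``1/exp(max similarity of m_j to a most-related miRNA known to d_i)``
  exists when at least one of m_j's most-related miRNAs is itself associated
  with d_i; otherwise no edge.

Self-loops carry weight ``1/e`` in the assembled matrix but cannot affect any
shortest path (all weights are positive), so the path matrix has zero
diagonal as required of a distance.
"""

from __future__ import annotations

from typing import Dict, Set, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .types import (
    UNDEFINED,
    AssocMatrix,
    DistanceMatrix,
    MostRelatedSet,
    SimMatrix,
    WeightedGraph,
)


def most_related(fmm: SimMatrix) -> MostRelatedSet:
    """For each miRNA, the argmax set of similarity over the *other* miRNAs.

    Ties are retained as a set.  Requires at least two miRNAs.
    """
    M = fmm.n
    if M < 2:
        raise ValueError("need at least 2 miRNAs to define most-related sets")
    vals = fmm.values.copy()
    np.fill_diagonal(vals, -np.inf)
    mrm: Dict[int, Set[int]] = {}
    for j in range(M):
        row = vals[:, j]
        mrm[j] = set(np.flatnonzero(row == row.max()))
    return MostRelatedSet(mrm)


def disease_mirna_weights(
    assoc: AssocMatrix, smm: SimMatrix, mrm: MostRelatedSet
) -> np.ndarray:
    """D x M matrix of disease–miRNA edge weights.

    ``smm`` is the miRNA similarity used to weight inferred edges; the
    pipeline passes the integrated matrix (FMM) so every needed entry is
    defined.  Sentinel (-1) entries, if present, make the corresponding
    most-related miRNA ineligible rather than producing a weight > 1.
    """
    D, M = assoc.n_diseases, assoc.n_mirnas
    dmm = assoc.dmm
    weights = np.zeros((D, M), dtype=float)
    known_w = float(np.exp(-1.0))  # 1/exp(1) for every known association
    for j in range(M):
        xs = sorted(mrm.mrm[j])
        sims = smm.values[j, xs]
        eligible = sims != UNDEFINED
        known_to = dmm[:, xs] == 1  # (D, len(xs))
        usable = known_to & eligible[None, :]
        has_edge = usable.any(axis=1)
        best = np.where(usable, sims[None, :], -np.inf).max(axis=1)
        col = np.where(has_edge, np.exp(-best), 0.0)
        col[dmm[:, j] == 1] = known_w
        weights[:, j] = col
    return weights


def intra_weights(fdd: SimMatrix, fmm: SimMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Entrywise ``1/exp(similarity)`` weights within each node class."""
    return np.exp(-fdd.values), np.exp(-fmm.values)


def assemble(dw: np.ndarray, mw: np.ndarray, dmw: np.ndarray) -> WeightedGraph:
    """Lay out the (D+M)^2 weight matrix, diseases first.

    The disease–miRNA block and its transpose are placed symmetrically.
    """
    dw = np.asarray(dw, dtype=float)
    mw = np.asarray(mw, dtype=float)
    dmw = np.asarray(dmw, dtype=float)
    D = dw.shape[0]
    M = mw.shape[0]
    if dw.shape != (D, D) or mw.shape != (M, M) or dmw.shape != (D, M):
        raise ValueError("block dimensions do not conform")
    gfw = np.zeros((D + M, D + M), dtype=float)
    gfw[:D, :D] = dw
    gfw[D:, D:] = mw
    gfw[:D, D:] = dmw
    gfw[D:, :D] = dmw.T
    return WeightedGraph(gfw=gfw, n_diseases=D, n_mirnas=M)


def shortest_paths(graph: WeightedGraph) -> DistanceMatrix:
    """All-pairs shortest paths over the weighted network (Dijkstra).

    The edge-distance matrix maps absent edges (weight 0) to infinity;
    unreachable pairs keep the infinite flag in the result.
    """
    gfw = graph.gfw
    if (gfw < 0).any():
        raise ValueError("negative edge weights are not allowed")
    dd = np.where(gfw > 0, gfw, np.inf)
    spm = _csgraph_shortest_path(csr_matrix(gfw), method="D", directed=False)
    np.fill_diagonal(spm, 0.0)
    return DistanceMatrix(dd=dd, spm=spm)
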