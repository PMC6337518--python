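"""miRNA functional similarity from the diseases each miRNA is known to affect.

Two miRNAs are functionally similar when the disease groups they are
associated with are semantically similar.  The similarity of one disease to a
group is the best match in the group,

    SS(d, G) = max_{y in G} SDD(d, y),

and the functional similarity of two miRNAs averages the cross-group best
matches both ways, normalized by the combined group size:

    SMM(mi, mj) = ( sum_{d in Gj} SS(d, Gi) + sum_{d in Gi} SS(d, Gj) )
                  / (|Gi| + |Gj|)

Sentinel (-1) entries of the disease similarity matrix are *skipped* inside
the max — a disease missing from the ontology cannot drag down an otherwise
well-defined best match.  A miRNA with an empty disease group, or a pair
whose cross matches are all undefined, gets the sentinel -1.
"""

from __future__ import annotations

import warnings
from typing import List, Set

import numpy as np

from .types import UNDEFINED, AssocMatrix, SimMatrix


def disease_groups(assoc: AssocMatrix) -> List[Set[int]]:
    """Disease-index group of each miRNA (column support of the matrix)."""
    return [set(np.flatnonzero(assoc.dmm[:, j])) for j in range(assoc.n_mirnas)]


def group_similarity(d: int | str, group, sdd: SimMatrix) -> float:
    """Best semantic match between one disease and a disease group.

    ``d`` and the group members may be names or integer indices into ``sdd``.
    Sentinel entries are ignored; if every entry is sentinel the result is
    the sentinel itself.
    """
    if not group:
        raise ValueError("disease group is empty")
    di = sdd.names.index(d) if isinstance(d, str) else int(d)
    idx = [sdd.names.index(g) if isinstance(g, str) else int(g) for g in group]
    vals = sdd.values[di, idx]
    defined = vals[vals != UNDEFINED]
    if defined.size == 0:
        return UNDEFINED
    return float(defined.max())


def functional_similarity_matrix(assoc: AssocMatrix, sdd: SimMatrix) -> SimMatrix:
    """Pairwise functional similarity for every miRNA in the matrix.

    Vectorized: ``best[d, i] = max over the group of miRNA i of SDD(d, .)``
    is computed once, then every pair is an average of gathered entries.
    """
    if sdd.n != assoc.n_diseases:
        raise ValueError("SDD index does not match the association matrix")
    D, M = assoc.n_diseases, assoc.n_mirnas
    groups = disease_groups(assoc)

    vals = np.where(sdd.values == UNDEFINED, np.nan, sdd.values)
    # best[d, i]: best defined match of disease d against miRNA i's group
    best = np.full((D, M), np.nan)
    with warnings.catch_warnings():
        # all-NaN rows legitimately yield NaN (undefined best match)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for i, g in enumerate(groups):
            if g:
                best[:, i] = np.nanmax(vals[:, sorted(g)], axis=1)

    smm = np.full((M, M), UNDEFINED, dtype=float)
    for i in range(M):
        if not groups[i]:
            continue
        gi = sorted(groups[i])
        for j in range(i, M):
            if not groups[j]:
                continue
            gj = sorted(groups[j])
            cross = np.concatenate((best[gj, i], best[gi, j]))
            defined = cross[~np.isnan(cross)]
            if defined.size == 0:
                continue  # pair stays sentinel
            # undefined best-matches drop out of both numerator and count
            val = float(defined.sum()) / defined.size
            smm[i, j] = smm[j, i] = val
    return SimMatrix(list(assoc.mirnas), smm, kind="SMM")
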