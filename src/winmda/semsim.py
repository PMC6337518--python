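"""Disease semantic similarity over an ontology DAG.

Each disease term carries one or more dot-delimited tree codes.  The DAG of a
disease ``H`` consists of ``H`` plus every ancestor term reached by stripping
trailing code segments, with edges pointing from the more general term to the
more specific one.

The semantic contribution of a node ``d`` to the focus ``H`` is

    D_H(H) = 1
    D_H(d) = beta(d) * sum over directed paths d -> H of alpha ** len(path)

where ``alpha`` (default 0.5) attenuates the contribution per hierarchy level
and ``beta(d)`` is the number of tree codes the term carries — a term filed
under two hierarchy addresses counts double.  The total semantic value
``TS(H)`` is the sum of contributions over all DAG nodes, and the similarity
of two diseases is the contribution mass of their shared terms normalized by
the two totals:

    SDD(di, dj) = sum_{d in shared} (D_di(d) + D_dj(d)) / (TS(di) + TS(dj))

Diseases absent from the ontology get the sentinel value ``-1`` (undefined);
downstream they fall back to the interaction-profile kernel similarity.
"""

from __future__ import annotations

from typing import Dict, Sequence, Set, Tuple

import numpy as np

from .types import UNDEFINED, ContributionTable, DiseaseDAG, OntologyTable, SimMatrix


def _parent_code(code: str) -> str | None:
    head, _, _ = code.rpartition(".")
    return head or None


def build_dag(ontology: OntologyTable, disease: str) -> DiseaseDAG:
    """Build the ancestor DAG of one disease term.

    Nodes are the disease plus the owners of every proper prefix of each of
    its tree codes; an edge (p -> c) exists whenever some code of ``c``
    extends some code of ``p`` by exactly one segment.  A prefix that maps to
    no term in the table is an orphan and raises ``ValueError``.
    """
    if disease not in ontology:
        raise KeyError(f"disease not in ontology: {disease!r}")
    owner = ontology.code_owner()
    nodes: Set[str] = {disease}
    for code in ontology.term_codes[disease]:
        cur = _parent_code(code)
        child_code = code
        while cur is not None:
            if cur not in owner:
                raise ValueError(
                    f"orphan tree code {child_code!r}: parent prefix {cur!r} "
                    "maps to no term"
                )
            nodes.add(owner[cur])
            child_code = cur
            cur = _parent_code(cur)

    edges: Set[Tuple[str, str]] = set()
    for child in nodes:
        for code in ontology.term_codes[child]:
            parent_prefix = _parent_code(code)
            if parent_prefix is not None and parent_prefix in owner:
                parent = owner[parent_prefix]
                if parent in nodes and parent != child:
                    edges.add((parent, child))
    beta = {t: len(ontology.term_codes[t]) for t in nodes}
    return DiseaseDAG(focus=disease, nodes=nodes, edges=edges, beta=beta)


def contributions(dag: DiseaseDAG, alpha: float = 0.5) -> ContributionTable:
    """Semantic contribution of every DAG node to the focus disease.

    Evaluated as a memoized recursion ``P(focus) = 1``,
    ``P(d) = alpha * sum_{c in children(d)} P(c)``, which equals the sum of
    ``alpha ** length`` over all directed paths from ``d`` to the focus; the
    node's contribution is ``beta(d) * P(d)`` (the focus itself contributes
    exactly 1).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    children: Dict[str, list] = {t: [] for t in dag.nodes}
    for p, c in dag.edges:
        children[p].append(c)

    memo: Dict[str, float] = {}
    visiting: Set[str] = set()

    def path_weight(term: str) -> float:
        if term == dag.focus:
            return 1.0
        if term in memo:
            return memo[term]
        if term in visiting:
            raise ValueError(f"cycle detected at {term!r}")
        visiting.add(term)
        val = alpha * sum(path_weight(c) for c in children[term])
        visiting.discard(term)
        memo[term] = val
        return val

    dh = {
        t: 1.0 if t == dag.focus else dag.beta[t] * path_weight(t)
        for t in dag.nodes
    }
    return ContributionTable(dh=dh, ts=float(sum(dh.values())))


def semantic_similarity_matrix(
    ontology: OntologyTable, diseases: Sequence[str], alpha: float = 0.5
) -> SimMatrix:
    """Pairwise semantic similarity over an ordered disease list.

    Entries involving a disease not present in the ontology are set to the
    sentinel ``-1``; the diagonal is 1 for covered diseases.
    """
    if len(diseases) == 0:
        raise ValueError("disease list is empty")
    tables: Dict[int, ContributionTable] = {}
    for i, d in enumerate(diseases):
        if d in ontology:
            tables[i] = contributions(build_dag(ontology, d), alpha)

    n = len(diseases)
    sdd = np.full((n, n), UNDEFINED, dtype=float)
    covered = sorted(tables)
    for a_pos, i in enumerate(covered):
        ti = tables[i]
        sdd[i, i] = 1.0
        for j in covered[a_pos + 1:]:
            tj = tables[j]
            shared = ti.dh.keys() & tj.dh.keys()
            if shared:
                num = sum(ti.dh[d] + tj.dh[d] for d in shared)
                val = num / (ti.ts + tj.ts)
            else:
                val = 0.0
            sdd[i, j] = sdd[j, i] = val
    return SimMatrix(list(diseases), sdd, kind="SDD")
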