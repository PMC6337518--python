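"""Model / Results front-end tying the pipeline together.

:class:`WINMDA` is constructed from a known disease–miRNA association list
and (optionally) a disease ontology; :meth:`WINMDA.fit` runs the full
pipeline — semantic similarity, functional similarity, interaction-profile
kernels, integration, weighted-network assembly, all-pairs shortest paths and
neighbor-aggregated scoring — and returns a :class:`WINMDAResults` holding
every intermediate matrix, the final score matrix and ranking helpers.

Example
-------
>>> from winmda import WINMDA
>>> from winmda.simulate import generate_fixture
>>> ontology, assoc = generate_fixture(20, 20, 2, 0.6, 0.02, seed=7)
>>> res = WINMDA(assoc, ontology, T=16, w=0.6).fit()
>>> res.rank_candidates("disease_000")[:3]   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import funsim, gip, network, predict, semsim
from .io import build_assoc_matrix, read_associations, read_ontology
from .types import (
    AssociationList,
    AssocMatrix,
    DistanceMatrix,
    OntologyTable,
    ScoreMatrix,
    SimMatrix,
)


@dataclass
class NetworkState:
    """Pipeline state up to (and including) the shortest-path matrix.

    Independent of the scoring parameters T and w, so parameter sweeps can
    reuse it.
    """

    assoc: AssocMatrix
    smm: SimMatrix
    dgs: SimMatrix
    fdgs: SimMatrix
    fmgs: SimMatrix
    fdd: SimMatrix
    fmm: SimMatrix
    graph: network.WeightedGraph
    dist: DistanceMatrix


def network_pipeline(assoc: AssocMatrix, sdd: SimMatrix) -> NetworkState:
    """Run every stage from the association matrix to the shortest paths.

    Factored out because cross-validation re-runs exactly this part per fold
    (the ontology-based SDD does not depend on the association matrix and is
    cached across folds).
    """
    smm = funsim.functional_similarity_matrix(assoc, sdd)
    dgs = gip.disease_gip(assoc)
    fdgs = gip.logistic_adjust(dgs)
    fmgs = gip.mirna_gip(assoc)
    fdd = gip.integrate_disease(sdd, fdgs)
    fmm = gip.integrate_mirna(smm, fmgs)

    mrm = network.most_related(fmm)
    dmw = network.disease_mirna_weights(assoc, fmm, mrm)
    dw, mw = network.intra_weights(fdd, fmm)
    graph = network.assemble(dw, mw, dmw)
    dist = network.shortest_paths(graph)
    return NetworkState(
        assoc=assoc, smm=smm, dgs=dgs, fdgs=fdgs, fmgs=fmgs,
        fdd=fdd, fmm=fmm, graph=graph, dist=dist,
    )


def score_network(state: NetworkState, T: int, w: float) -> "PipelineState":
    """Neighbor aggregation and final scoring on a prepared network."""
    assoc = state.assoc
    neighbors = predict.neighbor_sets(state.fdd, state.fmm, T)
    sdm, smd = predict.aggregate_scores(
        state.dist, neighbors, assoc.n_diseases, assoc.n_mirnas
    )
    scores = predict.final_scores(
        state.dist, sdm, smd, assoc.diseases, assoc.mirnas, T, w
    )
    return PipelineState(
        smm=state.smm, dgs=state.dgs, fdgs=state.fdgs, fmgs=state.fmgs,
        fdd=state.fdd, fmm=state.fmm, graph=state.graph, dist=state.dist,
        sdm=sdm, smd=smd, scores=scores,
    )


def score_pipeline(
    assoc: AssocMatrix,
    sdd: SimMatrix,
    T: int,
    w: float,
) -> "PipelineState":
    """Full pipeline downstream of the disease semantic similarity."""
    return score_network(network_pipeline(assoc, sdd), T, w)


@dataclass
class PipelineState:
    """Intermediate matrices of one pipeline run."""

    smm: SimMatrix
    dgs: SimMatrix
    fdgs: SimMatrix
    fmgs: SimMatrix
    fdd: SimMatrix
    fmm: SimMatrix
    graph: network.WeightedGraph
    dist: DistanceMatrix
    sdm: np.ndarray
    smd: np.ndarray
    scores: ScoreMatrix


class WINMDA:
    """Weighted-interactive-network miRNA–disease association model.

    Parameters
    ----------
    assoc : AssociationList or AssocMatrix
        Known disease–miRNA associations.
    ontology : OntologyTable, optional
        Disease ontology used for semantic similarity.  Diseases absent from
        it (or the whole table, if omitted) fall back to the
        interaction-profile kernel similarity.
    alpha : float
        Semantic contribution attenuation per hierarchy level (default 0.5).
    T : int
        Number of most similar neighbors aggregated per node (default 16).
    w : float
        Weight of the neighbor aggregate against the direct shortest path in
        the final score (default 0.6).
    """

    def __init__(
        self,
        assoc: AssociationList | AssocMatrix,
        ontology: Optional[OntologyTable] = None,
        *,
        alpha: float = 0.5,
        T: int = 16,
        w: float = 0.6,
    ) -> None:
        if isinstance(assoc, AssociationList):
            assoc = build_assoc_matrix(assoc)
        if not isinstance(assoc, AssocMatrix):
            raise TypeError("assoc must be an AssociationList or AssocMatrix")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if T < 1:
            raise ValueError("T must be >= 1")
        if not 0 <= w <= 1:
            raise ValueError("w must be in [0, 1]")
        self.assoc = assoc
        self.ontology = ontology
        self.alpha = alpha
        self.T = T
        self.w = w
        self._sdd: Optional[SimMatrix] = None

    @classmethod
    def from_files(cls, assoc_path, ontology_path=None, **params) -> "WINMDA":
        """Build the model from an association file and optional ontology TSV."""
        assoc = read_associations(assoc_path)
        ontology = read_ontology(ontology_path) if ontology_path else None
        return cls(assoc, ontology, **params)

    @property
    def sdd(self) -> SimMatrix:
        """Disease semantic similarity (cached; does not depend on DMM)."""
        if self._sdd is None:
            if self.ontology is not None:
                self._sdd = semsim.semantic_similarity_matrix(
                    self.ontology, self.assoc.diseases, self.alpha
                )
            else:
                n = self.assoc.n_diseases
                self._sdd = SimMatrix(
                    list(self.assoc.diseases), np.full((n, n), -1.0), kind="SDD"
                )
        return self._sdd

    def fit(self) -> "WINMDAResults":
        """Run the full pipeline and return a results object."""
        state = score_pipeline(self.assoc, self.sdd, self.T, self.w)
        return WINMDAResults(self, state)


class WINMDAResults:
    """Fitted pipeline state: similarity matrices, network, and scores."""

    def __init__(self, model: WINMDA, state: PipelineState) -> None:
        self.model = model
        self.sdd = model.sdd
        self.smm = state.smm
        self.dgs = state.dgs
        self.fdgs = state.fdgs
        self.fmgs = state.fmgs
        self.fdd = state.fdd
        self.fmm = state.fmm
        self.graph = state.graph
        self.dist = state.dist
        self.sdm = state.sdm
        self.smd = state.smd
        self.scores = state.scores

    @property
    def spm(self) -> np.ndarray:
        return self.dist.spm

    def rank_candidates(
        self, disease: str, top: Optional[int] = None, rank_order: str = "asc"
    ) -> List[Tuple[str, float]]:
        """Ranked unknown miRNAs for one disease (smaller score = stronger)."""
        ranked = predict.rank_candidates(
            self.scores, self.model.assoc, disease, rank_order=rank_order
        )
        return ranked[:top] if top is not None else ranked

    def summary(self) -> str:
        """Plain-text summary of dimensions, parameters and score statistics."""
        a = self.model.assoc
        known = int(a.dmm.sum())
        covered = int((np.diag(self.sdd.values) != -1).sum())
        finite = self.scores.fpr_score[np.isfinite(self.scores.fpr_score)]
        lines = [
            "WINMDA Results",
            "=" * 46,
            f"diseases:            {a.n_diseases}",
            f"miRNAs:              {a.n_mirnas}",
            f"known associations:  {known}",
            f"ontology coverage:   {covered}/{a.n_diseases} diseases",
            f"alpha:               {self.model.alpha}",
            f"T (neighbors):       {self.model.T}",
            f"w (path weight):     {self.model.w}",
            "-" * 46,
            f"score min/median/max: {finite.min():.4f} / "
            f"{np.median(finite):.4f} / {finite.max():.4f}",
            "(smaller score = stronger predicted association)",
        ]
        return "\n".join(lines)
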