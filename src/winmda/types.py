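"""Core container types shared across the pipeline.

All square similarity matrices are carried as :class:`SimMatrix`, which pairs
the numeric array with its ordered name index and a ``kind`` tag.  Two of the
kinds (``SDD``, ``SMM``) may contain the sentinel value ``-1`` marking pairs
for which the similarity is *undefined* (e.g. a disease with no ontology
annotation); every other kind is fully defined in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

import numpy as np

#: Sentinel marking an undefined similarity entry.
UNDEFINED = -1.0


@dataclass(frozen=True)
class AssociationList:
    """Deduplicated (disease, miRNA) name pairs in first-occurrence order."""

    records: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for d, m in self.records:
            if not d or not m:
                raise ValueError("association records must have non-empty names")
            if (d, m) in seen:
                raise ValueError(f"duplicate association record: {(d, m)!r}")
            seen.add((d, m))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AssocMatrix:
    """Binary disease x miRNA association matrix with stable name indices."""

    diseases: List[str]
    mirnas: List[str]
    dmm: np.ndarray  # shape (D, M), dtype int8, values in {0, 1}

    def __post_init__(self) -> None:
        self.dmm = np.asarray(self.dmm, dtype=np.int8)
        if self.dmm.shape != (len(self.diseases), len(self.mirnas)):
            raise ValueError("dmm shape does not match index lists")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease names in index")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValueError("duplicate miRNA names in index")
        if not np.isin(self.dmm, (0, 1)).all():
            raise ValueError("dmm must be binary")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    def disease_index(self, name: str) -> int:
        try:
            return self.diseases.index(name)
        except ValueError:
            raise KeyError(f"unknown disease: {name!r}") from None

    def mirna_index(self, name: str) -> int:
        try:
            return self.mirnas.index(name)
        except ValueError:
            raise KeyError(f"unknown miRNA: {name!r}") from None


@dataclass(frozen=True)
class OntologyTable:
    """Mapping of each disease term to its set of hierarchical tree codes.

    Codes are dot-delimited positional strings (``C04.588.614``); removing the
    last segment yields the parent code.  A code with a single segment is a
    hierarchy root.
    """

    term_codes: Mapping[str, frozenset]

    def __contains__(self, term: str) -> bool:
        return term in self.term_codes

    def code_owner(self) -> Dict[str, str]:
        """Invert the table: tree code -> term carrying it."""
        owner: Dict[str, str] = {}
        for term, codes in self.term_codes.items():
            for code in codes:
                owner[code] = term
        return owner


@dataclass
class SimMatrix:
    """Square similarity matrix over an ordered name index."""

    names: List[str]
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over the index")

    @property
    def n(self) -> int:
        return len(self.names)

    def defined_mask(self) -> np.ndarray:
        return self.values != UNDEFINED


@dataclass
class DiseaseDAG:
    """Sub-hierarchy induced by one disease and all its ontology ancestors.

    Edges point from the more general term (parent) to the more specific one
    (child); the focus disease is the unique sink every node can reach.
    ``beta`` is the tree-code multiplicity of each node.
    """

    focus: str
    nodes: Set[str]
    edges: Set[Tuple[str, str]]  # (parent, child)
    beta: Dict[str, int]

    def children(self, term: str) -> Set[str]:
        return {c for p, c in self.edges if p == term}

    def parents(self, term: str) -> Set[str]:
        return {p for p, c in self.edges if c == term}


@dataclass
class ContributionTable:
    """Per-node semantic contributions and their total for one disease DAG."""

    dh: Dict[str, float]
    ts: float


@dataclass
class WeightedGraph:
    """(D+M) x (D+M) edge-weight matrix, diseases first then miRNAs."""

    gfw: np.ndarray
    n_diseases: int
    n_mirnas: int

    def __post_init__(self) -> None:
        n = self.n_diseases + self.n_mirnas
        self.gfw = np.asarray(self.gfw, dtype=float)
        if self.gfw.shape != (n, n):
            raise ValueError("gfw shape does not match D + M")


@dataclass
class DistanceMatrix:
    """Edge distances (``inf`` where no edge) and all-pairs shortest paths."""

    dd: np.ndarray
    spm: np.ndarray


@dataclass
class MostRelatedSet:
    """For each miRNA, the set of other miRNAs attaining maximal similarity."""

    mrm: Dict[int, Set[int]]


@dataclass
class NeighborSets:
    """Top-T integrated-similarity neighbors per disease and per miRNA."""

    dk: Dict[int, List[int]]
    mk: Dict[int, List[int]]
    T: int


@dataclass
class ScoreMatrix:
    """Final D x M prediction scores; *smaller* score = stronger candidate."""

    diseases: List[str]
    mirnas: List[str]
    fpr_score: np.ndarray
    T: int
    w: float


@dataclass
class RocResult:
    """ROC curve points (FPR, TPR) and the area under the curve."""

    points: List[Tuple[float, float]]
    auc: float


@dataclass
class CvReport:
    """Summary of one cross-validation experiment."""

    scheme: str
    auc_mean: float
    auc_sd: float
    n_folds: int
    k: int | None = None
    repeats: int = 1
    per_repeat_auc: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "n_folds": self.n_folds,
            "k": self.k,
            "repeats": self.repeats,
        }
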