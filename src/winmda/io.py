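"""Readers and writers for the package's plain-text formats.

Formats
-------
* Association file: TSV or CSV with columns ``disease<TAB>mirna``; lines
  starting with ``#`` are comments.  Duplicates are collapsed, keeping
  first-occurrence order.
* Ontology file: TSV with columns ``term<TAB>tree_code``; a term may appear
  on several lines, one code each.
* Matrix files: TSV with the first row holding column names and the first
  column holding row names; ``inf`` is serialized literally.

Name matching is case-insensitive (``str.casefold``) with surrounding
whitespace stripped; the first-seen original spelling is preserved for
output.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .types import AssociationList, AssocMatrix, OntologyTable

_SEP = re.compile(r"[\t,]")


def _split_line(line: str) -> List[str]:
    return [f.strip() for f in _SEP.split(line)]


def _normalize(name: str) -> str:
    return name.strip().casefold()


def read_associations(path) -> AssociationList:
    """Read a two-column disease/miRNA association file.

    Duplicate pairs (after case-normalization) are collapsed; the order of
    first occurrence is preserved.  Malformed lines raise ``ValueError``
    naming the line number.
    """
    path = Path(path)
    records: List[Tuple[str, str]] = []
    seen = set()
    canonical: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two non-empty fields, got {raw!r}"
                )
            key = (_normalize(fields[0]), _normalize(fields[1]))
            for k, orig in zip(key, fields):
                canonical.setdefault(k, orig)
            if key in seen:
                continue
            seen.add(key)
            records.append((canonical[key[0]], canonical[key[1]]))
    if not records:
        raise ValueError(f"{path}: no association records found")
    return AssociationList(tuple(records))


def write_associations(assoc: AssociationList, path) -> None:
    with open(path, "w") as fh:
        fh.write("#disease\tmirna\n")
        for d, m in assoc.records:
            fh.write(f"{d}\t{m}\n")


def build_assoc_matrix(assoc: AssociationList) -> AssocMatrix:
    """Build the binary D x M association matrix from a pair list.

    Row and column indices follow first-occurrence order in the list, which
    fixes a deterministic node ordering for the whole pipeline.
    """
    if len(assoc) == 0:
        raise ValueError("association list is empty")
    diseases: List[str] = []
    mirnas: List[str] = []
    d_idx: Dict[str, int] = {}
    m_idx: Dict[str, int] = {}
    for d, m in assoc.records:
        if d not in d_idx:
            d_idx[d] = len(diseases)
            diseases.append(d)
        if m not in m_idx:
            m_idx[m] = len(mirnas)
            mirnas.append(m)
    dmm = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    for d, m in assoc.records:
        dmm[d_idx[d], m_idx[m]] = 1
    return AssocMatrix(diseases, mirnas, dmm)


def read_ontology(path) -> OntologyTable:
    """Read a two-column ``term<TAB>tree_code`` ontology file.

    A term occurring on multiple lines aggregates all its codes (this is how
    code multiplicity beta > 1 arises).  Codes with an empty dot-segment are
    rejected.
    """
    path = Path(path)
    term_codes: Dict[str, set] = {}
    canonical: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected term and tree code, got {raw!r}"
                )
            term_raw, code = fields[0], fields[1]
            if any(not seg for seg in code.split(".")):
                raise ValueError(
                    f"{path}:{lineno}: tree code {code!r} has an empty segment"
                )
            key = _normalize(term_raw)
            canonical.setdefault(key, term_raw)
            term_codes.setdefault(canonical[key], set()).add(code)
    if not term_codes:
        raise ValueError(f"{path}: no ontology records found")
    return OntologyTable({t: frozenset(c) for t, c in term_codes.items()})


def write_ontology(ontology: OntologyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#term\ttree_code\n")
        for term in ontology.term_codes:
            for code in sorted(ontology.term_codes[term]):
                fh.write(f"{term}\t{code}\n")


def write_matrix(values: np.ndarray, rows, cols, path) -> None:
    """Write a labelled matrix as TSV; infinities serialize as ``inf``."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=rows, columns=cols)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> Tuple[np.ndarray, List[str], List[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(r) for r in df.index], [str(c) for c in df.columns]
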