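"""Synthetic fixture generation.

Emulates the two external inputs the pipeline needs — a MeSH-style disease
ontology and an HMDD-style association list — with a planted block structure
so that ranking signal exists: diseases and miRNAs are partitioned into
blocks, diseases of the same block share an ontology subtree (hence high
semantic similarity) and share their associated miRNAs.

Within a block, associations are planted *per miRNA*: each in-block miRNA is
switched on for every disease of the block with the shared-planting rate
``(assoc_density - noise) / (1 - noise)``, and independent per-pair noise at
rate ``noise`` is then added everywhere.  Consequences:

* the marginal probability of a within-block pair is ``assoc_density`` and
  of a cross-block pair is ``noise``;
* at ``noise = 0`` the row supports of same-block diseases are identical
  (a clean planted signal);
* at ``noise = assoc_density`` the shared component vanishes and the matrix
  is iid Bernoulli — a true no-signal null whose LOOCV AUC is ~0.5.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .types import AssociationList, OntologyTable


def generate_fixture(
    n_diseases: int,
    n_mirnas: int,
    n_blocks: int,
    assoc_density: float,
    noise: float,
    seed: int,
    multi_code_fraction: float = 0.3,
) -> Tuple[OntologyTable, AssociationList]:
    """Generate a seeded (ontology, association list) pair.

    Parameters
    ----------
    n_diseases, n_mirnas : int
        Sizes of the two node sets.
    n_blocks : int
        Number of planted blocks; must not exceed ``min(n_diseases, n_mirnas)``.
    assoc_density : float in (0, 1]
        Probability that an in-block miRNA is associated with its block's
        diseases.
    noise : float in [0, 1)
        Probability of each cross-block association.
    seed : int
        Seed for all randomness; identical seeds give identical output.
    multi_code_fraction : float
        Fraction of diseases carrying a second tree code (so code
        multiplicity beta > 1 occurs in the ontology).
    """
    if n_blocks < 1 or n_blocks > min(n_diseases, n_mirnas):
        raise ValueError("n_blocks must be in [1, min(n_diseases, n_mirnas)]")
    if not 0 < assoc_density <= 1:
        raise ValueError("assoc_density must be in (0, 1]")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    if noise > assoc_density:
        raise ValueError("infeasible: noise may not exceed assoc_density")
    rng = np.random.default_rng(seed)

    diseases = [f"disease_{i:03d}" for i in range(n_diseases)]
    mirnas = [f"mir-{j:03d}" for j in range(n_mirnas)]
    d_block = np.arange(n_diseases) % n_blocks
    m_block = np.arange(n_mirnas) % n_blocks

    ontology = _block_ontology(diseases, d_block, n_blocks, multi_code_fraction, rng)

    # shared-planting rate so the within-block marginal equals assoc_density
    shared = (assoc_density - noise) / (1.0 - noise)
    dmm = np.zeros((n_diseases, n_mirnas), dtype=np.int8)
    for b in range(n_blocks):
        d_in = np.flatnonzero(d_block == b)
        m_in = np.flatnonzero(m_block == b)
        on = rng.random(m_in.size) < shared
        if shared > 0 and not on.any():  # keep every block represented
            on[0] = True
        dmm[np.ix_(d_in, m_in[on])] = 1
    if noise > 0:
        dmm[rng.random(dmm.shape) < noise] = 1

    records = [
        (diseases[i], mirnas[j]) for i, j in np.argwhere(dmm == 1)
    ]
    # first-occurrence order: row-major over the planted matrix
    return ontology, AssociationList(tuple(records))


def _block_ontology(
    diseases: List[str],
    d_block: np.ndarray,
    n_blocks: int,
    multi_code_fraction: float,
    rng: np.random.Generator,
) -> OntologyTable:
    """Rooted forest of tree codes: one subtree per block.

    Each block has an internal group term at a single-segment root code;
    every disease of the block receives a code extending a uniformly chosen
    existing code of the same block, so chains of varying depth arise.  A
    ``multi_code_fraction`` share of diseases gets a second code in the same
    subtree, which yields beta > 1 downstream.
    """
    term_codes: Dict[str, set] = {}
    block_codes: List[List[str]] = []
    for b in range(n_blocks):
        root = f"C{b:02d}"
        term_codes[f"group_{b:02d}"] = {root}
        block_codes.append([root])
    counters = [0] * n_blocks
    for i, name in enumerate(diseases):
        b = int(d_block[i])
        parent = block_codes[b][rng.integers(len(block_codes[b]))]
        counters[b] += 1
        code = f"{parent}.{counters[b]:03d}"
        codes = {code}
        if rng.random() < multi_code_fraction:
            parent2 = block_codes[b][rng.integers(len(block_codes[b]))]
            counters[b] += 1
            codes.add(f"{parent2}.{counters[b]:03d}")
        term_codes[name] = codes
        block_codes[b].extend(sorted(codes))
    return OntologyTable({t: frozenset(c) for t, c in term_codes.items()})
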