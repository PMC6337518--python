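"""Shared fixtures: the published brain-neoplasms hierarchy, small worked
examples, and the planted-block synthetic dataset."""

import numpy as np
import pytest

from winmda.types import AssocMatrix, OntologyTable, SimMatrix
from winmda.simulate import generate_fixture

# The 8-term hierarchy around "brain neoplasms": term -> MeSH tree codes.
# "central nervous system neoplasms" and "nervous system neoplasms" each
# carry two codes (multiplicity beta = 2).
BRAIN_NEOPLASM_CODES = {
    "brain neoplasms": {"C04.588.614.250.195", "C10.228.140.211"},
    "central nervous system neoplasms": {"C04.588.614.250", "C10.551.240"},
    "brain diseases": {"C10.228.140"},
    "nervous system neoplasms": {"C04.588.614", "C10.551"},
    "central nervous system diseases": {"C10.228"},
    "nervous system diseases": {"C10"},
    "neoplasms by site": {"C04.588"},
    "neoplasms": {"C04"},
}


@pytest.fixture(scope="session")
def brain_ontology() -> OntologyTable:
    return OntologyTable(
        {t: frozenset(c) for t, c in BRAIN_NEOPLASM_CODES.items()}
    )


@pytest.fixture()
def xyz_sdd() -> SimMatrix:
    """3-disease similarity matrix of the functional-similarity example."""
    values = np.array([
        [1.0, 0.6, 0.7],
        [0.6, 1.0, 0.5],
        [0.7, 0.5, 1.0],
    ])
    return SimMatrix(["X", "Y", "Z"], values, kind="SDD")


@pytest.fixture()
def xyz_assoc() -> AssocMatrix:
    """Two miRNAs with disease groups {X, Y} and {X, Z}."""
    dmm = np.array([[1, 1], [1, 0], [0, 1]], dtype=np.int8)
    return AssocMatrix(["X", "Y", "Z"], ["m1", "m2"], dmm)


@pytest.fixture(scope="session")
def planted():
    """Planted-block fixture: 20 x 20, 2 blocks, density 0.6, noise 0.02."""
    return generate_fixture(20, 20, 2, 0.6, 0.02, seed=7)


@pytest.fixture(scope="session")
def null_fixture():
    """Same sizes with noise == density: no block signal in the associations."""
    return generate_fixture(20, 20, 2, 0.6, 0.6, seed=7)
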