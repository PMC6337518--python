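"""Gaussian interaction-profile (GIP) kernel similarities and integration.

The interaction profile of a disease is its row of the binary association
matrix (for a miRNA, its column).  The kernel similarity is

    K(u, v) = exp(-gamma * ||u - v||^2),   gamma = n / sum_i ||u_i||^2,

i.e. the bandwidth is normalized by the mean squared profile norm.  On the
disease side the kernel is additionally squashed through a logistic curve

    FDGS = 1 / (1 + exp(-15 * DGS + ln(9999)))

so that unrelated profiles (DGS = 0) map to 1e-4 rather than to a spuriously
moderate similarity; the miRNA-side kernel is used as computed.  Integration
then fills the undefined (-1) entries of the semantic / functional
similarity matrices with the kernel values.
"""

from __future__ import annotations

import numpy as np

from .types import AssocMatrix, SimMatrix

#: Logistic correction constants.
LOGISTIC_SLOPE = 15.0
LOGISTIC_SHIFT = float(np.log(9999.0))


def _gip_kernel(profiles: np.ndarray) -> np.ndarray:
    norms_sq = (profiles.astype(float) ** 2).sum(axis=1)
    total = norms_sq.sum()
    if total == 0:
        raise ValueError("all-zero association matrix: GIP bandwidth undefined")
    gamma = profiles.shape[0] / total
    sq_dists = (
        norms_sq[:, None] + norms_sq[None, :]
        - 2.0 * profiles.astype(float) @ profiles.astype(float).T
    )
    np.maximum(sq_dists, 0.0, out=sq_dists)
    return np.exp(-gamma * sq_dists)


def disease_gip(assoc: AssocMatrix) -> SimMatrix:
    """Disease GIP kernel over association-matrix rows."""
    return SimMatrix(list(assoc.diseases), _gip_kernel(assoc.dmm), kind="DGS")


def mirna_gip(assoc: AssocMatrix) -> SimMatrix:
    """miRNA GIP kernel over association-matrix columns."""
    return SimMatrix(list(assoc.mirnas), _gip_kernel(assoc.dmm.T), kind="FMGS")


def logistic_adjust(dgs: SimMatrix) -> SimMatrix:
    """Logistic correction of the disease kernel; strictly increasing in DGS.

    Note the diagonal maps to logistic(1) ~= 0.997, not to 1; it is kept as
    computed.
    """
    values = 1.0 / (1.0 + np.exp(-LOGISTIC_SLOPE * dgs.values + LOGISTIC_SHIFT))
    return SimMatrix(list(dgs.names), values, kind="FDGS")


def _integrate(primary: SimMatrix, fallback: SimMatrix, kind: str) -> SimMatrix:
    if primary.names != fallback.names:
        raise ValueError("similarity matrices have mismatched indices")
    values = np.where(primary.values >= 0, primary.values, fallback.values)
    return SimMatrix(list(primary.names), values, kind=kind)


def integrate_disease(sdd: SimMatrix, fdgs: SimMatrix) -> SimMatrix:
    """Semantic similarity where defined (>= 0), kernel similarity otherwise."""
    return _integrate(sdd, fdgs, "FDD")


def integrate_mirna(smm: SimMatrix, fmgs: SimMatrix) -> SimMatrix:
    """Functional similarity where defined (>= 0), kernel similarity otherwise."""
    return _integrate(smm, fmgs, "FMM")
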