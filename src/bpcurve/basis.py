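"""Basis profile curve extraction via linear kernel PCA.

Each cluster's curve is the principal direction of its concatenated member
trials V_(q) (T x K_q).  With T >> K_q a direct T x T covariance
eigendecomposition is ill-posed, but the non-zero spectrum of V V^T equals
that of the small K_q x K_q Gram matrix V^T V: eigendecompose
(V^T V) F = F xi^2, map the leading eigenvector back through X = V F, and
keep the normalized first column as B_q(t).  Unit norm of B_q is what makes
the later per-trial projection algebra exact.

Trials are not mean-centered: the back-projection identity
alpha_k = sum_t B_q(t) V_k(t) relies on the raw trials entering the Gram
matrix.  The eigenvector sign is fixed so that the mean projection of the
member trials onto the curve is positive, matching the framework's
non-negative-contribution semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .epoching import TrialMatrix
from .factorization import ClusterAssignment

logger = logging.getLogger(__name__)

__all__ = ["BPCSet", "kernel_pca_first_component", "extract_bpcs"]


@dataclass
class BPCSet:
    """Unit-norm basis profile curves with their cluster provenance."""

    curves: np.ndarray  # (T, Q') unit-norm columns
    time: np.ndarray  # (T,)
    cluster_members: list  # list over curves of subgroup-label lists
    eigvals: np.ndarray  # leading Gram eigenvalue xi^2 per curve
    trial_counts: np.ndarray  # K_q per curve

    @property
    def n_curves(self) -> int:
        return self.curves.shape[1]


def kernel_pca_first_component(V_q: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading principal direction of a T x K trial block via its Gram matrix.

    Returns the unit-norm direction and the leading eigenvalue of V^T V
    (equal to the leading eigenvalue of V V^T).  A single-trial block reduces
    to the normalized trial itself.
    """
    V_q = np.asarray(V_q, dtype=float)
    if V_q.ndim == 1:
        V_q = V_q[:, None]
    if not np.any(V_q):
        raise ValueError("trial block is all zeros; no principal direction exists")
    if V_q.shape[1] == 1:
        logger.info("single-trial cluster: basis curve is the normalized trial")

    gram = V_q.T @ V_q
    gram = 0.5 * (gram + gram.T)  # numerical hygiene
    eigvals, F = eigh(gram)
    lead = float(max(eigvals[-1], 0.0))
    b = V_q @ F[:, -1]
    norm = np.linalg.norm(b)
    if norm == 0:
        raise ValueError("degenerate trial block: leading component has zero norm")
    b /= norm
    # sign: mean projection over member trials must be positive
    if np.sum(b @ V_q) < 0:
        b = -b
    return b, lead


def extract_bpcs(V: TrialMatrix, assignment: ClusterAssignment) -> BPCSet:
    """One basis profile curve per cluster, from the concatenated member trials."""
    curves, eigvals, counts = [], [], []
    for members in assignment.clusters:
        if not members:
            raise ValueError("cannot extract a curve for an empty cluster")
        mask = np.isin(V.labels, members)
        block = V.values[:, mask]
        b, ev = kernel_pca_first_component(block)
        curves.append(b)
        eigvals.append(ev)
        counts.append(block.shape[1])
    if not curves:
        raise ValueError("assignment contains no clusters")
    return BPCSet(
        curves=np.column_stack(curves),
        time=V.time.copy(),
        cluster_members=[list(m) for m in assignment.clusters],
        eigvals=np.asarray(eigvals),
        trial_counts=np.asarray(counts),
    )
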