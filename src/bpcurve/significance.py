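"""Single-trial cross-projections and the subgroup significance matrix.

The pairwise structure between stimulation-pair subgroups is measured without
assuming any response shape.  Every trial is unit-normalized and projected
into every raw trial, ``P(k, l) = sum_t Vtilde_k(t) V_l(t)`` (note P is not
symmetric).  The K x K projection matrix is then sorted into sets
``S[n][m] = P{k in n, l in m}`` with the self-pairs ``k = l`` omitted, and
each set is reduced to a one-sample t-value (mean over its standard error).
Negative t-values are clipped to zero — a cluster cannot contribute with
inverted sign — and the matrix is scaled by its global maximum, giving the
N x N significance matrix Xi with entries in [0, 1] that feeds the
non-negative factorization.

Unlike a correlation matrix, diagonal entries of Xi can be small, and an
off-diagonal entry can exceed the diagonals of its row: this happens when
within-subgroup variation (e.g. adaptation to repeated stimulation) exceeds
the between-subgroup variation of a shared response shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .epoching import TrialMatrix, _unique_in_order

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionSets",
    "SignificanceMatrix",
    "normalize_trials",
    "cross_projection_matrix",
    "build_projection_sets",
    "significance_matrix",
    "significance_from_trials",
]

#: finite stand-in for the t-value of a zero-variance set (sign of the mean
#: is preserved; only pathological synthetic inputs reach this)
ZERO_VARIANCE_T = 1e6


@dataclass
class ProjectionSets:
    """Cross-projection sets S[n][m], keyed by (row subgroup, col subgroup)."""

    sets: dict  # (label_n, label_m) -> 1-D float array
    labels: np.ndarray  # subgroup order (N,)


@dataclass
class SignificanceMatrix:
    """N x N matrix Xi of clipped, max-scaled cross-projection t-values."""

    values: np.ndarray  # (N, N), entries in [0, 1]
    labels: np.ndarray  # subgroup order (N,)


def normalize_trials(V: TrialMatrix) -> TrialMatrix:
    """Return a copy of the trial matrix with unit-Euclidean-norm columns."""
    norms = np.linalg.norm(V.values, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"trial {zero[0]} has zero norm and cannot be normalized")
    return TrialMatrix(
        values=V.values / norms,
        time=V.time.copy(),
        fs=V.fs,
        labels=V.labels.copy(),
    )


def cross_projection_matrix(V_norm: np.ndarray, V_raw: np.ndarray) -> np.ndarray:
    """P = Vtilde^T V: rows index the normalized trial, columns the raw one."""
    V_norm = np.asarray(V_norm, dtype=float)
    V_raw = np.asarray(V_raw, dtype=float)
    if V_norm.shape != V_raw.shape:
        raise ValueError(
            f"shape mismatch: normalized {V_norm.shape} vs raw {V_raw.shape}"
        )
    return V_norm.T @ V_raw


def build_projection_sets(P: np.ndarray, labels: np.ndarray) -> ProjectionSets:
    """Sort P into per-subgroup-pair sets, omitting k = l trial self-pairs."""
    P = np.asarray(P, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != (P.shape[0],) or P.shape[0] != P.shape[1]:
        raise ValueError("labels must cover all trials of the square matrix P")
    subgroups = _unique_in_order(labels)
    index = {lab: np.flatnonzero(labels == lab) for lab in subgroups}
    sets = {}
    for n in subgroups:
        for m in subgroups:
            block = P[np.ix_(index[n], index[m])]
            if n == m:
                k = block.shape[0]
                mask = ~np.eye(k, dtype=bool)
                sets[(n, m)] = block[mask]
            else:
                sets[(n, m)] = block.ravel()
    return ProjectionSets(sets=sets, labels=subgroups)


def _set_tvalue(x: np.ndarray) -> float:
    """One-sample t: mean / (sd / sqrt(count)), sample sd (count - 1)."""
    sd = x.std(ddof=1)
    if sd == 0:
        return ZERO_VARIANCE_T * np.sign(x.mean())
    return x.mean() / (sd / np.sqrt(x.size))


def significance_matrix(S: ProjectionSets) -> SignificanceMatrix:
    """Clip per-set t-values at zero and scale the matrix to its maximum.

    Sets with fewer than two elements (single-trial subgroups) have no
    dispersion estimate; their cells are set to zero with a warning.
    """
    labels = S.labels
    n = labels.size
    xi = np.zeros((n, n))
    for i, ln in enumerate(labels):
        for j, lm in enumerate(labels):
            x = S.sets[(ln, lm)]
            if x.size < 2:
                logger.warning(
                    "projection set (%r, %r) has %d element(s); cell set to 0",
                    ln, lm, x.size,
                )
                continue
            xi[i, j] = _set_tvalue(x)
    np.clip(xi, 0.0, None, out=xi)
    peak = xi.max()
    if peak <= 0:
        raise ValueError(
            "no reliable structure: all cross-projection t-values are non-positive"
        )
    xi /= peak
    return SignificanceMatrix(values=xi, labels=labels)


def significance_from_trials(V: TrialMatrix) -> SignificanceMatrix:
    """Convenience chain: normalize, cross-project, sort into sets, score."""
    Vn = normalize_trials(V)
    P = cross_projection_matrix(Vn.values, V.values)
    return significance_matrix(build_projection_sets(P, V.labels))
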