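"""Non-negative factorization of the significance matrix and subgroup clustering.

Xi ~ W H with W (N x Q) and H (Q x N) non-negative, fitted by multiplicative
updates that minimize the squared Frobenius error eta = |Xi - WH|^2.  After
each H update the rows of H are unit-normalized (the scale moves into the
columns of W, leaving the product unchanged).  Because the updates are
multiplicative, non-negativity is preserved and eta is non-increasing.

The inner dimension Q is chosen by degeneracy pruning: fit at Q, measure
zeta = max upper-off-diagonal of H H^T (how much any two rows overlap), and
step Q down by one until zeta < 0.5.  Q = 1 always terminates (zeta = 0).
Lowering the zeta threshold admits less shared structure between motifs and
can increase the number of discovered curves.

Clustering is winner-take-all on the columns of H: a subgroup joins the row
holding its largest weight, provided that weight exceeds 1/(2N) — half the
weight every subgroup would carry if all contributed equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FactorizationResult",
    "ClusterAssignment",
    "nnmf_update_step",
    "run_nnmf",
    "degeneracy",
    "reduce_dimension",
    "winner_take_all_clusters",
]

#: floor added to update denominators to avoid 0/0; standard practice, below
#: numerical tolerance of the results
EPS = 1e-12

DEFAULT_RESTARTS = 20
DEFAULT_MAX_ITER = 10_000
DEFAULT_TOL = 1e-5
DEFAULT_ZETA_THRESHOLD = 0.5


@dataclass
class FactorizationResult:
    """Best-of-restarts NNMF fit of the significance matrix."""

    W: np.ndarray  # (N, Q), non-negative
    H: np.ndarray  # (Q, N), non-negative, unit-norm rows
    eta: float  # |Xi - WH|^2
    zeta: float  # max upper-off-diagonal of H H^T
    q: int
    n_iter: int
    restart_index: int
    eta_history: np.ndarray = field(default=None)  # per-iteration eta, best restart
    eta_per_restart: np.ndarray = field(default=None)
    reduction_history: list = field(default_factory=list)  # (q, eta, zeta) per tried Q


@dataclass
class ClusterAssignment:
    """Winner-take-all partition of subgroups into clusters plus the excluded set."""

    clusters: list  # list over clusters of lists of subgroup labels
    excluded: list  # subgroup labels assigned to no cluster
    H_wta: np.ndarray  # (Q, N) winner-take-all matrix (original row order)
    cluster_rows: list  # original H-row index of each (renumbered) cluster
    labels: np.ndarray  # subgroup order (N,)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, label) -> int | None:
        """Cluster index of a subgroup, or None if excluded."""
        for q, members in enumerate(self.clusters):
            if label in members:
                return q
        return None


def nnmf_update_step(
    W: np.ndarray, H: np.ndarray, Xi: np.ndarray, eps: float = EPS
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update: H step, H row-normalization, W step.

    The row-normalization moves scale from H into the columns of W, so the
    product WH is unchanged by it (up to floating point).
    """
    H = H * (W.T @ Xi) / (W.T @ W @ H + eps)
    norms = np.linalg.norm(H, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    H = H / safe[:, None]
    W = W * safe[None, :]
    W = W * (Xi @ H.T) / (W @ (H @ H.T) + eps)
    return W, H


def _single_run(
    Xi: np.ndarray, q: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    n, m = Xi.shape
    W = rng.random((n, q))
    H = rng.random((q, m))
    etas = []
    prev = None
    for _ in range(max_iter):
        W, H = nnmf_update_step(W, H, Xi)
        eta = float(np.linalg.norm(Xi - W @ H) ** 2)
        if not np.isfinite(eta):
            return None
        etas.append(eta)
        if eta == 0.0 or (prev is not None and prev - eta < tol * eta):
            break
        prev = eta
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
        return None
    return W, H, np.asarray(etas)


def run_nnmf(
    Xi: np.ndarray,
    q: int,
    restarts: int = DEFAULT_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | np.random.SeedSequence = 0,
) -> FactorizationResult:
    """Fit Xi ~ WH at fixed inner dimension q, keeping the lowest-eta restart.

    W and H start from uniform random values in [0, 1); each restart draws
    from an independent stream spawned from ``seed``, so results are
    bit-reproducible for a fixed seed.
    """
    Xi = np.asarray(Xi, dtype=float)
    if Xi.ndim != 2:
        raise ValueError("Xi must be a matrix")
    if np.any(Xi < 0):
        raise ValueError("Xi must be non-negative")
    if not 1 <= q <= max(Xi.shape):
        raise ValueError(f"inner dimension q={q} out of range for shape {Xi.shape}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(restarts)
    best = None
    per_restart = np.full(restarts, np.nan)
    for r in range(restarts):
        out = _single_run(Xi, q, np.random.default_rng(streams[r]), tol, max_iter)
        if out is None:
            logger.warning("NNMF restart %d diverged (non-finite); skipped", r)
            continue
        W, H, etas = out
        per_restart[r] = etas[-1]
        if best is None or etas[-1] < best[3][-1]:
            best = (r, W, H, etas)
    if best is None:
        raise RuntimeError("all NNMF restarts produced non-finite values")
    r, W, H, etas = best
    logger.debug("NNMF q=%d: best restart %d, eta=%.6g, %d iters", q, r, etas[-1], etas.size)
    return FactorizationResult(
        W=W,
        H=H,
        eta=float(etas[-1]),
        zeta=degeneracy(H),
        q=q,
        n_iter=etas.size,
        restart_index=r,
        eta_history=etas,
        eta_per_restart=per_restart,
    )


def degeneracy(H: np.ndarray, metric: str = "max") -> float:
    """Overlap between rows of H: max (default) or sum of upper-off-diagonal H H^T."""
    H = np.asarray(H, dtype=float)
    q = H.shape[0]
    if q == 1:
        return 0.0
    G = H @ H.T
    iu = np.triu_indices(q, k=1)
    if metric == "max":
        return float(G[iu].max())
    if metric == "sum":
        return float(G[iu].sum())
    raise ValueError(f"unknown degeneracy metric {metric!r}")


def reduce_dimension(
    Xi: np.ndarray,
    q_start: int | None = None,
    zeta_threshold: float = DEFAULT_ZETA_THRESHOLD,
    restarts: int = DEFAULT_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    degeneracy_metric: str = "max",
) -> FactorizationResult:
    """Step the inner dimension down from q_start until zeta < threshold.

    Returns the first (largest-Q) factorization that satisfies the threshold;
    the per-Q (eta, zeta) trace is kept in ``reduction_history``.  By default
    q_start = min(N, 10): starting near the number of plausible distinct
    motifs is cheaper than starting at N and reaches the same endpoint.
    """
    Xi = np.asarray(Xi, dtype=float)
    n = Xi.shape[0]
    if q_start is None:
        q_start = min(n, 10)
    if q_start < 1:
        raise ValueError("q_start must be >= 1")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(q_start)
    history = []
    for q in range(q_start, 0, -1):
        res = run_nnmf(
            Xi, q, restarts=restarts, tol=tol, max_iter=max_iter,
            seed=streams[q - 1],
        )
        zeta = degeneracy(res.H, metric=degeneracy_metric)
        res.zeta = zeta
        history.append((q, res.eta, zeta))
        logger.info("Q=%d: eta=%.6g zeta=%.4f", q, res.eta, zeta)
        if zeta < zeta_threshold:
            res.reduction_history = history
            return res
    raise AssertionError("unreachable: Q=1 has zeta=0")  # pragma: no cover


def winner_take_all_clusters(H: np.ndarray, labels=None) -> ClusterAssignment:
    """Assign each subgroup to the row of H holding its largest weight.

    All but the largest element of each column are zeroed (ties go to the
    lowest row index); the survivor must exceed 1/(2N) for the subgroup to be
    assigned, otherwise it is excluded.  Empty clusters are dropped and the
    rest renumbered in descending order of total assigned weight.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("H must be non-negative")
    q, n = H.shape
    labels = np.arange(n) if labels is None else np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("labels must match the number of H columns")

    threshold = 1.0 / (2 * n)
    winner = np.argmax(H, axis=0)  # ties -> lowest index
    H_wta = np.zeros_like(H)
    H_wta[winner, np.arange(n)] = H[winner, np.arange(n)]

    members = {r: [] for r in range(q)}
    excluded = []
    for col in range(n):
        r = winner[col]
        if H_wta[r, col] > threshold:
            members[r].append(col)
        else:
            excluded.append(col)

    occupied = [r for r in range(q) if members[r]]
    # stable renumbering: heaviest cluster first
    occupied.sort(key=lambda r: -sum(H_wta[r, c] for c in members[r]))
    clusters = [[labels[c] for c in members[r]] for r in occupied]
    return ClusterAssignment(
        clusters=clusters,
        excluded=[labels[c] for c in excluded],
        H_wta=H_wta,
        cluster_rows=occupied,
        labels=labels,
    )
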