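"""Back-projection of basis curves into single trials and summary metrics.

Borrowing the functional-data-analysis parameterization, each trial of an
assigned subgroup is written as

    V_k(t) = alpha_k B_q(t) + eps_k(t)

where B_q is the unit-norm basis curve of the trial's cluster.  Because
sum_t B_q(t)^2 = 1 and the residual is orthogonal to the curve, the
projection weight is simply alpha_k = sum_t B_q(t) V_k(t), and the trial's
energy splits exactly as V_k'V_k = alpha_k^2 + eps_k'eps_k.

Per trial we report alpha (in microvolts, the curve being unit-norm), the
scalar noise eps'eps, the signal-to-noise alpha/(eps'eps), and the explained
variance 1 - eps'eps / V'V.  Per subgroup we report the mean of these, a
t-value of the alphas against zero (how reliably the subgroup expresses its
curve), and the residual pairwise structure <eps_k'eps_l>_{k != l} which
flags shape left unexplained by the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BPCSet, extract_bpcs
from .epoching import TrialMatrix
from .factorization import (
    ClusterAssignment,
    run_nnmf,
    winner_take_all_clusters,
)
from .significance import SignificanceMatrix, significance_from_trials

logger = logging.getLogger(__name__)

__all__ = [
    "TrialParameterization",
    "project_trials",
    "subgroup_metrics",
    "explained_variance_vs_Q",
]

#: finite stand-in for the signal-to-noise of a noiseless trial
SNR_CAP = 1e12


@dataclass
class TrialParameterization:
    """Per-trial curve weights and residuals; excluded trials carry NaN."""

    alpha: np.ndarray  # (K,) projection weight, microvolts
    residual: np.ndarray  # (T, K) eps_k(t); NaN columns for excluded trials
    noise: np.ndarray  # (K,) eps'eps
    snr: np.ndarray  # (K,) alpha / (eps'eps), capped when noise == 0
    snr_capped: np.ndarray  # (K,) bool, True where the cap was applied
    explained_variance: np.ndarray  # (K,) 1 - eps'eps / V'V
    bpc_index: np.ndarray  # (K,) int, -1 for excluded trials
    labels: np.ndarray  # (K,) subgroup label per trial

    @property
    def included(self) -> np.ndarray:
        return self.bpc_index >= 0


def project_trials(
    V: TrialMatrix, bpcs: BPCSet, assignment: ClusterAssignment
) -> TrialParameterization:
    """Parameterize every trial of an assigned subgroup as alpha * B + eps."""
    K = V.n_trials
    label_to_q = {}
    for q, members in enumerate(assignment.clusters):
        for lab in members:
            label_to_q[lab] = q

    alpha = np.full(K, np.nan)
    residual = np.full((V.n_samples, K), np.nan)
    noise = np.full(K, np.nan)
    snr = np.full(K, np.nan)
    capped = np.zeros(K, dtype=bool)
    ev = np.full(K, np.nan)
    bpc_index = np.full(K, -1, dtype=int)

    for q in range(bpcs.n_curves):
        b = bpcs.curves[:, q]
        mask = np.array([label_to_q.get(lab) == q for lab in V.labels])
        if not mask.any():
            continue
        block = V.values[:, mask]
        a = b @ block
        eps = block - np.outer(b, a)
        nse = np.einsum("tk,tk->k", eps, eps)
        power = np.einsum("tk,tk->k", block, block)
        alpha[mask] = a
        residual[:, mask] = eps
        noise[mask] = nse
        # noiseless up to floating point: cap the ratio instead of overflowing
        noiseless = nse <= power * 1e-15
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(~noiseless, a / np.where(~noiseless, nse, 1.0),
                         np.sign(a) * SNR_CAP)
        capped[mask] = noiseless
        snr[mask] = s
        ev[mask] = np.where(power > 0, 1.0 - nse / np.where(power > 0, power, 1.0), 0.0)
        bpc_index[mask] = q

    return TrialParameterization(
        alpha=alpha,
        residual=residual,
        noise=noise,
        snr=snr,
        snr_capped=capped,
        explained_variance=ev,
        bpc_index=bpc_index,
        labels=V.labels.copy(),
    )


def _residual_structure(E: np.ndarray) -> tuple[float, float]:
    """Mean over ordered pairs k != l of eps_k'eps_l, raw and normalized."""
    M = E.T @ E
    k = M.shape[0]
    mask = ~np.eye(k, dtype=bool)
    raw = float(M[mask].mean())
    d = np.sqrt(np.diag(M))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = M / np.outer(d, d)
    norm = float(C[mask].mean()) if np.all(d > 0) else np.nan
    return raw, norm


def subgroup_metrics(
    params: TrialParameterization, one_sided: bool = False
) -> pd.DataFrame:
    """Per-subgroup summary of the trial parameterizations.

    The t-value tests the subgroup's alphas against zero; both one- and
    two-sided p-values are reported.  Residual structure needs at least two
    member trials and is NaN otherwise.
    """
    rows = []
    seen = []
    for lab in params.labels:
        if any(lab == s for s in seen):
            continue
        seen.append(lab)
        mask = params.labels == lab
        q = params.bpc_index[mask][0]
        if q < 0:
            rows.append(
                dict(subgroup=lab, bpc=-1, n_trials=int(mask.sum()),
                     alpha_mean=np.nan, alpha_tval=np.nan, p_two_sided=np.nan,
                     p_one_sided=np.nan, snr_mean=np.nan, ev_mean=np.nan,
                     resid_raw=np.nan, resid_corr=np.nan)
            )
            continue
        a = params.alpha[mask]
        t = np.nan
        p2 = p1 = np.nan
        if a.size >= 2 and a.std(ddof=1) > 0:
            res = stats.ttest_1samp(a, 0.0)
            t, p2 = float(res.statistic), float(res.pvalue)
            p1 = p2 / 2 if t > 0 else 1 - p2 / 2
        if a.size >= 2:
            raw, corr = _residual_structure(params.residual[:, mask])
        else:
            logger.warning("subgroup %r has a single trial; residual structure undefined", lab)
            raw = corr = np.nan
        rows.append(
            dict(
                subgroup=lab,
                bpc=int(q),
                n_trials=int(mask.sum()),
                alpha_mean=float(a.mean()),
                alpha_tval=t,
                p_two_sided=p2,
                p_one_sided=p1,
                snr_mean=float(params.snr[mask].mean()),
                ev_mean=float(params.explained_variance[mask].mean()),
                resid_raw=raw,
                resid_corr=corr,
            )
        )
    return pd.DataFrame(rows)


def explained_variance_vs_Q(
    V: TrialMatrix,
    q_values,
    xi: SignificanceMatrix | None = None,
    restarts: int = 20,
    tol: float = 1e-5,
    max_iter: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled explained variance of the fitted curves at each forced Q.

    For each Q the factorization is run at that fixed inner dimension (no
    degeneracy pruning), curves are extracted and projected back, and the
    pooled explained energy sum(V'V - eps'eps) over included trials is
    normalized two ways: by the total energy of *all* trials (``ev_total``)
    and by the energy of the *included* trials only (``ev_included``).  The
    second is the honest measure of fit quality: stimulating a site with no
    effect should not dilute it.
    """
    if xi is None:
        xi = significance_from_trials(V)
    q_values = list(q_values)
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(q_values))
    power_all = float(np.einsum("tk,tk->", V.values, V.values))
    rows = []
    for q, stream in zip(q_values, streams):
        fact = run_nnmf(xi.values, q, restarts=restarts, tol=tol,
                        max_iter=max_iter, seed=stream)
        assignment = winner_take_all_clusters(fact.H, xi.labels)
        if assignment.n_clusters == 0:
            logger.warning("Q=%d: no subgroup passed the assignment threshold", q)
            rows.append(dict(q=q, ev_total=0.0, ev_included=0.0,
                             n_clusters=0, n_included_trials=0))
            continue
        bpcs = extract_bpcs(V, assignment)
        params = project_trials(V, bpcs, assignment)
        inc = params.included
        power_inc = float(np.einsum("tk,tk->", V.values[:, inc], V.values[:, inc]))
        explained = power_inc - float(params.noise[inc].sum())
        rows.append(
            dict(
                q=q,
                ev_total=explained / power_all if power_all > 0 else 0.0,
                ev_included=explained / power_inc if power_inc > 0 else 0.0,
                n_clusters=assignment.n_clusters,
                n_included_trials=int(inc.sum()),
            )
        )
    return pd.DataFrame(rows)
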