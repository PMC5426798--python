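"""Shifted rank-one approximation of a correlation matrix.

A correlation matrix whose off-diagonal entries follow rho_ij = c S_i S_j is
a diagonal plus a rank-one matrix.  Given eigenvalues lambda_1 >= ... of the
symmetric PSD matrix C, the diagonal shift

    lambda = lambda_1 - sum_{j>1}(lambda_1-lambda_j)^2 / sum_{j>1}(lambda_1-lambda_j)

maximizes the fraction of the Frobenius norm of C - lambda I captured by the
leading singular direction, yielding the approximation

    C ~= lambda I + (sigma_1 - lambda) u_1 u_1^T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["lambda_shift", "LowRankResult", "rank_one_approx",
           "approximation_quality"]


def lambda_shift(eigenvalues, rel_tol: float = 1e-12) -> float:
    """Closed-form optimal diagonal shift from sorted-descending eigenvalues.

    Eigenvalues below ``rel_tol`` times the largest are treated as numerical
    zeros and excluded from the rank.  All-equal spectra leave the shift
    undefined (zero denominator) and raise.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if lam.size < 2:
        raise ValueError("need at least two eigenvalues")
    keep = lam > rel_tol * abs(lam[0])
    lam = lam[keep] if keep.sum() >= 2 else lam
    gaps = lam[0] - lam[1:]
    denom = gaps.sum()
    if denom <= 0:
        raise ValueError("all eigenvalues equal: shift undefined")
    return float(lam[0] - (gaps ** 2).sum() / denom)


@dataclass
class LowRankResult:
    lambda_shift: float
    sigma1: float
    u1: np.ndarray
    approx: np.ndarray
    frobenius_fraction: float
    eigenvalues: np.ndarray


def rank_one_approx(C: np.ndarray, rates=None) -> LowRankResult:
    """Approximate a symmetric correlation matrix as lambda I + (s1-lambda) u1 u1^T.

    ``rates`` (optional) fixes the sign of u1 so its rate-weighted mean entry
    is nonnegative; without rates the plain mean entry is used.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    lam_all, U = np.linalg.eigh(C)
    order = np.argsort(lam_all)[::-1]
    lam_all = lam_all[order]
    U = U[:, order]
    lam = lambda_shift(lam_all)
    sigma1 = float(lam_all[0])
    u1 = U[:, 0].copy()
    weights = np.asarray(rates, dtype=float) if rates is not None else np.ones(C.shape[0])
    if float(weights @ u1) < 0:
        u1 = -u1
    approx = lam * np.eye(C.shape[0]) + (sigma1 - lam) * np.outer(u1, u1)
    shifted = (lam_all - lam) ** 2
    frac = float(shifted[0] / shifted.sum()) if shifted.sum() > 0 else 1.0
    return LowRankResult(lambda_shift=lam, sigma1=sigma1, u1=u1, approx=approx,
                         frobenius_fraction=frac, eigenvalues=lam_all)


def approximation_quality(C: np.ndarray, result: LowRankResult,
                          rates=None) -> dict:
    """Off-diagonal scatter diagnostics and the u1-vs-rate association."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    iu = np.triu_indices(n, k=1)
    true_od = C[iu]
    approx_od = result.approx[iu]
    res = stats.linregress(true_od, approx_od)
    out = {
        "true_range": (float(true_od.min()), float(true_od.max())),
        "approx_range": (float(approx_od.min()), float(approx_od.max())),
        "offdiag_r2": float(res.rvalue ** 2),
        "offdiag_slope": float(res.slope),
    }
    if rates is not None:
        r = np.asarray(rates, dtype=float)
        rr = stats.linregress(r, result.u1)
        out["u1_rate_r2"] = float(rr.rvalue ** 2)
        out["u1_rate_spearman"] = float(stats.spearmanr(r, result.u1).statistic)
    return out
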