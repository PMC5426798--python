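"""Decomposition of predicted correlations into graph-motif contributions.

Expanding (I-K)^{-1} C0 (I-K*)^{-1} in powers of K attributes correlation to
undirected paths: the order-n piece

    P^n = sum_{l=0..n} K^{n-l} C0 (K*)^l

collects every pair of directed paths (one onto each cell) of total length n.
The normalized contribution R^n divides entrywise by the geometric mean of
the total autospectra, so that the R^n sum over all orders converges to the
long-window correlation coefficient.  At second order the partition over the
intermediate cell separates four motif types: E and I chains (one cell two
synapses away from the other, through an E or I relay) and E and I common
input (a shared presynaptic E or I cell).

All quantities default to zero frequency, i.e. long-timescale correlation;
the matrices may equally be evaluated at any other frequency.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["spectral_radius", "order_contribution", "normalize_contribution",
           "second_order_by_motif", "cumulative_orders",
           "motif_regression_stats", "pair_table"]


def spectral_radius(K: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def _check_convergent(K):
    rho = spectral_radius(K)
    if rho >= 1.0:
        raise ValueError(f"motif series diverges: spectral radius {rho:.4f} >= 1")
    return rho


def order_contribution(K: np.ndarray, C0_diag: np.ndarray, n: int) -> np.ndarray:
    """P^n = sum_{l=0..n} K^(n-l) C0 (K^H)^l  (order-n path contribution)."""
    _check_convergent(K)
    C0 = np.diag(np.asarray(C0_diag, dtype=K.dtype))
    if n == 0:
        return C0
    KH = K.conj().T
    left = [np.linalg.matrix_power(K, p) for p in range(n + 1)]
    out = np.zeros_like(C0)
    right = np.eye(K.shape[0], dtype=K.dtype)
    for l in range(n + 1):
        out = out + left[n - l] @ C0 @ right
        right = right @ KH
    return out


def cumulative_orders(K: np.ndarray, C0_diag: np.ndarray, n_max: int):
    """List [P^0, ..., P^n_max] computed by the recursion
    C^n = C0 + K C^{n-1} + C^{n-1} K^H - K C^{n-2} K^H  (truncated series)."""
    _check_convergent(K)
    C0 = np.diag(np.asarray(C0_diag, dtype=K.dtype))
    KH = K.conj().T
    prev2 = None
    prev = C0
    P = [C0]
    for n in range(1, n_max + 1):
        Cn = C0 + K @ prev + prev @ KH
        if prev2 is not None:
            Cn = Cn - K @ prev2 @ KH
        P.append(Cn - prev)
        prev2, prev = prev, Cn
    return P


def normalize_contribution(P: np.ndarray, C_total: np.ndarray) -> np.ndarray:
    """R^n: P^n scaled by the geometric mean of total autospectra."""
    d = np.real(np.diag(C_total))
    if np.any(d <= 0):
        raise ValueError("total spectrum has nonpositive diagonal entries")
    inv = 1.0 / np.sqrt(d)
    return P * np.outer(inv, inv)


def second_order_by_motif(K: np.ndarray, C0_diag: np.ndarray,
                          cell_type: np.ndarray) -> dict:
    """Split P^2 by the type of the intermediate cell.

    Chains (K^2 C0 and C0 (K^H)^2, both directions summed) are split by the
    relay cell; common input (K C0 K^H) by the shared source cell.  The four
    pieces partition P^2 exactly.
    """
    _check_convergent(K)
    C0 = np.asarray(C0_diag, dtype=K.dtype)
    KH = K.conj().T
    out = {}
    for X, name in ((0, "E"), (1, "I")):
        m = np.asarray(cell_type) == X
        Ksel = K[:, m]
        K2_X = Ksel @ K[m, :]
        chain = K2_X @ np.diag(C0) + np.diag(C0) @ K2_X.conj().T
        common = (Ksel * C0[m][None, :]) @ Ksel.conj().T
        out[f"{name}_chain"] = chain
        out[f"{name}_common"] = common
    return out


def pair_table(matrices: dict, cell_type: np.ndarray, rates=None):
    """Long-format table over distinct E-E pairs (i < j, both excitatory).

    ``matrices`` maps column name -> square matrix; returns a pandas
    DataFrame with one row per pair, plus geometric-mean rate if given.
    """
    import pandas as pd

    exc = np.flatnonzero(np.asarray(cell_type) == 0)
    ii, jj = np.triu_indices(exc.size, k=1)
    gi, gj = exc[ii], exc[jj]
    data = {"i": gi, "j": gj}
    if rates is not None:
        rates = np.asarray(rates, dtype=float)
        data["geom_rate"] = np.sqrt(rates[gi] * rates[gj])
    for name, M in matrices.items():
        data[name] = np.real(np.asarray(M))[gi, gj]
    return pd.DataFrame(data)


def motif_regression_stats(table, total_col: str, contrib_cols,
                           fractions: bool = False,
                           max_nonpositive_frac: float = 0.01) -> dict:
    """Per-contribution simple OLS R^2 (with intercept) of the total against
    each contribution column, and optionally the mean fraction of total.

    The fraction-of-total measure only makes sense when the totals are
    (essentially all) positive: pairs with nonpositive total are dropped
    when they are rare (at most ``max_nonpositive_frac`` of pairs, matching
    the strong-asynchronous situation where a fraction of a percent of pairs
    sit just below zero) and the measure is refused outright when they are
    pervasive, as in the asynchronous regime where contributions of both
    signs cancel.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 pairs")
    y = np.asarray(table[total_col], dtype=float)
    out = {"r2": {}, "fraction": {}}
    for col in contrib_cols:
        x = np.asarray(table[col], dtype=float)
        res = stats.linregress(x, y)
        out["r2"][col] = float(res.rvalue ** 2)
    if fractions:
        bad = y <= 0
        if bad.mean() > max_nonpositive_frac:
            raise ValueError(
                f"fraction-of-total undefined: {bad.sum()} of {bad.size} "
                "totals are nonpositive in this regime")
        keep = ~bad
        for col in contrib_cols:
            x = np.asarray(table[col], dtype=float)
            out["fraction"][col] = float(np.mean(x[keep] / y[keep]))
    return out
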