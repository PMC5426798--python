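"""Network linear response: interaction matrix, cross-spectra, windowed counts.

Each cell's spike train is approximated as its baseline train plus the
filtered trains of its presynaptic partners passed through the cell's
susceptibility, giving in the frequency domain

    C(f) = (I - K(f))^{-1} C0(f) (I - K(f)*)^{-1},

with C0(f) the diagonal matrix of baseline power spectra and the interaction
matrix combining, for an edge j -> i of source type X,

    K_ij(f) = A_<gX>,i(f) J_ij(f) + A_sX2,i(f) L_ij(f)
    J_ij(f) = alpha_hat_ij tau_r,X F_X(f)
    L_ij(f) = J_ij(f) * (alpha_hat_ij / 2) * tau_r,X / (tau_r,X + tau_d,X)

where F_X is the unit-area synaptic kernel transform.  J converts a rate
modulation of the source into the modulation of the target's mean
conductance (per unit rate: alpha_hat tau_r), L into the modulation of its
conductance variance; the scale factors are exactly the rate-derivatives of
the Poisson conductance moments.  Inhibition enters through the sign of the
susceptibility to <gI> (negative), not through signed weights.

Transform convention: C(f) = integral C(tau) exp(-2 pi i f tau) dtau with f
in cycles/ms internally (Hz = 1000 * cycles/ms at the API boundary where
noted).  The spike-count covariance over windows of length T follows from
the triangular-kernel identity

    Cov_T(i,j) = integral C_ij(f) T^2 sinc^2(f T) df

evaluated by quadrature on a uniform frequency grid after splitting off the
exact Poisson part (the diagonal delta contributes nu_i T exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .network import EXC, INH, SYNAPSE, Network
from .richardson import (SolverGrid, compute_spectral_set,
                         default_frequency_grid)
from .diffusion import operating_points, cell_operating_point, \
    self_consistent_rates

__all__ = ["synaptic_filter_ft", "interaction_matrix",
           "cross_spectrum_matrix", "window_covariance",
           "NetworkLinearResponse"]


def synaptic_filter_ft(tau_r, tau_d, f):
    """Transform of the unit-area double-exponential synaptic kernel at
    frequency f (cycles per unit of tau_r/tau_d):
    1 / ((1 + 2 pi i f tau_r)(1 + 2 pi i f tau_d))."""
    w = 2j * np.pi * np.asarray(f, dtype=float)
    return 1.0 / ((1.0 + w * tau_r) * (1.0 + w * tau_d))


def _edge_filters(network: Network, f_cyc_ms: float):
    """Dense J(f) and L(f) matrices (zero off the adjacency support)."""
    amp = network.edge_amplitudes()
    ct = network.cell_type
    J = np.zeros(amp.shape, dtype=np.complex128)
    L = np.zeros(amp.shape, dtype=np.complex128)
    for X in (EXC, INH):
        syn = SYNAPSE[X]
        cols = ct == X
        Ff = synaptic_filter_ft(syn.tau_r, syn.tau_d, f_cyc_ms)
        Jx = amp[:, cols] * syn.tau_r * Ff
        J[:, cols] = Jx
        L[:, cols] = Jx * amp[:, cols] * 0.5 * syn.tau_r / (syn.tau_r + syn.tau_d)
    return J, L


def interaction_matrix(network: Network, A_gE, A_gI, A_sE2, A_sI2,
                       f_cyc_ms: float) -> np.ndarray:
    """K(f) given the per-cell susceptibilities evaluated at f."""
    for arr in (A_gE, A_gI, A_sE2, A_sI2):
        if np.any(~np.isfinite(arr)):
            raise ValueError("missing susceptibility for some cell")
    J, L = _edge_filters(network, f_cyc_ms)
    ct = network.cell_type
    K = np.zeros(J.shape, dtype=np.complex128)
    colE = ct == EXC
    K[:, colE] = (np.asarray(A_gE)[:, None] * J[:, colE]
                  + np.asarray(A_sE2)[:, None] * L[:, colE])
    K[:, ~colE] = (np.asarray(A_gI)[:, None] * J[:, ~colE]
                   + np.asarray(A_sI2)[:, None] * L[:, ~colE])
    return K


def cross_spectrum_matrix(K: np.ndarray, C0_diag: np.ndarray) -> np.ndarray:
    """C(f) = (I-K)^{-1} diag(C0) (I-K)^{-H}; raises if I-K is singular."""
    n = K.shape[0]
    M = np.eye(n) - K
    try:
        B = np.linalg.inv(M)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"I - K singular: {err}") from err
    C = (B * np.asarray(C0_diag)[None, :]) @ B.conj().T
    return 0.5 * (C + C.conj().T)


def _window_quadrature(T, f_max, df):
    """Trapezoid nodes/weights for integral C(f) T^2 sinc^2(fT) df over the
    whole line, folded onto f >= 0.  The triangular-kernel weight confines
    the mass to f of order 1/T, so range and resolution adapt to T."""
    f_max = min(f_max, max(200.0 / T, 0.05))
    df = min(df, 1.0 / (40.0 * T))
    freqs = np.arange(0.0, f_max + df, df)
    s = np.sinc(freqs * T) ** 2 * T * T
    w = np.full(freqs.size, df)
    w[0] = w[-1] = 0.5 * df
    w = w * s * np.where(freqs > 0, 2.0, 1.0)
    return freqs, w


def window_covariance(cross_spectrum, rates, T, f_max: float = 1.5,
                      df: float = 2.5e-4):
    """Spike-count covariance and correlation at window length T (ms).

    ``cross_spectrum`` is a callable f (cycles/ms) -> complex matrix;
    ``rates`` the stationary rates (1/ms) giving the exact Poisson diagonal.
    ``T=np.inf`` returns the long-window limit Cov_T/T = C(0).
    """
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    if np.isinf(T):
        C0m = np.real(cross_spectrum(0.0))
        cov = C0m.copy()
    else:
        freqs, weights = _window_quadrature(T, f_max, df)
        acc = np.zeros((n, n))
        for f, w in zip(freqs, weights):
            resid = np.real(cross_spectrum(f)) - np.diag(rates)
            acc += w * resid
        cov = acc + np.diag(rates) * T
    var = np.diag(cov).copy()
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ArithmeticError(
            f"nonpositive predicted count variance for cells {bad[:5]}; "
            "refine the frequency grid instead of clipping")
    corr = cov / np.sqrt(np.outer(var, var))
    return cov, corr


class NetworkLinearResponse:
    """Full linear-response prediction for one network.

    Computes the self-consistent operating point, solves each cell's
    baseline spectrum and susceptibilities on a logarithmic frequency grid,
    and exposes K(f), C(f) and windowed count statistics with the spectral
    functions interpolated (monotone cubic, separately in real and imaginary
    part) between solver frequencies.
    """

    def __init__(self, network: Network, grid: SolverGrid = SolverGrid(),
                 solver_freqs_hz=None, rates=None, progress: bool = False):
        self.network = network
        self.grid = grid
        if rates is None:
            rates = self_consistent_rates(network, grid).nu
        self.rates = np.asarray(rates, dtype=float)
        if solver_freqs_hz is None:
            solver_freqs_hz = default_frequency_grid()
        self.freqs_hz = np.asarray(solver_freqs_hz, dtype=float)
        gE, gI, sE2, sI2 = operating_points(network, self.rates)
        self.spectra = []
        for i in range(network.n_cells):
            op = cell_operating_point(network, i, gE, gI, sE2, sI2)
            self.spectra.append(compute_spectral_set(op, self.freqs_hz, grid))
            if progress and (i + 1) % 20 == 0:
                print(f"  spectra {i + 1}/{network.n_cells}")
        self.nu0 = np.array([s.nu0 for s in self.spectra])
        f = self.freqs_hz
        self._C0_tab = np.array([s.C0 for s in self.spectra])
        self._A_tab = {k: np.array([s.A[k] for s in self.spectra])
                       for k in ("gE_mean", "gI_mean", "sigmaE2", "sigmaI2",
                                 "mu")}
        self._C0_ip = PchipInterpolator(f, self._C0_tab, axis=1,
                                        extrapolate=True)
        self._A_ip = {k: (PchipInterpolator(f, v.real, axis=1, extrapolate=True),
                          PchipInterpolator(f, v.imag, axis=1, extrapolate=True))
                      for k, v in self._A_tab.items()}

    # interpolated per-cell functions ---------------------------------------

    def baseline_spectrum(self, f_hz: float) -> np.ndarray:
        f_hz = min(abs(f_hz), self.freqs_hz[-1])
        return np.maximum(self._C0_ip(f_hz), 0.0)

    def susceptibilities(self, f_hz: float) -> dict:
        f_hz = min(abs(f_hz), self.freqs_hz[-1])
        return {k: re(f_hz) + 1j * im(f_hz)
                for k, (re, im) in self._A_ip.items()}

    # matrices --------------------------------------------------------------

    def interaction(self, f_hz: float) -> np.ndarray:
        A = self.susceptibilities(f_hz)
        return interaction_matrix(self.network, A["gE_mean"], A["gI_mean"],
                                  A["sigmaE2"], A["sigmaI2"], f_hz * 1e-3)

    def cross_spectrum(self, f_hz: float) -> np.ndarray:
        return cross_spectrum_matrix(self.interaction(f_hz),
                                     self.baseline_spectrum(f_hz))

    def zero_frequency(self) -> np.ndarray:
        return np.real(self.cross_spectrum(0.0))

    def spectral_radius(self, f_hz: float = 0.0) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.interaction(f_hz)))))

    def window_statistics(self, T, f_max_hz: float = 1500.0,
                          df_hz: float = 0.25):
        """(cov, corr) of spike counts at window T ms (T may be np.inf).

        Uses a vectorized path: the per-cell spectral tables are evaluated
        on the whole quadrature grid at once before the per-frequency
        matrix algebra.
        """
        if np.isinf(T):
            return window_covariance(
                lambda f_cyc: self.cross_spectrum(f_cyc * 1e3),
                self.rates, T)
        freqs, weights = _window_quadrature(T, f_max_hz * 1e-3, df_hz * 1e-3)
        f_hz = np.minimum(freqs * 1e3, self.freqs_hz[-1])
        C0_all = np.maximum(self._C0_ip(f_hz), 0.0)
        A_all = {k: re(f_hz) + 1j * im(f_hz)
                 for k, (re, im) in self._A_ip.items()}
        n = self.network.n_cells
        acc = np.zeros((n, n))
        diag_r = np.diag(self.rates)
        for idx in range(freqs.size):
            K = interaction_matrix(
                self.network, A_all["gE_mean"][:, idx],
                A_all["gI_mean"][:, idx], A_all["sigmaE2"][:, idx],
                A_all["sigmaI2"][:, idx], freqs[idx])
            Cf = cross_spectrum_matrix(K, C0_all[:, idx])
            acc += weights[idx] * (np.real(Cf) - diag_r)
        cov = acc + diag_r * T
        var = np.diag(cov).copy()
        if np.any(var <= 0):
            raise ArithmeticError("nonpositive predicted count variance; "
                                  "refine the frequency grid")
        corr = cov / np.sqrt(np.outer(var, var))
        return cov, corr
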