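"""Threshold integration for the LIF with multiplicative (conductance) noise.

The effective single-cell model, once recurrent input is summarized by mean
conductances and conductance fluctuations, is the Ito stochastic equation

    tau_m dv = [-v - gE (v - E_E) - gI (v - E_I)] dt
               + [sE (v-E_E) dW_E + sI (v-E_I) dW_I + sigma sqrt(tau_m) dW]

with threshold theta, reset 0 and refractory period tau_ref, i.e. drift

    a(v) = [-v - gE (v - E_E) - gI (v - E_I)] / tau_m

and voltage-dependent diffusion coefficient

    D(v) = [sE2 (v - E_E)^2 + sI2 (v - E_I)^2 + sigma^2 tau_m] / (2 tau_m^2).

Stationary rate, spike-train power spectrum and linear-response
susceptibilities are all solutions of first-order boundary-value problems in
voltage, integrated from threshold downward on a uniform grid ("threshold
integration").  The probability flux J(v) = a P - d(D P)/dv and the scaled
density q = D P satisfy dq/dv = (a/D) q - J, which each sweep integrates with
an exponential (integrating-factor) step using the midpoint value of a/D, so
the stationary problem is resolved essentially exactly and frequency-domain
problems are first order in the grid spacing with an exactly-integrated
stiff part.

Four conductance susceptibilities are available (to the means gE, gI and the
variances sE2, sI2) plus the current-equivalent susceptibility to the
effective potential mu; at omega = 0 each equals the partial derivative of
the stationary rate with respect to its parameter, computed from its own
stationary-perturbation boundary-value problem rather than as a numerical
omega -> 0 limit.  The spike-train power spectrum uses the renewal identity
C0(f) = nu0 (1 - |F|^2)/|1 - F|^2 with F the Fourier transform of the
interspike-interval density; F is obtained from the first-passage problem by
the same sweep, and the refractory period contributes a delay factor
exp(-2 pi i f tau_ref).  C0(0) = nu0 * CV^2 comes from the first two
first-passage moments, solved as backward ODEs on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import EXC, INH, SYNAPSE, TAU_M, TAU_REF

__all__ = ["CellOperatingPoint", "SolverGrid", "SpectralSet",
           "ThresholdIntegrator", "steady_rate", "susceptibility",
           "unperturbed_power_spectrum", "compute_spectral_set",
           "default_frequency_grid", "SUSCEPTIBILITY_KINDS"]

E_E = SYNAPSE[EXC].reversal
E_I = SYNAPSE[INH].reversal

SUSCEPTIBILITY_KINDS = ("gE_mean", "gI_mean", "sigmaE2", "sigmaI2", "mu")


@dataclass(frozen=True)
class CellOperatingPoint:
    """Inputs defining the effective single-cell problem.

    ``gE_mean``/``gI_mean`` are mean synaptic conductances (dimensionless),
    ``sE2``/``sI2`` the conductance fluctuation variances, ``sigma`` the
    background-noise magnitude, ``theta`` the spike threshold.
    """

    gE_mean: float
    gI_mean: float
    sE2: float
    sI2: float
    sigma: float
    theta: float
    tau_m: float = TAU_M
    tau_ref: float = TAU_REF


@dataclass(frozen=True)
class SolverGrid:
    """Voltage-grid settings.

    ``v_lb`` is the lower (reflecting) bound.  The default (None) places it
    adaptively at ``mu - 8 * std`` (capped at -1 from above), where mu and
    std are the effective operating point's quasi-stationary mean and
    subthreshold voltage spread — deep enough that the unbounded-domain
    problem is recovered to well below the grid-discretization error.  The
    working grid is uniform, contains the reset (0) and threshold exactly,
    and extends to at most ``v_lb`` (it may overshoot below by less than one
    step so that 0 lands on a node).
    """

    v_lb: float | None = None
    n_v: int = 2048

    def __post_init__(self):
        if self.v_lb is not None and self.v_lb >= 0:
            raise ValueError("lower bound must be below the reset potential")
        if self.n_v < 512:
            raise ValueError("grid too coarse (n_v >= 512)")


@dataclass
class SpectralSet:
    """Baseline spectral quantities of one cell on a frequency grid (Hz).

    ``freqs[0]`` is exactly 0; ``C0`` is the spike-train power spectrum in
    spikes/ms units and ``A[kind]`` the complex susceptibility per unit
    parameter, with ``A[kind][0]`` equal to the stationary-rate derivative.
    """

    freqs: np.ndarray
    nu0: float
    C0: np.ndarray
    A: dict = field(default_factory=dict)


@njit(cache=True)
def _sweep(omega, dv, k_re, D, expG, wG, Emod, s, j_top, jump, tau_ref):
    """Downward integrating-factor sweep shared by every frequency-domain
    boundary-value problem.

    Returns (J at the lower bound, integral of the density).  ``Emod`` is
    deltaD * P0 for diffusion-modulation problems (else zeros); ``s`` is the
    source term on nodes; ``jump`` is subtracted from J when the sweep passes
    the reset node.  Density is P = (u - Emod)/D with u the swept variable.
    """
    n = D.shape[0]
    J = j_top + 0j
    u = 0j
    P_up = (u - Emod[n - 1]) / D[n - 1]
    Pint = 0j
    iw = 1j * omega
    for k in range(n - 1, 0, -1):
        J = J + iw * P_up * dv
        if k - 1 == k_re:
            J = J - jump
        H = J - s[k - 1]
        u = u * expG[k - 1] + H * wG[k - 1]
        P_lo = (u - Emod[k - 1]) / D[k - 1]
        Pint += 0.5 * (P_up + P_lo) * dv
        P_up = P_lo
    return J, Pint


@njit(cache=True)
def _sweep_density(dv, k_re, D, expG, wG, s, j_top, jump):
    """Stationary-form sweep (omega = 0) returning the full density array."""
    n = D.shape[0]
    P = np.zeros(n)
    J = j_top
    u = 0.0
    for k in range(n - 1, 0, -1):
        if k - 1 == k_re:
            J = J - jump
        H = J - s[k - 1]
        u = u * expG[k - 1] + H * wG[k - 1]
        P[k - 1] = u / D[k - 1]
    return P


@njit(cache=True)
def _sweep_moment(dv, D, expG, wG, R):
    """Upward sweep for first-passage moment ODEs  D w' + a w = -R  with
    w(v_lb) = 0; returns w on nodes (w = dT/dv for the moment T)."""
    n = D.shape[0]
    w = np.zeros(n)
    for k in range(n - 1):
        w[k + 1] = w[k] * expG[k] - (R[k + 1] / D[k + 1]) * wG[k]
    return w


class ThresholdIntegrator:
    """Boundary-value solver for one operating point.

    Precomputes the voltage grid and the exponential step factors (which are
    shared by every stationary, spectral and susceptibility problem for the
    cell) once, then exposes the individual solves.
    """

    def __init__(self, op: CellOperatingPoint, grid: SolverGrid = SolverGrid()):
        self.op = op
        self.grid = grid
        theta = op.theta
        if theta <= 0:
            raise ValueError("threshold must be positive")
        v_lb = grid.v_lb
        if v_lb is None:
            g0 = 1.0 + op.gE_mean + op.gI_mean
            mu = (op.gE_mean * E_E + op.gI_mean * E_I) / g0
            s2 = (op.sE2 * (mu - E_E) ** 2 + op.sI2 * (mu - E_I) ** 2
                  + op.sigma ** 2 * op.tau_m) / (g0 * op.tau_m)
            std = np.sqrt(0.5 * s2)  # quasi-stationary voltage spread
            v_lb = min(-1.0, mu - 8.0 * std)
        self.v_lb = v_lb
        # uniform grid with nodes exactly at 0 and theta
        span = theta - v_lb
        dv = span / (grid.n_v - 1)
        m_up = int(round(theta / dv))
        m_up = max(m_up, 8)
        dv = theta / m_up
        m_dn = int(np.ceil(-v_lb / dv))
        self.v = (np.arange(-m_dn, m_up + 1)) * dv
        self.dv = dv
        self.k_re = m_dn  # index of v = 0
        v = self.v
        tm = op.tau_m
        self.a = (-v - op.gE_mean * (v - E_E) - op.gI_mean * (v - E_I)) / tm
        self.D = (op.sE2 * (v - E_E) ** 2 + op.sI2 * (v - E_I) ** 2
                  + op.sigma ** 2 * tm) / (2.0 * tm * tm)
        if np.any(self.D <= 0):
            raise ValueError("diffusion coefficient must be positive on the grid")
        vm = 0.5 * (v[1:] + v[:-1])
        a_mid = (-vm - op.gE_mean * (vm - E_E) - op.gI_mean * (vm - E_I)) / tm
        D_mid = (op.sE2 * (vm - E_E) ** 2 + op.sI2 * (vm - E_I) ** 2
                 + op.sigma ** 2 * tm) / (2.0 * tm * tm)
        G = a_mid / D_mid
        x = G * dv
        self.expG = np.exp(-x)
        with np.errstate(invalid="ignore"):
            w = np.where(np.abs(x) > 1e-8, (1.0 - self.expG) / G,
                         dv * (1.0 - 0.5 * x))
        self.wG = w
        self._stationary = None

    # -- stationary ---------------------------------------------------------

    def stationary(self):
        """(nu0, P0): steady rate (1/ms) and normalized stationary density."""
        if self._stationary is None:
            zeros = np.zeros(self.v.size)
            P_hat = _sweep_density(self.dv, self.k_re, self.D, self.expG,
                                   self.wG, zeros, 1.0, 1.0)
            area = np.trapezoid(P_hat, dx=self.dv)
            nu0 = 1.0 / (area + self.op.tau_ref)
            self._stationary = (nu0, nu0 * P_hat, area)
        return self._stationary[0], self._stationary[1]

    @property
    def nu0(self) -> float:
        return self.stationary()[0]

    # -- first-passage moments ---------------------------------------------

    def fpt_moments(self):
        """Mean and variance of the diffusion first-passage time from reset
        to threshold (refractory period not included)."""
        def cumulative_from_top(w):
            # S(v_k) = int_{v_k}^{theta} w dv by trapezoid
            incr = 0.5 * (w[1:] + w[:-1]) * self.dv
            S = np.zeros(self.v.size)
            S[:-1] = np.cumsum(incr[::-1])[::-1]
            return S

        w1 = _sweep_moment(self.dv, self.D, self.expG, self.wG,
                           np.ones(self.v.size))
        T1 = -cumulative_from_top(w1)  # mean FPT from each start voltage
        w2 = _sweep_moment(self.dv, self.D, self.expG, self.wG, 2.0 * T1)
        T2 = -cumulative_from_top(w2)
        m = T1[self.k_re]
        var = T2[self.k_re] - m * m
        return m, var

    # -- power spectrum ------------------------------------------------------

    def isi_transform(self, freq_hz: float) -> complex:
        """Fourier transform of the ISI density at frequency f (Hz),
        including the refractory delay factor."""
        omega = 2.0 * np.pi * freq_hz * 1e-3  # rad/ms
        zerosc = np.zeros(self.v.size, dtype=np.complex128)
        Ja, _ = _sweep(omega, self.dv, self.k_re, self.D, self.expG, self.wG,
                       zerosc, zerosc, 1.0, 0.0, self.op.tau_ref)
        Jb, _ = _sweep(omega, self.dv, self.k_re, self.D, self.expG, self.wG,
                       zerosc, zerosc, 0.0, 1.0, self.op.tau_ref)
        f_fp = -Jb / Ja
        return f_fp * np.exp(-1j * omega * self.op.tau_ref)

    def power_spectrum(self, freqs_hz) -> np.ndarray:
        """Baseline spike-train power spectrum C0(f) (units 1/ms) on a grid
        of frequencies in Hz.  f = 0 entries use the renewal CV^2 limit."""
        nu0, _ = self.stationary()
        out = np.empty(len(freqs_hz))
        m, var = None, None
        for i, f in enumerate(freqs_hz):
            if f == 0.0:
                if m is None:
                    m, var = self.fpt_moments()
                isi_mean = m + self.op.tau_ref
                out[i] = nu0 * var / (isi_mean * isi_mean)
            else:
                F = self.isi_transform(f)
                out[i] = nu0 * (1.0 - abs(F) ** 2) / abs(1.0 - F) ** 2
        return out

    # -- susceptibilities ----------------------------------------------------

    def _modulation_terms(self, which: str):
        """(delta drift, delta diffusion) arrays per unit parameter change."""
        v, tm = self.v, self.op.tau_m
        da = np.zeros(v.size)
        dD = np.zeros(v.size)
        if which == "gE_mean":
            da = -(v - E_E) / tm
        elif which == "gI_mean":
            da = -(v - E_I) / tm
        elif which == "mu":
            g0 = 1.0 + self.op.gE_mean + self.op.gI_mean
            da = np.full(v.size, g0 / tm)
        elif which == "sigmaE2":
            dD = (v - E_E) ** 2 / (2.0 * tm * tm)
        elif which == "sigmaI2":
            dD = (v - E_I) ** 2 / (2.0 * tm * tm)
        else:
            raise ValueError(f"unknown susceptibility kind {which!r}")
        return da, dD

    def susceptibility(self, freq_hz: float, which: str) -> complex:
        """First-order rate response per unit modulation of one parameter at
        frequency f (Hz); at f = 0 this is d(nu0)/d(parameter)."""
        nu0, P0 = self.stationary()
        da, dD = self._modulation_terms(which)
        Emod = (dD * P0).astype(np.complex128)
        a_over_D = self.a / self.D
        s = (da * P0 - a_over_D * dD * P0).astype(np.complex128)
        zerosc = np.zeros(self.v.size, dtype=np.complex128)
        if freq_hz == 0.0:
            # stationary perturbation: exit-rate change A fixed by probability
            # conservation, integral(P1) + A*tau_ref = 0 split over the
            # homogeneous (reinjection) and inhomogeneous (source) solutions;
            # the homogeneous density integral is the stationary one.
            int_a = self._stationary[2] + self.op.tau_ref
            _, Pint_b = _sweep(0.0, self.dv, self.k_re, self.D, self.expG,
                               self.wG, Emod, s, 0.0, 0.0, self.op.tau_ref)
            return complex(-Pint_b.real / int_a)
        omega = 2.0 * np.pi * freq_hz * 1e-3
        jump = np.exp(-1j * omega * self.op.tau_ref)
        Ja, _ = _sweep(omega, self.dv, self.k_re, self.D, self.expG, self.wG,
                       zerosc, zerosc, 1.0, jump, self.op.tau_ref)
        Jb, _ = _sweep(omega, self.dv, self.k_re, self.D, self.expG, self.wG,
                       Emod, s, 0.0, 0.0, self.op.tau_ref)
        return -Jb / Ja


def steady_rate(op: CellOperatingPoint, grid: SolverGrid = SolverGrid()) -> float:
    """Stationary firing rate in 1/ms."""
    return ThresholdIntegrator(op, grid).nu0


def susceptibility(op: CellOperatingPoint, freqs_hz, which: str,
                   grid: SolverGrid = SolverGrid()) -> np.ndarray:
    ti = ThresholdIntegrator(op, grid)
    return np.array([ti.susceptibility(f, which) for f in np.atleast_1d(freqs_hz)])


def unperturbed_power_spectrum(op: CellOperatingPoint, freqs_hz,
                               grid: SolverGrid = SolverGrid()) -> np.ndarray:
    return ThresholdIntegrator(op, grid).power_spectrum(np.atleast_1d(freqs_hz))


def default_frequency_grid(n_log: int = 64, f_min: float = 0.1,
                           f_max: float = 1000.0) -> np.ndarray:
    """Solver frequency grid in Hz: 0 plus a logarithmic sweep."""
    return np.concatenate([[0.0], np.geomspace(f_min, f_max, n_log)])


def compute_spectral_set(op: CellOperatingPoint, freqs_hz=None,
                         grid: SolverGrid = SolverGrid(),
                         kinds=SUSCEPTIBILITY_KINDS) -> SpectralSet:
    """Solve every baseline quantity for one cell on one frequency grid."""
    if freqs_hz is None:
        freqs_hz = default_frequency_grid()
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    ti = ThresholdIntegrator(op, grid)
    C0 = ti.power_spectrum(freqs_hz)
    A = {k: np.array([ti.susceptibility(f, k) for f in freqs_hz])
         for k in kinds}
    return SpectralSet(freqs=freqs_hz, nu0=ti.nu0, C0=C0, A=A)
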