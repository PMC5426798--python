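"""Diffusion approximation of synaptic input and the network rate fixed point.

A presynaptic Poisson spike train of rate ``nu`` (1/ms) entering a
second-order alpha synapse with jump size ``alpha_hat`` produces a
conductance with

    mean     = alpha_hat * nu * tau_r
    variance = (1/2) * alpha_hat**2 * nu * tau_r * tau_r / (tau_r + tau_d)

(Campbell's theorem applied to the double-exponential kernel).  Treating the
fluctuating part of each conductance as white noise maps the
conductance-based neuron onto an effective current-based neuron with

    g0      = 1 + <gE> + <gI>
    mu      = (<gE> E_E + <gI> E_I) / g0          (rest and drive at 0)
    tau_eff = tau_m / g0
    sigma_eff^2 = [sE2 (mu-E_E)^2 + sI2 (mu-E_I)^2 + sigma^2 tau_m]/(g0 tau_m)

The network steady state is the fixed point nu_i = f_i(nu) where f_i is the
stationary rate of cell i given the conductance moments generated by its
actual presynaptic partners (per-edge bookkeeping, not mean field).  The
fixed point is found by damped Picard iteration seeded from the uncoupled
rates.  All rates are carried in 1/ms internally; Hz only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import EXC, INH, SYNAPSE, Network
from .richardson import (CellOperatingPoint, SolverGrid, ThresholdIntegrator)

__all__ = ["conductance_moments", "EffectiveParams", "effective_params",
           "input_rates", "operating_points", "RateVector",
           "self_consistent_rates", "uncoupled_rates"]


def conductance_moments(rate, alpha_hat, tau_r, tau_d):
    """(mean, variance) of the conductance for Poisson input at ``rate``
    (1/ms).  Both are linear in the rate."""
    rate = np.asarray(rate, dtype=float)
    mean = alpha_hat * rate * tau_r
    var = 0.5 * alpha_hat ** 2 * rate * tau_r * tau_r / (tau_r + tau_d)
    return mean, var


@dataclass(frozen=True)
class EffectiveParams:
    """Effective current-based description of one conductance-driven cell."""

    g0: float
    mu: float
    tau_eff: float
    sigma_eff: float
    gE_mean: float
    gI_mean: float
    sigmaE: float
    sigmaI: float


def effective_params(gE_mean, gI_mean, sigmaE, sigmaI, sigma, theta=1.0,
                     tau_m=None) -> EffectiveParams:
    """Map conductance moments to the effective (g0, mu, tau_eff, sigma_eff)."""
    from .network import TAU_M
    tau_m = TAU_M if tau_m is None else tau_m
    E_Erev = SYNAPSE[EXC].reversal
    E_Irev = SYNAPSE[INH].reversal
    g0 = 1.0 + gE_mean + gI_mean
    mu = (gE_mean * E_Erev + gI_mean * E_Irev) / g0
    tau_eff = tau_m / g0
    s2 = (sigmaE ** 2 * (mu - E_Erev) ** 2 + sigmaI ** 2 * (mu - E_Irev) ** 2
          + sigma ** 2 * tau_m) / (g0 * tau_m)
    return EffectiveParams(g0=g0, mu=mu, tau_eff=tau_eff,
                           sigma_eff=float(np.sqrt(s2)), gE_mean=gE_mean,
                           gI_mean=gI_mean, sigmaE=sigmaE, sigmaI=sigmaI)


def effective_operating_point(p: EffectiveParams, theta: float,
                              tau_m=None, tau_ref=None) -> "CellOperatingPoint":
    """Pose the effective scalar (current-based) equation as a solver problem.

    Cross-check mode: the multiplicative-noise terms are replaced by a
    constant diffusion with the effective variance, i.e. an
    Ornstein-Uhlenbeck drift -g0 (v - mu)/tau_m with
    D = sigma_eff^2 g0 / (2 tau_m).  The drift is reproduced by keeping the
    original mean conductances and the diffusion by a rescaled background
    noise sigma_eff sqrt(g0).
    """
    from .network import TAU_M, TAU_REF
    return CellOperatingPoint(
        gE_mean=p.gE_mean, gI_mean=p.gI_mean, sE2=0.0, sI2=0.0,
        sigma=p.sigma_eff * np.sqrt(p.g0), theta=theta,
        tau_m=TAU_M if tau_m is None else tau_m,
        tau_ref=TAU_REF if tau_ref is None else tau_ref)


def input_rates(network: Network, nu: np.ndarray):
    """Total presynaptic rate (1/ms) of each type arriving at each cell,
    summed over that cell's actual presynaptic partners."""
    A = network.adjacency.astype(float)
    is_E = network.cell_type == EXC
    nuE_in = A[:, is_E] @ nu[is_E]
    nuI_in = A[:, ~is_E] @ nu[~is_E]
    return nuE_in, nuI_in


def operating_points(network: Network, nu: np.ndarray):
    """Per-cell conductance moments given the presynaptic rate vector.

    Returns arrays (gE_mean, gI_mean, sE2, sI2) of length n_cells.
    """
    nuE_in, nuI_in = input_rates(network, nu)
    scale = network.edge_amplitude_scale()
    ct = network.cell_type
    ampE = scale[ct, EXC]
    ampI = scale[ct, INH]
    gE, sE2 = conductance_moments(nuE_in, ampE, SYNAPSE[EXC].tau_r,
                                  SYNAPSE[EXC].tau_d)
    gI, sI2 = conductance_moments(nuI_in, ampI, SYNAPSE[INH].tau_r,
                                  SYNAPSE[INH].tau_d)
    return gE, gI, sE2, sI2


def cell_operating_point(network: Network, i: int, gE, gI, sE2, sI2
                         ) -> CellOperatingPoint:
    return CellOperatingPoint(gE_mean=float(gE[i]), gI_mean=float(gI[i]),
                              sE2=float(sE2[i]), sI2=float(sI2[i]),
                              sigma=float(network.sigma[i]),
                              theta=float(network.theta[i]),
                              tau_m=network.config.tau_m,
                              tau_ref=network.config.tau_ref)


def _rate_map(network: Network, nu: np.ndarray, grid: SolverGrid) -> np.ndarray:
    gE, gI, sE2, sI2 = operating_points(network, nu)
    out = np.empty(network.n_cells)
    for i in range(network.n_cells):
        op = cell_operating_point(network, i, gE, gI, sE2, sI2)
        out[i] = ThresholdIntegrator(op, grid).nu0
    return out


def uncoupled_rates(network: Network, grid: SolverGrid = SolverGrid()) -> np.ndarray:
    """Stationary rates (1/ms) with all synapses silenced (noise only)."""
    return _rate_map(network, np.zeros(network.n_cells), grid)


@dataclass
class RateVector:
    """Self-consistent rates (1/ms) and the fixed-point residual history."""

    nu: np.ndarray
    residual: float
    residual_history: np.ndarray
    n_iter: int

    @property
    def hz(self) -> np.ndarray:
        return self.nu * 1e3


def self_consistent_rates(network: Network, grid: SolverGrid = SolverGrid(),
                          damping: float = 0.5, tol: float = 1e-6,
                          max_iter: int = 500, nu0=None) -> RateVector:
    """Damped Picard iteration nu <- (1-gamma) nu + gamma f(nu).

    ``tol`` is relative (infinity norm of the update over the norm of nu).
    Raises RuntimeError carrying the residual trajectory on non-convergence.
    """
    if not network.adjacency.any():
        nu = _rate_map(network, np.zeros(network.n_cells), grid)
        return RateVector(nu=nu, residual=0.0,
                          residual_history=np.zeros(1), n_iter=1)
    nu = uncoupled_rates(network, grid) if nu0 is None else np.asarray(nu0, float)
    hist = []
    for it in range(max_iter):
        f = _rate_map(network, nu, grid)
        res = np.max(np.abs(f - nu)) / max(np.max(np.abs(nu)), 1e-12)
        hist.append(res)
        nu = (1.0 - damping) * nu + damping * f
        if res < tol:
            return RateVector(nu=nu, residual=res,
                              residual_history=np.array(hist), n_iter=it + 1)
    raise RuntimeError(
        f"rate fixed point did not converge in {max_iter} iterations "
        f"(final residual {hist[-1]:.3g}); residual history attached",
        np.array(hist))
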