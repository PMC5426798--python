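"""Correlation susceptibility: how correlation transfer depends on rate.

With inhibitory common input the dominant source of E-E correlation, the
long-window correlation of a pair approximately factorizes into single-cell
terms, motivating the pair susceptibility

    S_ij = A_i(0) A_j(0) / sqrt(C_ii(0) C_jj(0))

(A the zero-frequency susceptibility to mean inhibitory conductance or to
the effective current) and, under the Poisson-variance assumption
C_ii(0) = nu_i, the single-cell susceptibility S_i = A_<gI>,i(0) / nu_i.

The stationary rate is a function of six parameters,
nu = f(<gI>, sigma_I, <gE>, sigma_E, sigma, theta).  To see how S depends on
where a cell sits in this parameter space, nuisance parameters are
successively frozen at population averages (taken over excitatory cells,
the population whose pairs are analyzed):

    full              S from each cell's own operating point
    averaged_nuisance sigma_I, <gE>, sigma_E, sigma at population means
    averaged_gI       additionally <gI> at its mean (theta free)
    fixed_theta       theta = 1, sweeping <gI> — the path a network would
                      follow if rate diversity came from inhibition instead
                      of excitability

plus a two-parameter rate/susceptibility surface over (<gI>, theta).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .network import EXC, Network
from .richardson import CellOperatingPoint, SolverGrid, ThresholdIntegrator
from .diffusion import operating_points, cell_operating_point

__all__ = ["pair_susceptibility", "single_cell_susceptibility",
           "SusceptibilityTable", "network_susceptibility_table",
           "rate_surface", "common_input_grouping"]


def pair_susceptibility(A0_i, A0_j, C_ii0, C_jj0) -> float:
    """S_ij from zero-frequency susceptibilities and autospectra."""
    if C_ii0 <= 0 or C_jj0 <= 0:
        raise ValueError("autospectra must be positive")
    return float(A0_i * A0_j / np.sqrt(C_ii0 * C_jj0))


def _cell_solution(op: CellOperatingPoint, grid: SolverGrid):
    ti = ThresholdIntegrator(op, grid)
    nu = ti.nu0
    A0 = ti.susceptibility(0.0, "gI_mean").real
    return nu, A0


def single_cell_susceptibility(op: CellOperatingPoint,
                               grid: SolverGrid = SolverGrid()) -> float:
    """S = A_<gI>(0)/nu at one operating point; NaN when the rate vanishes."""
    nu, A0 = _cell_solution(op, grid)
    if nu <= 0:
        return float("nan")
    return A0 / nu


class SusceptibilityTable(dict):
    """Maps variant name -> array over cells (rates in 1/ms, S in ms)."""


def network_susceptibility_table(network: Network, rates: np.ndarray,
                                 grid: SolverGrid = SolverGrid(),
                                 variants=("full", "averaged_nuisance",
                                           "averaged_gI")) -> SusceptibilityTable:
    """Evaluate the susceptibility variants for every excitatory cell.

    ``rates`` is the self-consistent rate vector (1/ms).  Population
    averages are over excitatory cells.
    """
    gE, gI, sE2, sI2 = operating_points(network, rates)
    exc = network.exc
    means = {
        "gE_mean": float(gE[exc].mean()),
        "gI_mean": float(gI[exc].mean()),
        "sE2": float(sE2[exc].mean()),
        "sI2": float(sI2[exc].mean()),
        "sigma": float(network.sigma[exc].mean()),
    }
    out = SusceptibilityTable()
    out["cells"] = exc
    out["pop_means"] = means
    for variant in variants:
        nus = np.empty(exc.size)
        Ss = np.empty(exc.size)
        for k, i in enumerate(exc):
            op = cell_operating_point(network, i, gE, gI, sE2, sI2)
            if variant in ("averaged_nuisance", "averaged_gI"):
                op = replace(op, sE2=means["sE2"], sI2=means["sI2"],
                             gE_mean=means["gE_mean"], sigma=means["sigma"])
            if variant == "averaged_gI":
                op = replace(op, gI_mean=means["gI_mean"])
            nu, A0 = _cell_solution(op, grid)
            nus[k] = nu
            Ss[k] = A0 / nu if nu > 0 else np.nan
        out[variant] = {"nu": nus, "S": Ss}
    return out


def fixed_theta_sweep(network: Network, rates: np.ndarray, gI_values,
                      theta: float = 1.0, grid: SolverGrid = SolverGrid()):
    """S(<gI>) along the theta-fixed path, other parameters at population
    means; returns (nu array, S array) over ``gI_values``."""
    tab = network_susceptibility_table(network, rates, grid, variants=())
    means = tab["pop_means"]
    nus = np.empty(len(gI_values))
    Ss = np.empty(len(gI_values))
    for k, g in enumerate(gI_values):
        op = CellOperatingPoint(gE_mean=means["gE_mean"], gI_mean=float(g),
                                sE2=means["sE2"], sI2=means["sI2"],
                                sigma=means["sigma"], theta=theta,
                                tau_m=network.config.tau_m,
                                tau_ref=network.config.tau_ref)
        nu, A0 = _cell_solution(op, grid)
        nus[k] = nu
        Ss[k] = A0 / nu if nu > 0 else np.nan
    return nus, Ss


def rate_surface(network: Network, rates: np.ndarray, gI_grid, theta_grid,
                 grid: SolverGrid = SolverGrid()):
    """Rate F(<gI>, theta) and susceptibility S-hat on a parameter grid,
    nuisance parameters at population means.  Returns (F, S) arrays of shape
    (len(gI_grid), len(theta_grid))."""
    tab = network_susceptibility_table(network, rates, grid, variants=())
    means = tab["pop_means"]
    F = np.empty((len(gI_grid), len(theta_grid)))
    S = np.empty_like(F)
    for a, g in enumerate(gI_grid):
        for b, th in enumerate(theta_grid):
            op = CellOperatingPoint(gE_mean=means["gE_mean"], gI_mean=float(g),
                                    sE2=means["sE2"], sI2=means["sI2"],
                                    sigma=means["sigma"], theta=float(th),
                                    tau_m=network.config.tau_m,
                                    tau_ref=network.config.tau_ref)
            nu, A0 = _cell_solution(op, grid)
            F[a, b] = nu
            S[a, b] = A0 / nu if nu > 0 else np.nan
    return F, S


def common_input_grouping(network: Network, rates=None, motif_I_common=None,
                          total=None):
    """Shared-inhibitory-input table over distinct E-E pairs.

    For each pair, counts shared presynaptic I cells, converts to the
    common-input fraction c = shared / N_EI, and attaches the pair's
    I-common motif contribution (and total correlation) when provided.
    """
    import pandas as pd

    A = network.adjacency.astype(np.int64)
    exc = network.exc
    inh = network.inh
    n_EI = network.config.n_in[EXC, 1]
    Ai = A[np.ix_(exc, inh)]
    shared = Ai @ Ai.T
    ii, jj = np.triu_indices(exc.size, k=1)
    data = {
        "i": exc[ii],
        "j": exc[jj],
        "n_shared_I": shared[ii, jj],
        "c": shared[ii, jj] / n_EI if n_EI else np.zeros(ii.size),
    }
    if rates is not None:
        r = np.asarray(rates, dtype=float)
        data["geom_rate"] = np.sqrt(r[exc[ii]] * r[exc[jj]])
    if motif_I_common is not None:
        data["rho_I_common"] = np.real(motif_I_common)[exc[ii], exc[jj]]
    if total is not None:
        data["rho_total"] = np.real(total)[exc[ii], exc[jj]]
    return pd.DataFrame(data)
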