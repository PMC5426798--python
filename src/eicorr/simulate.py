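"""Monte-Carlo simulation of the conductance-based LIF network.

The membrane equation for cell i is

    tau_m dv_i/dt = -v_i - g_E,i (v_i - E_E) - g_I,i (v_i - E_I)
                    + sigma_i sqrt(tau_m) xi_i(t)

with independent white background noise xi_i, integrated by Euler-Maruyama at
a step much smaller than every time scale in the system (default 0.01 ms).
Each conductance follows a second-order alpha filter (rise tau_r, decay
tau_d); a presynaptic spike makes the auxiliary variable g^(1) of every
postsynaptic target jump by that edge's effective pulse size (the delta in
the synaptic equation integrates to exactly that jump, independent of dt).
On threshold crossing, a spike is recorded at the end of the step, the
voltage is clamped at reset (0) for the refractory period while conductances
keep evolving, and integration resumes.

Spike counts are retained in 1 ms bins; every larger counting window is
obtained by summing bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import EXC, INH, SYNAPSE, Network

__all__ = ["SimConfig", "SpikeCounts", "simulate", "spike_count_stats",
           "PairStats", "population_power_spectrum", "save_counts",
           "load_counts"]


@dataclass
class SimConfig:
    """Integration and counting settings.

    ``duration`` is the usable (post-equilibration) time per realization in
    ms; ``equilibration`` is simulated and discarded at the start of each
    realization.  ``bin_width`` must be an integer multiple of ``dt``.
    """

    dt: float = 0.01
    duration: float = 1000.0
    n_realizations: int = 1
    equilibration: float = 1000.0
    bin_width: float = 1.0
    seed: int | None = None

    def validate(self, network: Network) -> None:
        min_tau_r = min(SYNAPSE[EXC].tau_r, SYNAPSE[INH].tau_r)
        if self.dt > 0.01 * min_tau_r * (1 + 1e-12):
            import warnings
            warnings.warn("dt exceeds 1% of the fastest synaptic rise time; "
                          "integration error may be non-negligible")
        nb = self.bin_width / self.dt
        if abs(nb - round(nb)) > 1e-9:
            raise ValueError("bin_width must be an integer multiple of dt")
        if self.duration <= 0 or self.n_realizations < 1:
            raise ValueError("invalid duration / realization count")


@dataclass
class SpikeCounts:
    """Binned spike counts, shape (realization, cell, bin)."""

    counts: np.ndarray
    bin_width: float
    cell_type: np.ndarray

    @property
    def n_realizations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.counts.shape[2] * self.bin_width

    @property
    def rates(self) -> np.ndarray:
        """Per-cell mean firing rate in Hz."""
        total = self.counts.sum(axis=(0, 2))
        return total / (self.n_realizations * self.duration) * 1e3

    def rebin(self, T: float) -> np.ndarray:
        """Counts in windows of length T ms, shape (realization, cell, window)."""
        k = T / self.bin_width
        if abs(k - round(k)) > 1e-9:
            raise ValueError("T must be an integer multiple of the bin width")
        k = int(round(k))
        n_win = self.counts.shape[2] // k
        c = self.counts[:, :, :n_win * k]
        return c.reshape(c.shape[0], c.shape[1], n_win, k).sum(axis=3)


@njit(cache=True)
def _run_chunk(v, g1E, gE, g1I, gI, refr, theta, sigma_amp, is_exc,
               indptr, targets, amps, xi_buf, n_steps, dt, tau_m, n_ref_steps,
               bin_steps, counts, E_E, E_I, tr_E, td_E, tr_I, td_I):
    """Euler-Maruyama integration of one chunk; counts[cell, bin] (in-place).

    State arrays are updated in place so successive chunks continue the same
    trajectory.  ``sigma_amp`` is sigma_i*sqrt(dt/tau_m); ``amps`` holds the
    per-edge conductance jumps in CSR-by-source layout; ``xi_buf`` is a flat
    buffer of n_steps*n unit normals generated by the caller.
    """
    n = v.shape[0]
    cdE = dt / td_E
    crE = dt / tr_E
    cdI = dt / td_I
    crI = dt / tr_I
    inv_tau = dt / tau_m
    for step in range(n_steps):
        b = step // bin_steps
        xi = xi_buf[step * n:(step + 1) * n]
        for i in range(n):
            # synaptic filters evolve for every cell, refractory or not
            g1e = g1E[i]
            g1i = g1I[i]
            ge = gE[i] + cdE * (g1e - gE[i])
            gi = gI[i] + cdI * (g1i - gI[i])
            gE[i] = ge
            gI[i] = gi
            g1E[i] = g1e - crE * g1e
            g1I[i] = g1i - crI * g1i
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = 0.0
                continue
            vi = v[i]
            vi = vi + inv_tau * (-vi - ge * (vi - E_E) - gi * (vi - E_I)) \
                + sigma_amp[i] * xi[i]
            if vi >= theta[i]:
                counts[i, b] += 1
                refr[i] = n_ref_steps
                vi = 0.0
                for e in range(indptr[i], indptr[i + 1]):
                    m = targets[e]
                    if is_exc[i]:
                        g1E[m] += amps[e]
                    else:
                        g1I[m] += amps[e]
            v[i] = vi
    return counts


def _csr_by_source(network: Network):
    amp = network.edge_amplitudes()
    A = network.adjacency
    n = network.n_cells
    indptr = np.zeros(n + 1, dtype=np.int64)
    tgt_lists = []
    amp_lists = []
    for j in range(n):
        t = np.flatnonzero(A[:, j])
        tgt_lists.append(t)
        amp_lists.append(amp[t, j])
        indptr[j + 1] = indptr[j] + t.size
    targets = np.concatenate(tgt_lists) if tgt_lists else np.empty(0, np.int64)
    amps = np.concatenate(amp_lists) if amp_lists else np.empty(0)
    return indptr, targets.astype(np.int64), amps.astype(np.float64)


def simulate(network: Network, sim: SimConfig, initial_v=None) -> SpikeCounts:
    """Run the network and return binned spike counts.

    Realizations are statistically independent: each starts from rest with a
    fresh noise stream (seeded from ``sim.seed``) and discards its own
    equilibration transient.  Voltage overflow aborts with a diagnostic.
    """
    sim.validate(network)
    cfg = network.config
    n = network.n_cells
    indptr, targets, amps = _csr_by_source(network)
    dt = sim.dt
    bin_steps = int(round(sim.bin_width / dt))
    n_bins = int(round(sim.duration / sim.bin_width))
    eq_steps = int(round(sim.equilibration / dt))
    n_ref_steps = int(np.ceil(cfg.tau_ref / dt))
    sigma_amp = network.sigma * np.sqrt(dt / cfg.tau_m)
    is_exc = (network.cell_type == EXC)
    syn_args = (SYNAPSE[EXC].reversal, SYNAPSE[INH].reversal,
                SYNAPSE[EXC].tau_r, SYNAPSE[EXC].tau_d,
                SYNAPSE[INH].tau_r, SYNAPSE[INH].tau_d)
    ss = np.random.SeedSequence(sim.seed)
    children = ss.spawn(sim.n_realizations)
    all_counts = np.zeros((sim.n_realizations, n, n_bins), dtype=np.int8)
    # chunk long realizations so noise buffers and count arrays stay small
    chunk_bins = min(n_bins, max(1, int(round(500 / sim.bin_width))))
    for r in range(sim.n_realizations):
        rng = np.random.default_rng(children[r])
        v = np.zeros(n) if initial_v is None else initial_v.astype(float).copy()
        g1E = np.zeros(n); gEc = np.zeros(n)
        g1I = np.zeros(n); gIc = np.zeros(n)
        refr = np.zeros(n, dtype=np.int64)
        if eq_steps:
            scratch = np.zeros((n, max(1, eq_steps // bin_steps + 1)), dtype=np.int32)
            done_eq = 0
            while done_eq < eq_steps:
                ns = min(eq_steps - done_eq, chunk_bins * bin_steps)
                xi = rng.standard_normal(ns * n)
                _run_chunk(v, g1E, gEc, g1I, gIc, refr, network.theta,
                           sigma_amp, is_exc, indptr, targets, amps, xi, ns,
                           dt, cfg.tau_m, n_ref_steps, bin_steps, scratch,
                           *syn_args)
                done_eq += ns
        done = 0
        while done < n_bins:
            nb = min(chunk_bins, n_bins - done)
            cchunk = np.zeros((n, nb), dtype=np.int32)
            xi = rng.standard_normal(nb * bin_steps * n)
            _run_chunk(v, g1E, gEc, g1I, gIc, refr, network.theta, sigma_amp,
                       is_exc, indptr, targets, amps, xi, nb * bin_steps, dt,
                       cfg.tau_m, n_ref_steps, bin_steps, cchunk, *syn_args)
            all_counts[r, :, done:done + nb] = cchunk
            done += nb
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("voltage diverged (NaN/overflow); "
                                     "reduce dt or check parameters")
    return SpikeCounts(counts=all_counts, bin_width=sim.bin_width,
                       cell_type=network.cell_type.copy())


@dataclass
class PairStats:
    """Windowed count statistics: per-cell rate/Fano and pairwise Pearson
    correlations at window length T.  Undefined correlations (a zero-variance
    cell) are NaN, never silently zero."""

    T: float
    rates: np.ndarray
    fano: np.ndarray
    corr: np.ndarray
    cov: np.ndarray


def spike_count_stats(counts: SpikeCounts, T: float) -> PairStats:
    """Rates, Fano factors and pairwise correlations at window length T (ms).

    Counts are re-binned to windows of length T within each realization; the
    moments pool windows across realizations.
    """
    win = counts.rebin(T)  # (real, cell, window)
    x = win.transpose(1, 0, 2).reshape(win.shape[1], -1).astype(np.float64)
    mean = x.mean(axis=1)
    cov = np.cov(x, ddof=1)
    var = np.diag(cov).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
        denom = np.sqrt(np.outer(var, var))
        corr = np.where(denom > 0, cov / denom, np.nan)
    np.fill_diagonal(corr, np.where(var > 0, 1.0, np.nan))
    rates = mean / T * 1e3
    return PairStats(T=T, rates=rates, fano=fano, corr=corr, cov=cov)


def population_power_spectrum(counts: SpikeCounts, cell_type: int = EXC,
                              nperseg_ms: float = 1024.0):
    """Averaged-periodogram (Welch) spectrum of the population-summed,
    mean-subtracted spike count, normalized to its maximum and expressed in
    dB/Hz.  Returns (frequencies in Hz, spectrum in dB)."""
    from scipy import signal

    sel = counts.cell_type == cell_type
    pop = counts.counts[:, sel, :].sum(axis=1).astype(np.float64)
    fs = 1e3 / counts.bin_width  # Hz
    nperseg = min(pop.shape[1], int(round(nperseg_ms / counts.bin_width)))
    if pop.shape[1] * counts.n_realizations * counts.bin_width < 1000.0:
        raise ValueError("need at least 1 s of data for a spectrum")
    f, p = signal.welch(pop - pop.mean(axis=1, keepdims=True), fs=fs,
                        nperseg=nperseg, axis=1, detrend=False)
    pxx = p.mean(axis=0)
    db = 10.0 * np.log10(pxx / pxx.max())
    return f, db


def save_counts(counts: SpikeCounts, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=counts.counts,
                         chunks=(1, counts.n_cells, min(65536, counts.counts.shape[2])),
                         compression="gzip", compression_opts=1)
        f.attrs["bin_width"] = counts.bin_width
        f.create_dataset("cell_type", data=counts.cell_type)


def load_counts(path) -> SpikeCounts:
    import h5py

    with h5py.File(path, "r") as f:
        return SpikeCounts(counts=f["counts"][...],
                           bin_width=float(f.attrs["bin_width"]),
                           cell_type=f["cell_type"][...])
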