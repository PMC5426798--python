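"""Monte-Carlo simulator and spike-count statistics."""

import numpy as np
import pytest

from eicorr import (make_network, SimConfig, simulate, spike_count_stats,
                    population_power_spectrum, CellOperatingPoint,
                    ThresholdIntegrator)
from eicorr.simulate import SpikeCounts


def quiet_network(sigma=1e-9, theta=None, n_E=4, n_I=2):
    net = make_network("asynchronous", heterogeneous=False, rng_seed=0,
                       n_E=n_E, n_I=n_I)
    net.adjacency[:] = 0
    net.sigma[:] = sigma
    if theta is not None:
        net.theta[:] = theta
    return net


def test_no_input_no_noise_no_spikes():
    net = quiet_network()
    c = simulate(net, SimConfig(duration=500.0, equilibration=50.0, seed=0))
    assert c.counts.sum() == 0


def test_same_seed_identical_spike_trains(asyn_net):
    sim = SimConfig(duration=2000.0, equilibration=100.0, seed=5)
    a = simulate(asyn_net, sim)
    b = simulate(asyn_net, sim)
    assert np.array_equal(a.counts, b.counts)
    c = simulate(asyn_net, SimConfig(duration=2000.0, equilibration=100.0,
                                     seed=6))
    assert not np.array_equal(a.counts, c.counts)


def test_refractory_rate_ceiling():
    # drive an uncoupled cell absurdly hard: rate must stay below 1/tau_ref
    net = quiet_network(sigma=3.0, theta=0.7)
    c = simulate(net, SimConfig(duration=5000.0, equilibration=100.0, seed=1))
    assert np.all(c.rates <= 1000.0 / net.config.tau_ref)
    assert c.rates.max() > 50.0  # actually firing hard


def test_single_cell_rate_matches_threshold_integration():
    """MC rate of an uncoupled noisy cell vs the boundary-value solver."""
    net = quiet_network(sigma=1.0, theta=1.0, n_E=16, n_I=0)
    c = simulate(net, SimConfig(duration=20000.0, equilibration=500.0, seed=2))
    mc = c.rates.mean()  # Hz, averaged over 16 iid cells
    op = CellOperatingPoint(0.0, 0.0, 0.0, 0.0, 1.0, 1.0)
    pred = ThresholdIntegrator(op).nu0 * 1e3
    n_spk = c.counts.sum()
    sem = pred / np.sqrt(n_spk)
    assert abs(mc - pred) < max(4 * sem, 0.02 * pred)


def test_rate_convergence_in_dt(asyn_net):
    a = simulate(asyn_net, SimConfig(dt=0.01, duration=20000.0,
                                     equilibration=500.0, seed=3))
    b = simulate(asyn_net, SimConfig(dt=0.005, duration=20000.0,
                                     equilibration=500.0, seed=4))
    ra = a.rates[asyn_net.exc].mean()
    rb = b.rates[asyn_net.exc].mean()
    assert abs(ra - rb) / rb < 0.05  # statistical + discretization error


class TestCountStatistics:
    def poisson_counts(self, rate_hz=10.0, n_cells=10, n_bins=100_000,
                       seed=0):
        rng = np.random.default_rng(seed)
        lam = rate_hz / 1000.0
        counts = rng.poisson(lam, size=(1, n_cells, n_bins)).astype(np.int8)
        return SpikeCounts(counts=counts, bin_width=1.0,
                           cell_type=np.zeros(n_cells, dtype=int))

    def test_self_correlation_is_one(self):
        st = spike_count_stats(self.poisson_counts(), 100.0)
        assert np.allclose(np.diag(st.corr), 1.0)

    def test_independent_poisson_fano_one_corr_zero(self):
        st = spike_count_stats(self.poisson_counts(), 100.0)
        n_win = 1000
        assert np.allclose(st.fano, 1.0, atol=5 * np.sqrt(2 / n_win))
        off = st.corr[np.triu_indices_from(st.corr, k=1)]
        assert np.all(np.abs(off) < 5 / np.sqrt(n_win))
        assert np.allclose(st.rates, 10.0, rtol=0.08)

    def test_zero_variance_cell_reported_missing(self):
        pc = self.poisson_counts(n_cells=3)
        pc.counts[:, 2, :] = 0
        st = spike_count_stats(pc, 100.0)
        assert np.isnan(st.corr[0, 2]) and np.isnan(st.corr[2, 2])
        assert np.isfinite(st.corr[0, 1])

    def test_window_must_divide(self):
        with pytest.raises(ValueError):
            spike_count_stats(self.poisson_counts(), 0.3)


class TestPopulationSpectrum:
    def test_flat_for_homogeneous_poisson(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.02, size=(4, 20, 60_000)).astype(np.int8)
        sc = SpikeCounts(counts, 1.0, np.zeros(20, dtype=int))
        f, db = population_power_spectrum(sc)
        band = db[(f > 1) & (f < 400)]
        assert band.max() - band.min() < 3.0  # dB, flat up to estimator noise

    def test_peak_at_injected_modulation_frequency(self):
        rng = np.random.default_rng(2)
        t = np.arange(120_000)
        lam = 0.02 * (1 + 0.6 * np.sin(2 * np.pi * 0.008 * t))  # 8 Hz
        counts = rng.poisson(lam, size=(1, 30, t.size)).astype(np.int8)
        sc = SpikeCounts(counts, 1.0, np.zeros(30, dtype=int))
        f, db = population_power_spectrum(sc, nperseg_ms=4096)
        sel = (f > 2) & (f < 50)
        assert abs(f[sel][np.argmax(db[sel])] - 8.0) < 1.0

    def test_insufficient_data_rejected(self):
        sc = SpikeCounts(np.zeros((1, 5, 100), dtype=np.int8), 1.0,
                         np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            population_power_spectrum(sc)


def test_counts_roundtrip_hdf5(tmp_path):
    rng = np.random.default_rng(0)
    sc = SpikeCounts(rng.poisson(0.01, (2, 6, 500)).astype(np.int8), 1.0,
                     np.zeros(6, dtype=int))
    from eicorr.simulate import save_counts, load_counts
    p = tmp_path / "c.h5"
    save_counts(sc, p)
    back = load_counts(p)
    assert np.array_equal(back.counts, sc.counts)
    assert back.bin_width == 1.0
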