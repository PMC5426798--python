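"""Connectivity, threshold sampling and network presets."""

import numpy as np
import pytest
from scipy import integrate, stats

from eicorr import (EXC, INH, NetworkConfig, build_connectivity,
                    sample_thresholds, make_network, save_network,
                    load_network)
from eicorr.network import SIGMA_CANDIDATES, REGIME_WEIGHTS


def test_fixed_in_degree_rows_exact():
    cfg = NetworkConfig()
    A = build_connectivity(cfg, rng_seed=0)
    ct = np.r_[np.zeros(80, int), np.ones(20, int)]
    n_in = cfg.n_in
    for i in range(100):
        row = A[i]
        assert row[i] == 0  # no autapses
        assert row[ct == EXC].sum() == n_in[ct[i], EXC]
        assert row[ct == INH].sum() == n_in[ct[i], INH]
    # every E row: 32 E + 7 I = 39 inputs, every I row: 16 + 8 = 24
    assert np.all(A[:80].sum(axis=1) == 39)
    assert np.all(A[80:].sum(axis=1) == 24)


def test_zero_in_degree_gives_empty_graph():
    cfg = NetworkConfig(conn_prob=np.zeros((2, 2)))
    A = build_connectivity(cfg, rng_seed=3)
    assert not A.any()


def test_erdos_renyi_mean_in_degree_binomial():
    # E->E in-degree is Binomial(n_E - 1, 0.4): mean 31.6
    cfg = NetworkConfig(topology="erdos_renyi")
    degs = []
    for seed in range(40):
        A = build_connectivity(cfg, seed)
        degs.append(A[:80, :80].sum(axis=1))
    degs = np.concatenate(degs)
    expected_mean = 79 * 0.4
    expected_sd = np.sqrt(79 * 0.4 * 0.6)
    assert abs(degs.mean() - expected_mean) < 4 * expected_sd / np.sqrt(degs.size)
    assert abs(degs.std() - expected_sd) / expected_sd < 0.1
    assert not np.any(np.diag(A))


def test_in_degree_exceeding_pool_is_configuration_error():
    cfg = NetworkConfig(n_E=10, n_I=2, conn_prob=np.array([[2.0, 0.3],
                                                           [0.2, 0.4]]))
    with pytest.raises(ValueError, match="exceeds"):
        build_connectivity(cfg, 0)


def test_connectivity_deterministic_in_seed():
    cfg = NetworkConfig()
    A1 = build_connectivity(cfg, 42)
    A2 = build_connectivity(cfg, 42)
    A3 = build_connectivity(cfg, 43)
    assert np.array_equal(A1, A2)
    assert not np.array_equal(A1, A3)


class TestThresholds:
    def test_degenerate_spread_gives_unit_thresholds(self):
        assert np.all(sample_thresholds(50, 0.0) == 1.0)

    def test_bounds_respected(self):
        th = sample_thresholds(20000, 0.2, rng_seed=1)
        assert th.min() >= 0.7 and th.max() <= 1.4

    def test_moments_match_quadrature(self):
        # oracle: numerical integration of the truncated lognormal moments
        s = 0.2
        mu = -0.5 * s ** 2
        a, b = (np.log(0.7) - mu) / s, (np.log(1.4) - mu) / s
        Z = stats.norm.cdf(b) - stats.norm.cdf(a)

        def moment(k):
            val, _ = integrate.quad(
                lambda x: np.exp(k * x) * stats.norm.pdf(x, mu, s) / Z,
                np.log(0.7), np.log(1.4))
            return val

        m1, m2 = moment(1), moment(2)
        th = sample_thresholds(100_000, s, rng_seed=5)
        assert abs(th.mean() - m1) < 5e-3
        assert abs(th.var() - (m2 - m1 ** 2)) < 5e-4
        # truncation shrinks the variance below the untruncated e^{s^2}-1
        assert th.var() < np.exp(s ** 2) - 1

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_thresholds(10, 0.2, bounds=(1.4, 0.7))

    def test_acceptance_rate_reported(self):
        th, acc = sample_thresholds(1000, 0.2, rng_seed=0,
                                    return_acceptance=True)
        assert 0 < acc <= 1
        assert th.size == 1000


class TestPresets:
    def test_asynchronous_weights(self):
        net = make_network("asynchronous", rng_seed=0)
        W = net.config.W  # indexed [target][source]
        assert W[EXC, INH] == 10 and W[INH, EXC] == 5
        assert W[EXC, EXC] == 0.5 and W[INH, INH] == 5

    def test_strong_asynchronous_raises_excitation(self):
        W = REGIME_WEIGHTS["strong_asynchronous"]
        assert W[INH, EXC] == 8 and W[EXC, EXC] == 9
        Wa = REGIME_WEIGHTS["asynchronous"]
        assert W[EXC, INH] == Wa[EXC, INH] and W[INH, INH] == Wa[INH, INH]

    def test_homogeneous_thresholds_are_unity(self):
        net = make_network("asynchronous", heterogeneous=False, rng_seed=0)
        assert np.all(net.theta == 1.0)

    def test_edge_amplitudes(self):
        net = make_network("asynchronous", rng_seed=0)
        amp = net.edge_amplitudes()
        # E->E edge: alpha_E * W_EE / N_EE = 1 * 0.5 / 32
        ee = amp[:80, :80][net.adjacency[:80, :80] == 1]
        assert np.allclose(ee, 0.5 / 32)
        # I->E edge: alpha_I * W_EI / N_EI = 2 * 10 / 7
        ei = amp[:80, 80:][net.adjacency[:80, 80:] == 1]
        assert np.allclose(ei, 2 * 10 / 7)
        assert np.all(amp[net.adjacency == 0] == 0)

    def test_sigma_candidates_documented_and_selectable(self):
        net = make_network("asynchronous", rng_seed=0, sigma_reading="literal")
        assert net.config.sigma_E == SIGMA_CANDIDATES["literal"]["asynchronous"][0]

    def test_same_seed_identical_network(self):
        a = make_network("asynchronous", rng_seed=9)
        b = make_network("asynchronous", rng_seed=9)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.theta, b.theta)


def test_roundtrip_serialization(tmp_path, asyn_net):
    p = tmp_path / "net.zip"
    save_network(asyn_net, p)
    back = load_network(p)
    assert np.array_equal(back.adjacency, asyn_net.adjacency)
    assert np.allclose(back.theta, asyn_net.theta)
    assert np.allclose(back.edge_amplitudes(), asyn_net.edge_amplitudes())
    assert back.config.regime == asyn_net.config.regime
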