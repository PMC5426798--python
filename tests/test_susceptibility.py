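"""Correlation susceptibility, parameter-averaged variants, common input."""

import numpy as np
import pytest

from eicorr import (make_network, pair_susceptibility,
                    network_susceptibility_table, fixed_theta_sweep,
                    rate_surface, common_input_grouping,
                    CellOperatingPoint, ThresholdIntegrator)
from eicorr.susceptibility import single_cell_susceptibility
from eicorr.diffusion import self_consistent_rates


@pytest.fixture(scope="module")
def asyn_rates(asyn_net):
    return self_consistent_rates(asyn_net).nu


def test_pair_susceptibility_self_pair_nonnegative():
    assert pair_susceptibility(-0.3, -0.3, 1.0, 1.0) >= 0
    with pytest.raises(ValueError):
        pair_susceptibility(1.0, 1.0, 0.0, 1.0)


def test_poisson_variance_assumption_factorizes():
    # under C_ii(0) = nu_i the pair value is exactly S_i * S_j
    A_i, A_j, nu_i, nu_j = -0.02, -0.05, 0.01, 0.02
    S = pair_susceptibility(A_i, A_j, nu_i, nu_j)
    assert S == pytest.approx((A_i / np.sqrt(nu_i)) * (A_j / np.sqrt(nu_j)))
    assert S == pytest.approx((A_i / nu_i) * (A_j / nu_j)
                              * np.sqrt(nu_i * nu_j))


def test_homogeneous_population_variants_coincide():
    net = make_network("asynchronous", heterogeneous=False, rng_seed=1)
    rates = self_consistent_rates(net).nu
    tab = network_susceptibility_table(net, rates)
    # fixed in-degree + identical thresholds: all E cells share an operating
    # point, so averaging nuisance parameters changes nothing
    for variant in ("full", "averaged_nuisance", "averaged_gI"):
        assert np.allclose(tab[variant]["S"], tab["full"]["S"], rtol=1e-10)
        assert np.ptp(tab[variant]["nu"]) / tab[variant]["nu"].mean() < 1e-9


def test_susceptibility_negative_in_network(asyn_net, asyn_rates):
    tab = network_susceptibility_table(asyn_net, asyn_rates,
                                       variants=("full",))
    assert np.all(tab["full"]["S"] < 0)


def test_averaged_gI_variant_correlation_decreasing_at_high_rate(
        asyn_net, asyn_rates):
    """Along the threshold path of the asynchronous regime, the implied
    equal-pair correlation susceptibility S(nu)^2 nu falls with rate above
    ~5 Hz: correlations decrease with firing rate there."""
    tab = network_susceptibility_table(asyn_net, asyn_rates,
                                       variants=("averaged_gI",))
    nu = tab["averaged_gI"]["nu"]
    S = tab["averaged_gI"]["S"]
    pair = S ** 2 * nu  # S_i S_j sqrt(nu_i nu_j) for an equal pair
    nu_hz = nu * 1e3
    sel = nu_hz > 5.0
    order = np.argsort(nu_hz[sel])
    p = pair[sel][order]
    k = max(1, p.size // 3)
    assert p[-k:].mean() < p[:k].mean()


def test_fixed_theta_sweep_correlation_increasing_at_low_rate(asyn_net,
                                                              asyn_rates):
    """Along the theta=1 path (rate diversity from inhibition instead of
    excitability), S(nu)^2 nu grows with rate below ~15 Hz: the alternative
    mechanism reverses the correlation-rate trend."""
    gI = np.linspace(0.8, 4.0, 14)
    nu, S = fixed_theta_sweep(asyn_net, asyn_rates, gI)
    pair = S ** 2 * nu
    nu_hz = nu * 1e3
    sel = (nu_hz > 1.0) & (nu_hz < 14.0)
    order = np.argsort(nu_hz[sel])
    p = pair[sel][order]
    assert np.all(np.diff(p) > 0)


def test_rate_surface_monotonicity_and_consistency(asyn_net, asyn_rates):
    gI = np.linspace(1.2, 2.4, 4)
    th = np.linspace(0.8, 1.3, 4)
    F, S = rate_surface(asyn_net, asyn_rates, gI, th)
    # rate falls with more inhibition at fixed threshold ...
    assert np.all(np.diff(F, axis=0) < 0)
    # ... and with higher threshold at fixed inhibition
    assert np.all(np.diff(F, axis=1) < 0)
    # grid point equals a direct per-cell evaluation
    tab = network_susceptibility_table(asyn_net, asyn_rates, variants=())
    m = tab["pop_means"]
    op = CellOperatingPoint(gE_mean=m["gE_mean"], gI_mean=gI[1],
                            sE2=m["sE2"], sI2=m["sI2"], sigma=m["sigma"],
                            theta=th[2])
    assert F[1, 2] == pytest.approx(ThresholdIntegrator(op).nu0, rel=1e-9)
    assert S[1, 2] == pytest.approx(single_cell_susceptibility(op), rel=1e-9)


class TestCommonInput:
    def test_disjoint_input_sets_group_zero(self, asyn_net):
        tab = common_input_grouping(asyn_net)
        row = tab[tab.n_shared_I == 0]
        assert (row.c == 0).all()

    def test_shared_count_matches_hypergeometric_expectation(self):
        # N_EI = 7 draws from n_I = 20, two cells independently:
        # E[shared] = 7^2/20 = 2.45
        counts = []
        for seed in range(25):
            net = make_network("asynchronous", rng_seed=seed)
            counts.append(common_input_grouping(net).n_shared_I.mean())
        mean = np.mean(counts)
        assert abs(mean - 49 / 20) < 0.05

    def test_two_shared_inputs_fraction(self, asyn_net):
        tab = common_input_grouping(asyn_net)
        two = tab[tab.n_shared_I == 2]
        assert np.allclose(two.c, 2 / 7)  # ~0.28

    def test_grouping_monotone_in_icommon_contribution(self, asyn_lr,
                                                       asyn_net):
        from eicorr import second_order_by_motif, normalize_contribution
        K = asyn_lr.interaction(0.0)
        C = asyn_lr.zero_frequency()
        C0 = asyn_lr.baseline_spectrum(0.0)
        mot = second_order_by_motif(K, C0, asyn_net.cell_type)
        Ric = normalize_contribution(mot["I_common"], C)
        tab = common_input_grouping(asyn_net, rates=asyn_lr.rates,
                                    motif_I_common=Ric)
        means = tab.groupby("n_shared_I").rho_I_common.mean()
        assert np.all(np.diff(means.values) > 0)
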