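"""Path-order decomposition and motif statistics."""

import numpy as np
import pandas as pd
import pytest

from eicorr import (order_contribution, cumulative_orders,
                    normalize_contribution, second_order_by_motif,
                    motif_regression_stats, pair_table, make_network)
from eicorr.motifs import spectral_radius


def random_system(n=30, rho_target=0.5, seed=0, frac_inh=0.3):
    rng = np.random.default_rng(seed)
    K = rng.normal(size=(n, n)) / np.sqrt(n)
    np.fill_diagonal(K, 0.0)
    K *= rho_target / spectral_radius(K)
    C0 = rng.uniform(0.5, 2.0, n)
    ct = (rng.random(n) < frac_inh).astype(int)
    return K, C0, ct


def test_order_zero_is_baseline():
    K, C0, _ = random_system()
    assert np.allclose(order_contribution(K, C0, 0), np.diag(C0))


def test_divergent_series_rejected():
    K, C0, _ = random_system(rho_target=1.2)
    with pytest.raises(ValueError, match="diverges"):
        order_contribution(K, C0, 2)


def test_series_converges_geometrically_to_full_inverse():
    """Truncation error of sum P^k is bounded by c rho(K)^(n+1) and matches
    the exact matrix-inverse expression (the independent oracle)."""
    K, C0, _ = random_system(rho_target=0.6, seed=4)
    B = np.linalg.inv(np.eye(K.shape[0]) - K)
    C_full = (B * C0[None, :]) @ B.conj().T
    Ps = cumulative_orders(K, C0, 40)
    rho = spectral_radius(K)
    errs = []
    for n in (10, 20, 30, 40):
        err = np.abs(sum(Ps[:n + 1]) - C_full).max()
        errs.append(err)
    # geometric decay with ratio about rho^10 per 10 orders
    ratios = np.array(errs[1:]) / np.array(errs[:-1])
    assert np.all(ratios < rho ** 10 * 5)
    assert errs[-1] < 1e-6


def test_cumulative_recursion_matches_direct_sum():
    K, C0, _ = random_system(seed=7)
    Ps = cumulative_orders(K, C0, 4)
    for n in range(5):
        assert np.allclose(Ps[n], order_contribution(K, C0, n), atol=1e-12)


def test_normalization_identity_and_errors():
    K, C0, _ = random_system(seed=1)
    Lam = np.diag(np.linspace(1.0, 2.0, K.shape[0]))
    R = normalize_contribution(Lam, Lam)
    assert np.allclose(R, np.eye(K.shape[0]))
    with pytest.raises(ValueError):
        normalize_contribution(Lam, -Lam)


def test_normalized_orders_sum_to_correlation(asyn_lr):
    """Sum of R^k at zero frequency equals the long-window correlation
    matrix (direct normalized-inverse oracle) to 1e-6."""
    K = asyn_lr.interaction(0.0)
    C = asyn_lr.zero_frequency()
    C0 = asyn_lr.baseline_spectrum(0.0)
    Ps = cumulative_orders(K, C0, 60)
    total = sum(normalize_contribution(P, C) for P in Ps)
    rho_inf = normalize_contribution(C, C)
    assert np.abs(total - rho_inf).max() < 1e-6


def test_second_order_partition_exact():
    K, C0, ct = random_system(seed=3)
    parts = second_order_by_motif(K, C0, ct)
    P2 = order_contribution(K, C0, 2)
    total = sum(parts.values())
    assert np.allclose(total, P2, atol=1e-12)


def test_no_inhibitory_paths_no_inhibitory_motifs(asyn_net):
    net = make_network("asynchronous", rng_seed=2)
    K = np.random.default_rng(0).normal(size=(net.n_cells,) * 2) * 0.01
    K[:, net.inh] = 0.0  # silence all paths through I cells
    C0 = np.ones(net.n_cells)
    parts = second_order_by_motif(K, C0, net.cell_type)
    assert np.allclose(parts["I_common"], 0.0)
    ee = np.ix_(net.exc, net.exc)
    assert np.allclose(parts["I_chain"][ee], 0.0)


def test_first_order_separates_by_direct_connectivity(asyn_lr, asyn_net):
    """R^1 of a pair depends only on rates and whether the pair is
    unconnected / one-way / bidirectional: three separated bands."""
    K = asyn_lr.interaction(0.0)
    C = asyn_lr.zero_frequency()
    C0 = asyn_lr.baseline_spectrum(0.0)
    R1 = normalize_contribution(order_contribution(K, C0, 1), C)
    A = asyn_net.adjacency
    ex = asyn_net.exc
    ii, jj = np.triu_indices(ex.size, k=1)
    nlinks = A[ex[ii], ex[jj]] + A[ex[jj], ex[ii]]
    vals = R1[ex[ii], ex[jj]]
    m0 = vals[nlinks == 0]
    m1 = vals[nlinks == 1]
    assert np.allclose(m0, 0.0, atol=1e-15)
    assert m1.min() > m0.max()
    if np.any(nlinks == 2):
        assert vals[nlinks == 2].mean() > m1.mean()


class TestRegressionStats:
    def table(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        return pd.DataFrame({"total": 2 * x + rng.normal(size=200) * 0.5,
                             "self": 2 * x + rng.normal(size=200) * 0.5,
                             "x": x})

    def test_self_regression_r2_one(self):
        t = self.table()
        t["total"] = t["self"]
        st = motif_regression_stats(t, "total", ["self"])
        assert st["r2"]["self"] == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self):
        t = self.table()
        st = motif_regression_stats(t, "total", ["x"])
        assert st["r2"]["x"] == pytest.approx(
            np.corrcoef(t["total"], t["x"])[0, 1] ** 2)

    def test_fraction_refused_for_signed_totals(self):
        t = self.table()  # totals of both signs
        with pytest.raises(ValueError, match="nonpositive"):
            motif_regression_stats(t, "total", ["x"], fractions=True)

    def test_fraction_of_total(self):
        rng = np.random.default_rng(1)
        total = rng.uniform(1.0, 3.0, 20)
        t = pd.DataFrame({"total": total, "part": 0.5 * total})
        st = motif_regression_stats(t, "total", ["part"], fractions=True)
        assert st["fraction"]["part"] == pytest.approx(0.5)

    def test_fraction_drops_rare_nonpositive_totals(self):
        rng = np.random.default_rng(2)
        total = rng.uniform(1.0, 3.0, 500)
        total[0] = -0.1  # one stray pair just below zero
        t = pd.DataFrame({"total": total, "part": 0.5 * total})
        st = motif_regression_stats(t, "total", ["part"], fractions=True)
        assert st["fraction"]["part"] == pytest.approx(0.5)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            motif_regression_stats(self.table().head(2), "total", ["x"])


def test_pair_table_distinct_ee_pairs(asyn_net):
    M = np.arange(asyn_net.n_cells ** 2, dtype=float).reshape(
        asyn_net.n_cells, -1)
    tab = pair_table({"m": M}, asyn_net.cell_type,
                     rates=np.ones(asyn_net.n_cells))
    n_e = asyn_net.exc.size
    assert len(tab) == n_e * (n_e - 1) // 2
    assert (tab["i"] < tab["j"]).all()
    assert set(tab["i"]).issubset(set(asyn_net.exc))
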