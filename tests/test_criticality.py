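"""Criticality measures: DNM index, Gaussian MI, entropies, CTE."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dnmcrit.criticality import (
    conditional_transfer_entropy,
    distribution_entropy_from_mi,
    dnm_index,
    gaussian_mi,
    group_compare,
    group_mean_cte,
    mi_matrix,
    network_entropy_from_mi,
)
from dnmcrit.dnmnet import DNMnet

from conftest import make_corrected


def simple_net(nodes, edges=()):
    return DNMnet(
        nodes=tuple(nodes), edges=tuple(edges),
        node_stats=pd.DataFrame(), edge_stats=pd.DataFrame(),
    )


def histogram_mi(x, y, bins=24):
    """Independent MI oracle: equal-frequency 2-D histogram plus
    Miller–Madow bias correction, in nats."""
    qx = np.quantile(x, np.linspace(0, 1, bins + 1))
    qy = np.quantile(y, np.linspace(0, 1, bins + 1))
    qx[0], qx[-1] = -np.inf, np.inf
    qy[0], qy[-1] = -np.inf, np.inf
    counts, _, _ = np.histogram2d(x, y, bins=[qx, qy])
    n = counts.sum()
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())
    # Miller–Madow: subtract the plug-in entropy biases
    k_xy = int(nz.sum())
    correction = (k_xy - 1) / (2 * n) - 2 * (bins - 1) / (2 * n)
    return mi - correction


class TestDnmIndex:
    def test_constant_signal_gives_zero(self):
        cor = make_corrected(np.ones((2, 3, 10)))
        assert dnm_index(cor, simple_net([0, 1])) == 0.0

    def test_single_node_no_edges_is_its_sd(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 2, 50))
        data[:, 0, :] *= 2.0
        cor = make_corrected(data)
        from dnmcrit.dnmnet import node_fluctuation

        expected = node_fluctuation(cor)[0]
        assert dnm_index(cor, simple_net([0])) == pytest.approx(expected)

    def test_hand_computed_two_node_value(self):
        # SDs {1, 4} and one edge with |rho| = 0.5: sqrt(1*4) * 0.5 = 1.0
        n = 4000
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        y = (x + np.sqrt(3.0) * e) / 2.0  # corr(x, y) = 0.5, SD 1
        x = x - x.mean()
        y = y - y.mean()
        x /= x.std(ddof=1)
        y /= y.std(ddof=1)
        # orthogonalize exactly to |rho| = 0.5 via Gram-Schmidt
        y = 0.5 * x + np.sqrt(0.75) * (
            (y - (y @ x) / (x @ x) * x)
            / np.std(y - (y @ x) / (x @ x) * x, ddof=1)
        )
        data = np.stack([x, 4.0 * y])[np.newaxis]
        cor = make_corrected(data)
        got = dnm_index(cor, simple_net([0, 1], edges=[(0, 1)]))
        assert got == pytest.approx(1.0, rel=1e-3)

    def test_linear_scale_law(self, small_cohort):
        _, cohort = small_cohort
        net = simple_net([2, 3, 4], edges=[(2, 3), (3, 4)])
        cor = cohort[0]
        base = dnm_index(cor, net)
        scaled = dnm_index(replace(cor, data=3.0 * cor.data), net)
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)


class TestGaussianMI:
    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 210))
        y = rng.normal(size=(50, 210))
        mi = gaussian_mi(x, y, delta_t=20.0, sampling_rate=500.0)
        assert mi <= 0.005  # chi2(1)/2n null scale at 10^4 pairs

    def test_exact_dependence_is_clipped_finite(self):
        x = np.random.default_rng(3).normal(size=(1, 100))
        y = np.roll(x, 10, axis=1)  # y_{t+10} = x_t exactly
        mi = gaussian_mi(x, y, delta_t=20.0, sampling_rate=500.0,
                         demean_epochs=False)
        assert np.isfinite(mi)
        assert mi > 5.0

    def test_zero_variance_warns_and_returns_zero(self):
        x = np.zeros((2, 50))
        y = np.random.default_rng(4).normal(size=(2, 50))
        with pytest.warns(UserWarning):
            assert gaussian_mi(x, y, 20.0, 500.0) == 0.0

    def test_lag_must_fit_in_epoch(self):
        x = np.zeros((2, 5))
        with pytest.raises(ValueError):
            gaussian_mi(x, x, delta_t=20.0, sampling_rate=500.0)

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_matches_closed_form_and_histogram_oracle(self, rho):
        # lagged bivariate Gaussian with known rho: the Gaussian MI must hit
        # -1/2 ln(1-rho^2) and agree with the binned estimator
        rng = np.random.default_rng(int(rho * 100))
        n = 100_000
        lag = 10
        x = rng.normal(size=n + lag)
        y = np.empty(n + lag)
        y[:] = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n + lag)
        y = np.roll(y, lag)  # y_{t+lag} correlates with x_t
        got = gaussian_mi(x, y, delta_t=20.0, sampling_rate=500.0,
                          demean_epochs=False)
        expected = -0.5 * np.log(1 - rho**2)
        assert got == pytest.approx(expected, abs=0.02)
        h = histogram_mi(x[:-lag], y[lag:])
        # bootstrap SE of the histogram estimator
        boots = []
        for _ in range(16):
            idx = rng.integers(0, n, size=n)
            boots.append(histogram_mi(x[:-lag][idx], y[lag:][idx]))
        se = np.std(boots)
        assert abs(got - h) <= max(3 * se, 0.02)


class TestEntropies:
    def test_uniform_mi_distribution_entropy_is_one(self):
        mi = np.full((4, 4), 2.0)
        np.fill_diagonal(mi, 0.0)
        assert distribution_entropy_from_mi(mi) == pytest.approx(1.0)

    def test_single_nonzero_mi_gives_zero_entropy(self):
        mi = np.zeros((3, 3))
        mi[0, 1] = 1.0
        assert distribution_entropy_from_mi(mi) == pytest.approx(0.0)

    def test_hand_computed_three_edge_case(self):
        # MI multiset {1, 1, 2}: -(2*0.25 ln 0.25 + 0.5 ln 0.5)/ln 3 = 0.9464
        got = distribution_entropy_from_mi(np.array([1.0, 1.0, 2.0]))
        expected = -(2 * 0.25 * np.log(0.25) + 0.5 * np.log(0.5)) / np.log(3)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.946, abs=5e-4)

    def test_matrix_form_counts_zero_pairs_in_normalisation(self):
        # in matrix form the Ne = n(n-1) directed pairs include zeros
        mi = np.zeros((3, 3))
        mi[0, 1], mi[1, 0], mi[0, 2] = 1.0, 1.0, 2.0
        expected = -(2 * 0.25 * np.log(0.25) + 0.5 * np.log(0.5)) / np.log(6)
        assert distribution_entropy_from_mi(mi) == pytest.approx(expected)

    def test_all_zero_mi_returns_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert distribution_entropy_from_mi(np.zeros((3, 3))) == 1.0

    def test_uniform_outgoing_network_entropy_is_log_n_minus_1(self):
        n = 5
        mi = np.ones((n, n))
        np.fill_diagonal(mi, 0.0)
        assert network_entropy_from_mi(mi) == pytest.approx(np.log(n - 1))

    def test_two_nodes_always_zero(self):
        mi = np.array([[0.0, 3.0], [1.0, 0.0]])
        assert network_entropy_from_mi(mi) == pytest.approx(0.0)

    def test_hand_computed_outgoing_mix(self):
        # one node with outgoing {1, 3}: -(0.25 ln 0.25 + 0.75 ln 0.75)
        mi = np.zeros((3, 3))
        mi[0, 1], mi[0, 2] = 1.0, 3.0
        mi[1, 0], mi[1, 2] = 1.0, 1.0
        mi[2, 0], mi[2, 1] = 1.0, 1.0
        h0 = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        expected = (h0 + np.log(2) + np.log(2)) / 3
        assert network_entropy_from_mi(mi) == pytest.approx(expected)
        assert h0 == pytest.approx(0.5623, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        mi = np.abs(rng.normal(size=(6, 6)))
        np.fill_diagonal(mi, 0.0)
        for c in (0.1, 7.3):
            assert distribution_entropy_from_mi(c * mi) == pytest.approx(
                distribution_entropy_from_mi(mi)
            )
            assert network_entropy_from_mi(c * mi) == pytest.approx(
                network_entropy_from_mi(mi)
            )

    def test_entropies_within_theoretical_bounds(self, small_cohort):
        _, cohort = small_cohort
        nodes = list(range(6))
        for cor in cohort[:4]:
            mi = mi_matrix(cor, nodes, 20.0)
            de = distribution_entropy_from_mi(mi)
            ne = network_entropy_from_mi(mi)
            assert 0.0 <= de <= 1.0
            assert 0.0 <= ne <= np.log(len(nodes) - 1) + 1e-12


class TestCTE:
    def test_null_system_within_null_band(self):
        # independent AR channels: every pairwise CTE at the chi2(1)/2n scale
        rng = np.random.default_rng(6)
        n_ep, n_t = 40, 260
        data = rng.normal(size=(n_ep, 5, n_t))
        cor = make_corrected(data)
        cte = conditional_transfer_entropy(cor, 20.0)
        off = cte[~np.eye(5, dtype=bool)]
        assert np.all(off <= 0.01)

    def test_diagonal_is_zero(self, small_cohort):
        _, cohort = small_cohort
        cte = conditional_transfer_entropy(cohort[0], 20.0)
        assert np.all(np.diag(cte) == 0.0)
        assert np.all(cte >= 0.0)

    def test_chain_direct_vs_indirect(self):
        # x -> y -> z at lag one sample: conditioning on time t blocks the
        # x -> z route, so CTE(x->z) stays at null scale
        rng = np.random.default_rng(7)
        n_ep, n_t = 60, 200
        x = np.empty((n_ep, n_t))
        y = np.empty((n_ep, n_t))
        z = np.empty((n_ep, n_t))
        x[:, 0], y[:, 0], z[:, 0] = rng.normal(size=(3, n_ep))
        for t in range(1, n_t):
            x[:, t] = 0.5 * x[:, t - 1] + rng.normal(size=n_ep)
            y[:, t] = 0.5 * y[:, t - 1] + 0.6 * x[:, t - 1] + rng.normal(size=n_ep)
            z[:, t] = 0.5 * z[:, t - 1] + 0.6 * y[:, t - 1] + rng.normal(size=n_ep)
        cor = make_corrected(np.stack([x, y, z], axis=1))
        cte = conditional_transfer_entropy(cor, delta_t=2.0)  # 1 sample
        assert cte[0, 1] > cte[0, 2]
        assert cte[0, 2] <= 0.01
        assert cte[1, 2] > 0.05

    def test_two_channel_matches_recursive_partial_correlation(self):
        # oracle: 3-variable identity
        # rho_{x y.z} = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))
        # with x = x_t, y = y_{t+lag}, z = y_t
        rng = np.random.default_rng(8)
        n_ep, n_t = 30, 120
        a = np.empty((n_ep, n_t))
        b = np.empty((n_ep, n_t))
        a[:, 0], b[:, 0] = rng.normal(size=(2, n_ep))
        for t in range(1, n_t):
            a[:, t] = 0.8 * a[:, t - 1] + rng.normal(size=n_ep)
            b[:, t] = 0.5 * b[:, t - 1] + 0.4 * a[:, t - 1] + rng.normal(size=n_ep)
        cor = make_corrected(np.stack([a, b], axis=1))
        lag = 1
        d = cor.data - cor.data.mean(axis=2, keepdims=True)
        xt = d[:, 0, :-lag].ravel()
        ylag = d[:, 1, lag:].ravel()
        yt = d[:, 1, :-lag].ravel()
        r_xy = np.corrcoef(xt, ylag)[0, 1]
        r_xz = np.corrcoef(xt, yt)[0, 1]
        r_yz = np.corrcoef(ylag, yt)[0, 1]
        rho = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        expected = -0.5 * np.log(1 - rho**2)
        cte = conditional_transfer_entropy(cor, delta_t=2.0)
        assert cte[0, 1] == pytest.approx(expected, rel=1e-6)

    def test_insufficient_samples_error_names_requirement(self):
        cor = make_corrected(np.random.default_rng(9).normal(size=(1, 20, 30)))
        with pytest.raises(ValueError, match="need at least"):
            conditional_transfer_entropy(cor, 20.0)


class TestGroupSummaries:
    def test_group_compare_contrasts(self, trio_cohort):
        _, cohort = trio_cohort
        rng = np.random.default_rng(10)
        values = rng.normal(size=len(cohort))
        groups = [c.group for c in cohort]
        out = group_compare(values, groups)
        assert set(out) == {"HC_gt_UHR", "HC_gt_PD", "UHR_vs_PD"}
        assert out["HC_gt_PD"].alternative == "greater"
        assert out["UHR_vs_PD"].alternative == "two-sided"

    def test_group_compare_matches_exact_enumeration(self):
        # at n <= 10 per group the rank-sum p must equal full enumeration of
        # rank assignments
        from test_stats import brute_force_ranksum_p

        rng = np.random.default_rng(12)
        values = rng.normal(size=14)
        groups = np.array(["HC"] * 5 + ["UHR"] * 4 + ["PD"] * 5)
        out = group_compare(values, groups)
        hc, uhr, pdv = values[:5], values[5:9], values[9:]
        assert out["HC_gt_PD"].p_value == pytest.approx(
            brute_force_ranksum_p(hc, pdv, "greater")
        )
        assert out["UHR_vs_PD"].p_value == pytest.approx(
            brute_force_ranksum_p(uhr, pdv, "two-sided")
        )

    def test_single_subject_mean_is_identity(self):
        m = np.random.default_rng(11).normal(size=(4, 4))
        mean, summary = group_mean_cte([m], ["HC"], "HC")
        assert np.array_equal(mean, m)

    def test_all_zero_matrices(self):
        mats = [np.zeros((3, 3))] * 4
        mean, summary = group_mean_cte(mats, ["PD"] * 4, "PD")
        assert np.all(mean == 0.0)
        assert summary["mean_offdiag"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_mean_cte([np.zeros((2, 2))], ["HC"], "PD")
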