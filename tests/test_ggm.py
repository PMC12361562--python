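"""Core network math: pcor maps, likelihood, fit indices, centrality."""
import numpy as np
import pytest
from scipy import stats

import flournet as fn
from flournet.ggm import GGMNetwork, network_from_correlation

from conftest import random_correlation


class TestPcorMaps:
    def test_identity_gives_empty_network(self):
        assert np.allclose(fn.pcor_from_corr(np.eye(12)), 0.0)

    def test_equicorrelated_three_variables(self):
        # all pairwise r = 0.5: partial = (0.5 - 0.25) / (1 - 0.25) = 1/3
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        om = fn.pcor_from_corr(R)
        assert np.allclose(om[np.triu_indices(3, 1)], 1.0 / 3.0, atol=1e-12)

    def test_two_node_partial_equals_marginal(self):
        R = fn.corr_from_pcor(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert np.isclose(R[0, 1], 0.5, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip(self, seed):
        R = random_correlation(12, seed)
        assert np.abs(fn.corr_from_pcor(fn.pcor_from_corr(R)) - R).max() < 1e-10

    def test_round_trip_reference_matrix(self, ref_R):
        back = fn.corr_from_pcor(fn.pcor_from_corr(ref_R))
        assert np.abs(back - ref_R).max() < 1e-10

    def test_total_sample_pcor_close_to_published_pooled_edges(self, ref_R, schema):
        # total-sample and pooled meta-analytic networks differ slightly
        om = fn.pcor_from_corr(ref_R)
        e, ws = schema.index("E"), schema.index("WS")
        assert om[e, ws] == pytest.approx(0.650, abs=0.05)

    def test_zero_network_implies_identity(self):
        assert np.allclose(fn.corr_from_pcor(np.zeros((5, 5))), np.eye(5))

    def test_singular_matrix_raises_with_condition_number(self):
        R = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            fn.pcor_from_corr(R)

    def test_permutation_equivariance(self):
        R = random_correlation(6, 3)
        perm = np.array([2, 0, 5, 1, 4, 3])
        om = fn.pcor_from_corr(R)
        om_p = fn.pcor_from_corr(R[np.ix_(perm, perm)])
        assert np.allclose(om_p, om[np.ix_(perm, perm)], atol=1e-12)


class TestEdgeInference:
    def test_zero_partial_gives_p_one(self):
        om = np.zeros((12, 12))
        assert np.allclose(fn.edge_pvalues(om, 1000), 1.0)

    def test_t_distribution_oracle(self):
        # t = w sqrt((N-2-k)/(1-w^2)) with k = 10 conditioned variables
        om = np.zeros((12, 12))
        om[0, 1] = om[1, 0] = 0.1
        for N, sig in ((1000, True), (100, False)):
            df = N - 12
            t = 0.1 * np.sqrt(df / (1 - 0.01))
            expected = 2 * stats.t.sf(t, df)
            p = fn.edge_pvalues(om, N)[0, 1]
            assert p == pytest.approx(expected, rel=1e-12)
            assert bool(p < 0.05) is sig

    def test_threshold_counts(self):
        om = np.zeros((12, 12))
        om[0, 1] = om[1, 0] = 0.3
        om[2, 3] = om[3, 2] = 0.2
        pv = np.ones((12, 12))
        pv[0, 1] = pv[1, 0] = 0.01
        pv[2, 3] = pv[3, 2] = 0.06
        net = GGMNetwork(nodes=tuple(fn.DEFAULT_SCHEMA.codes), omega=om, pvals=pv)
        thr = fn.threshold(net, alpha=0.05)
        assert thr.n_edges() == 1
        assert thr.omega[2, 3] == 0.0
        assert thr.omega_full[2, 3] == 0.2  # pre-threshold weights preserved

    def test_threshold_keeps_all_when_significant(self, small_cset):
        # N = 60 keeps every p-value well above floating-point underflow
        R = small_cset.R[0]
        net = network_from_correlation(R, small_cset.schema.codes, N=60)
        all_sig = fn.threshold(net, alpha=1.0)
        assert np.allclose(all_sig.omega, net.omega)
        none_sig = fn.threshold(net, alpha=net.pvals[net.pvals > 0].min() / 2)
        assert none_sig.n_edges() == 0


class TestLikelihood:
    def test_perfect_fit_zero_discrepancy(self):
        R = random_correlation(5, 1)
        F, _, chisq = fn.gaussian_discrepancy(R, R, 500)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert chisq == pytest.approx(0.0, abs=1e-9)

    def test_two_variable_closed_form(self):
        # S with r=0.5 vs independence: F = -ln(1 - 0.25)
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        F, _, chisq = fn.gaussian_discrepancy(S, np.eye(2), 101)
        assert F == pytest.approx(-np.log(0.75), rel=1e-12)
        assert chisq == pytest.approx(100 * -np.log(0.75), rel=1e-12)

    def test_chisq_linear_in_sample_size(self):
        S = random_correlation(4, 2)
        Sigma = np.eye(4)
        _, _, c1 = fn.gaussian_discrepancy(S, Sigma, 101)
        _, _, c2 = fn.gaussian_discrepancy(S, Sigma, 201)
        assert c2 / c1 == pytest.approx(200.0 / 100.0, rel=1e-12)


class TestFitIndices:
    def test_exact_fit_limit(self):
        fi = fn.fit_indices(39.0, 39, 5000.0, 66, 1000, loglik=-1.0, n_params=39)
        assert fi.rmsea == 0.0
        assert fi.cfi == 1.0

    def test_saturated_model(self):
        fi = fn.fit_indices(0.0, 0, 5000.0, 66, 1000, loglik=-1.0, n_params=78)
        assert fi.rmsea == 0.0
        assert np.isnan(fi.tli) and np.isnan(fi.rfi)

    def test_rmsea_definition(self):
        fi = fn.fit_indices(500.0, 40, 9000.0, 66, 2001, loglik=-1.0, n_params=38)
        assert fi.rmsea == pytest.approx(np.sqrt(460.0 / (40 * 2000)), rel=1e-12)
        assert fi.rmsea_low < fi.rmsea < fi.rmsea_high

    def test_information_criteria(self):
        fi = fn.fit_indices(10.0, 5, 100.0, 66, 1000, loglik=-1234.5, n_params=7)
        assert fi.aic == pytest.approx(2 * 1234.5 + 14)
        assert fi.bic == pytest.approx(2 * 1234.5 + 7 * np.log(1000))


class TestCentralityPrimitives:
    def test_empty_network_zero_influence(self):
        assert np.allclose(fn.expected_influence(np.zeros((12, 12))), 0.0)

    def test_signed_sum_example(self):
        om = np.zeros((3, 3))
        om[0, 1] = om[1, 0] = 0.3
        om[0, 2] = om[2, 0] = -0.1
        ei = fn.expected_influence(om)
        assert np.allclose(ei, [0.2, 0.3, -0.1])

    def test_influence_equals_column_sum(self):
        om = fn.pcor_from_corr(random_correlation(8, 4))
        assert np.allclose(fn.expected_influence(om), om.sum(axis=0))

    def test_predictability_identity_and_two_node(self):
        assert np.allclose(fn.predictability(np.eye(4)), 0.0)
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert np.allclose(fn.predictability(R), 0.36)

    @pytest.mark.parametrize("seed", range(4))
    def test_predictability_equals_regression_r2(self, seed):
        # R^2 of node-on-all-others least squares, on random 5-node systems
        R = random_correlation(5, 100 + seed)
        r2 = fn.predictability(R)
        for i in range(5):
            others = [j for j in range(5) if j != i]
            Rxx = R[np.ix_(others, others)]
            rxy = R[others, i]
            beta = np.linalg.solve(Rxx, rxy)
            assert r2[i] == pytest.approx(float(rxy @ beta), abs=1e-12)

    def test_predictability_sign_flip_invariance(self):
        R = random_correlation(6, 7)
        D = np.diag([1, -1, 1, -1, -1, 1.0])
        assert np.allclose(fn.predictability(D @ R @ D), fn.predictability(R))


class TestNetworkContainer:
    def test_edge_list_round_shape(self, pooled_omega, schema):
        net = GGMNetwork(nodes=schema.codes, omega=pooled_omega)
        edges = net.to_edge_list()
        assert len(edges) == 66
        assert net.implied_correlation().shape == (12, 12)

    def test_rejects_non_hollow(self, schema):
        bad = np.eye(12) * 0.5
        with pytest.raises(ValueError, match="hollow"):
            GGMNetwork(nodes=schema.codes, omega=bad)
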