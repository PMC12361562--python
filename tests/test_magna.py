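"""Meta-analytic network aggregation: vech plumbing, sampling covariance,
heterogeneity comparison, random-effects fit and recovery."""
import warnings

import numpy as np
import pytest

import flournet as fn
from flournet.correlate import CorrelationSet
from flournet.magna import MAGNA, corr_sampling_cov, edge_labels, unvech, vech_offdiag

from conftest import random_correlation


class TestVech:
    def test_identity_gives_zero_vector(self):
        assert np.allclose(vech_offdiag(np.eye(12)), 0.0)

    def test_length_is_66_for_12_nodes(self):
        assert len(vech_offdiag(np.eye(12))) == 66
        assert len(edge_labels()) == 66

    def test_round_trip_reference(self, ref_R):
        assert np.array_equal(unvech(vech_offdiag(ref_R)), ref_R)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="triangular"):
            unvech(np.zeros(65))


class TestSamplingCovariance:
    def test_two_variable_closed_form(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        V = corr_sampling_cov(R, 100)
        assert V.shape == (1, 1)
        assert V[0, 0] == pytest.approx((1 - 0.25) ** 2 / 100, rel=1e-12)

    def test_independence_diagonal(self):
        V = corr_sampling_cov(np.eye(5), 200)
        assert np.allclose(np.diag(V), 1 / 200)
        assert np.abs(V - np.diag(np.diag(V))).max() < 1e-15

    def test_symmetric_psd(self, ref_R):
        V = corr_sampling_cov(ref_R, 1000)
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V)[0] > -1e-12


def _cset_from_mats(mats, Ns):
    return CorrelationSet(
        countries=[f"c{i}" for i in range(len(mats))], R=list(mats), N=list(Ns)
    )


class TestHeterogeneityComparison:
    def test_identical_countries_prefer_pooled(self):
        S = random_correlation(12, 1)
        het = fn.fit_saturated_models(_cset_from_mats([S, S], [800, 800]))
        assert het.chisq_diff == pytest.approx(0.0, abs=1e-8)
        assert het.preferred_bic == "pooled"
        assert het.preferred_aic == "pooled"

    def test_heterogeneous_study_prefers_single(self):
        truth = fn.make_pooled_truth("reference")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mats, _ = fn.perturb_country_structures(truth, 0.12, 8, seed=2)
        rng = np.random.default_rng(3)
        Rs = [
            np.corrcoef((rng.standard_normal((3000, 12)) @ np.linalg.cholesky(M).T).T)
            for M in mats
        ]
        het = fn.fit_saturated_models(_cset_from_mats(Rs, [3000] * 8))
        assert het.preferred_aic == "single"
        assert het.preferred_bic == "single"

    def test_pooled_chisq_nonnegative(self, small_cset):
        het = fn.fit_saturated_models(small_cset)
        assert het.chisq_diff >= 0
        assert het.df_diff == 66 * (small_cset.n_countries - 1)

    def test_single_country_rejected(self):
        with pytest.raises(ValueError, match="2 countries"):
            fn.fit_saturated_models(_cset_from_mats([np.eye(12)], [500]))


class TestRandomEffectsFit:
    def test_single_country_reduces_to_saturated_ggm(self):
        S = random_correlation(12, 4)
        res = MAGNA(_cset_from_mats([S], [2000])).fit(tau_fixed=0.0)
        expected = fn.pcor_from_corr(S)
        assert np.abs(res.network_unthresholded.omega - expected).max() < 1e-6

    def test_shared_matrix_reduction(self):
        S = random_correlation(12, 5)
        res = MAGNA(_cset_from_mats([S] * 4, [1000] * 4)).fit(tau_fixed=0.0)
        assert np.abs(res.rho - vech_offdiag(S)).max() < 1e-8

    def test_needs_three_countries_to_estimate_tau(self):
        S = random_correlation(12, 6)
        with pytest.raises(ValueError, match="3 countries"):
            MAGNA(_cset_from_mats([S, S], [500, 500])).fit()

    def test_country_order_invariance(self, small_cset):
        res1 = MAGNA(small_cset).fit()
        perm = ["c3", "c0", "c4", "c2", "c1"]
        res2 = MAGNA(small_cset.subset(perm)).fit()
        assert np.abs(res1.rho - res2.rho).max() < 1e-8
        assert np.abs(res1.tau - res2.tau).max() < 1e-6

    def test_homogeneous_truth_tau_near_zero(self):
        cfgs = [
            fn.CountryConfig(f"c{i}", n=2000, missing_rate=0.0, weight_dispersion=0.0, seed=50 + i)
            for i in range(22)
        ]
        study = fn.generate_study(configs=cfgs, tau=0.0, seed=6)
        cset, _ = fn.build_correlation_set(study.samples)
        res = MAGNA(cset).fit()
        assert res.mean_tau < 0.02

    def test_edge_table_and_summary(self, small_cset):
        res = MAGNA(small_cset).fit()
        tab = res.edge_table()
        assert len(tab) == 66
        assert (tab["ci_low"] <= tab["ci_high"]).all()
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()
        assert "random-effect SD" in res.summary()

    def test_random_effect_summary_sorted(self, small_cset):
        res = MAGNA(small_cset).fit()
        re = res.random_effect_summary()
        assert len(re) == 66
        assert (np.diff(re["tau"].to_numpy()) <= 1e-12).all()
        assert res.min_tau <= res.mean_tau <= res.max_tau

    def test_tau_spread_shrinks_with_more_countries(self):
        # constant-tau truth: dispersion of tau-hat falls as C grows
        spreads = {}
        for C, seed in ((22, 7), (100, 8)):
            truth = fn.make_pooled_truth("random", p=12, density=0.2, seed=9)
            mats, _ = fn.perturb_country_structures(truth, 0.1, C, seed=seed)
            rng = np.random.default_rng(seed)
            Rs = [
                np.corrcoef((rng.standard_normal((2500, 12)) @ np.linalg.cholesky(M).T).T)
                for M in mats
            ]
            res = MAGNA(_cset_from_mats(Rs, [2500] * C)).fit()
            spreads[C] = res.tau.std()
        assert spreads[100] < spreads[22]

    def test_fisher_z_close_to_raw_scale(self, small_cset):
        raw = MAGNA(small_cset).fit()
        fz = MAGNA(small_cset, fisher_z=True).fit()
        assert np.abs(raw.rho - fz.rho).max() < 0.02

    def test_delta_method_se_matches_country_bootstrap(self):
        # nonparametric bootstrap over countries as an independent SE oracle
        C, n = 50, 1500
        truth = fn.make_pooled_truth("reference")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mats, _ = fn.perturb_country_structures(truth, 0.12, C, seed=31)
        rng = np.random.default_rng(31)
        Rs = [
            np.corrcoef((rng.standard_normal((n, 12)) @ np.linalg.cholesky(M).T).T)
            for M in mats
        ]
        cset = _cset_from_mats(Rs, [n] * C)
        res = MAGNA(cset).fit()
        B = 120
        oms = np.empty((B, 66))
        for b in range(B):
            idx = rng.integers(0, C, C)
            cs_b = CorrelationSet(
                countries=[f"b{i}" for i in range(C)], R=[Rs[i] for i in idx], N=[n] * C
            )
            oms[b] = MAGNA(cs_b).fit().omega_vec
        ratio = res.se_vec / oms.std(axis=0, ddof=1)
        assert 0.9 < np.median(ratio) < 1.1
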