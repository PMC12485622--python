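import numpy as np
import pytest

import omicsgp as og
from omicsgp.rkhs import GibbsConfig, eigen_prepare, gelman_rubin

from conftest import make_feature_matrix, random_psd_kernel


def standardized_linear_kernel(rng, n, p):
    fm = make_feature_matrix(rng.standard_normal((n, p)))
    return og.linear_kernel(og.standardize_features(fm))


class TestEigenPrepare:
    def test_identity_keeps_everything(self):
        K = og.KernelMatrix(["A", "B", "C"], np.eye(3), "i")
        gamma, lam = eigen_prepare(K)
        assert lam.shape == (3,)
        np.testing.assert_allclose(lam, 1.0)

    def test_rank_one_keeps_single_pair(self, rng):
        v = rng.standard_normal(5)
        K = og.KernelMatrix([f"L{i}" for i in range(5)], np.outer(v, v), "r1")
        gamma, lam = eigen_prepare(K)
        assert lam.shape == (1,)
        np.testing.assert_allclose(np.abs(gamma[:, 0]), np.abs(v) / np.linalg.norm(v))

    def test_reconstruction(self, rng):
        K = random_psd_kernel(rng, 10)
        gamma, lam = eigen_prepare(K, min_eigen_keep=0.0)
        rec = (gamma * lam) @ gamma.T
        assert np.linalg.norm(rec - K.values) / np.linalg.norm(K.values) <= 1e-6


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        chain = rng.standard_normal(1000)
        assert gelman_rubin(np.stack([chain, chain])) == pytest.approx(1.0, abs=1e-3)

    def test_iid_chains_below_gate(self, rng):
        chains = rng.standard_normal((2, 1000))
        assert gelman_rubin(chains) < 1.1

    def test_disjoint_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 2.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.standard_normal((1, 100)))


class TestConfigValidation:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=100, burn_in=100)

    def test_minimum_retained_draws(self):
        with pytest.raises(ValueError, match="50"):
            GibbsConfig(n_iter=200, burn_in=100, thin=10)

    def test_fixed_variances_length_checked(self, rng):
        K = standardized_linear_kernel(rng, 10, 5)
        model = og.MultiKernelRKHS(rng.standard_normal(10), [K])
        with pytest.raises(ValueError, match="fixed_variances"):
            model.fit(GibbsConfig(n_iter=600, burn_in=100, fixed_variances=(1.0,)))


class TestConjugateOracles:
    """With variances fixed, the sampler's stationary mean has a closed form."""

    def test_identity_kernel_matches_ridge(self, rng):
        n = 40
        y = rng.standard_normal(n)
        yc = y - y.mean()
        K = og.KernelMatrix([f"L{i}" for i in range(n)], np.eye(n), "i")
        lam = 0.5 / 1.0
        expected = yc / (1 + lam)
        fit = og.MultiKernelRKHS(yc, [K]).fit(
            GibbsConfig(n_iter=4500, burn_in=500, thin=1, seed=2,
                        fixed_variances=(1.0, 0.5), fix_mu=0.0)
        )
        u = fit.line_effects[fit.term_labels[0]]
        assert np.abs(u - expected).max() < 0.03

    def test_general_kernel_matches_gblup(self, rng):
        n = 40
        K = standardized_linear_kernel(rng, n, 25)
        y = K.values @ rng.standard_normal(n) + 0.5 * rng.standard_normal(n)
        yc = y - y.mean()
        s2g, s2e = 1.0, 0.5
        u_hat = K.values @ np.linalg.solve(K.values + (s2e / s2g) * np.eye(n), yc)
        fit = og.MultiKernelRKHS(yc, [K]).fit(
            GibbsConfig(n_iter=4500, burn_in=500, thin=1, seed=3,
                        fixed_variances=(s2g, s2e), fix_mu=0.0)
        )
        u = fit.line_effects[fit.term_labels[0]]
        assert np.abs(u - u_hat).max() < 0.05

    def test_masked_prediction_matches_partitioned_blup(self, rng):
        n = 45
        K = standardized_linear_kernel(rng, n, 30)
        y = K.values @ rng.standard_normal(n) + 0.4 * rng.standard_normal(n)
        yc = y - y.mean()
        s2g, s2e = 1.0, 0.5
        lam = s2e / s2g
        mask = np.arange(0, n, 3)
        obs = np.setdiff1d(np.arange(n), mask)
        Koo = K.values[np.ix_(obs, obs)]
        Kmo = K.values[np.ix_(mask, obs)]
        pred_cf = Kmo @ np.linalg.solve(Koo + lam * np.eye(len(obs)), yc[obs])
        fit = og.MultiKernelRKHS(yc, [K], masked=mask).fit(
            GibbsConfig(n_iter=6500, burn_in=500, thin=1, seed=5,
                        fixed_variances=(s2g, s2e), fix_mu=0.0)
        )
        assert np.abs(fit.predict(mask) - pred_cf).max() < 0.06


class TestModelInterface:
    def test_constant_observed_phenotype_rejected(self, rng):
        K = standardized_linear_kernel(rng, 10, 4)
        with pytest.raises(ValueError, match="constant"):
            og.MultiKernelRKHS(np.ones(10), [K])

    def test_nan_entries_are_masked_automatically(self, rng):
        K = standardized_linear_kernel(rng, 12, 5)
        y = rng.standard_normal(12)
        y[[2, 7]] = np.nan
        fit = og.MultiKernelRKHS(y, [K]).fit(
            GibbsConfig(n_iter=700, burn_in=200, seed=0)
        )
        np.testing.assert_array_equal(fit.masked_index, [2, 7])
        assert np.isfinite(fit.predictions).all()

    def test_empty_mask_gives_empty_predictions(self, rng):
        K = standardized_linear_kernel(rng, 10, 4)
        fit = og.MultiKernelRKHS(rng.standard_normal(10), [K]).fit(
            GibbsConfig(n_iter=700, burn_in=200, seed=0)
        )
        assert fit.predictions.size == 0

    def test_prediction_index_mismatch_rejected(self, rng):
        K = standardized_linear_kernel(rng, 10, 4)
        fit = og.MultiKernelRKHS(rng.standard_normal(10), [K], masked=[1, 2]).fit(
            GibbsConfig(n_iter=700, burn_in=200, seed=0)
        )
        with pytest.raises(ValueError, match="not masked"):
            fit.predict([3])

    def test_kernel_order_mismatch_rejected(self, rng):
        K1 = standardized_linear_kernel(rng, 10, 4)
        K2 = og.KernelMatrix([f"X{i}" for i in range(10)], np.eye(10), "other")
        with pytest.raises(ValueError, match="line order"):
            og.MultiKernelRKHS(rng.standard_normal(10), [K1, K2])


class TestEquivariance:
    def test_scale_equivariance_is_exact(self, rng):
        n = 20
        K = standardized_linear_kernel(rng, n, 8)
        y = rng.standard_normal(n)
        mask = [0, 5]
        cfg = GibbsConfig(n_iter=700, burn_in=200, seed=9)
        fit1 = og.MultiKernelRKHS(y, [K], masked=mask).fit(cfg)
        c = 3.7
        fit2 = og.MultiKernelRKHS(c * y, [K], masked=mask).fit(cfg)
        np.testing.assert_allclose(
            fit2.variance_components["post_mean"],
            c**2 * fit1.variance_components["post_mean"],
            rtol=1e-8,
        )
        np.testing.assert_allclose(
            fit2.predictions - fit2.mu, c * (fit1.predictions - fit1.mu), rtol=1e-6
        )

    def test_permutation_equivariance_within_mc_error(self, rng):
        n = 30
        K = standardized_linear_kernel(rng, n, 12)
        y = K.values @ rng.standard_normal(n) + 0.3 * rng.standard_normal(n)
        perm = rng.permutation(n)
        Kp = og.KernelMatrix(
            [K.line_ids[i] for i in perm], K.values[np.ix_(perm, perm)], K.recipe
        )
        mask = np.array([0, 4, 9])
        cfg = GibbsConfig(n_iter=4500, burn_in=500, thin=1, seed=4,
                          fixed_variances=(1.0, 0.4), fix_mu=0.0)
        fit = og.MultiKernelRKHS(y, [K], masked=mask).fit(cfg)
        mask_p = np.array([int(np.flatnonzero(perm == i)[0]) for i in mask])
        fit_p = og.MultiKernelRKHS(y[perm], [Kp], masked=mask_p).fit(cfg)
        np.testing.assert_allclose(
            fit_p.predict(mask_p), fit.predict(mask), atol=0.06
        )


class TestDiagnostics:
    def test_two_chain_fit_reports_rhat_below_gate(self, small_m4_kernels, small_dataset):
        kernels, spec = small_m4_kernels
        dataset, _ = small_dataset
        fit = og.MultiKernelRKHS(
            dataset.trait_vector("trait1"), kernels, term_labels=spec.term_labels
        ).fit(GibbsConfig(n_iter=2500, burn_in=500, seed=21, n_chains=2))
        assert fit.max_rhat < 1.1
        assert (fit.variance_components["post_mean"] > 0).all()

    def test_adding_noise_kernel_does_not_help_prediction(self, rng):
        # genomic-only signal: a pure-noise kernel term should not raise APC
        n = 80
        Kg = standardized_linear_kernel(rng, n, 60)
        gamma, lam = eigen_prepare(Kg)
        u = gamma @ (np.sqrt(lam) * rng.standard_normal(len(lam)))
        y = u + 0.4 * rng.standard_normal(n)
        Kn = og.KernelMatrix(Kg.line_ids, np.eye(n), "noise")
        test = np.arange(0, n, 2)
        cfg = GibbsConfig(n_iter=2000, burn_in=500, seed=3)
        fit1 = og.MultiKernelRKHS(y, [Kg], masked=test).fit(cfg)
        fit2 = og.MultiKernelRKHS(y, [Kg, Kn], masked=test).fit(cfg)
        apc1 = og.apc(y[test], fit1.predict(test))
        apc2 = og.apc(y[test], fit2.predict(test))
        assert apc2 <= apc1 + 0.1
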