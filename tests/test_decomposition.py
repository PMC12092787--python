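"""Order selection, whitening, Infomax, ICASSO, standardization."""

import numpy as np
import pytest

import sbmorph as sm
from sbmorph.exceptions import DegenerateComponentError, ValidationError


def _mdl_oracle(eigenvalues, n_eff, max_k):
    """Brute-force evaluation of the MDL criterion from the eigen-spectrum."""
    n = len(eigenvalues)
    vals = []
    for k in range(1, max_k + 1):
        tail = eigenvalues[k:]
        m = n - k
        if m == 0:
            fit = 0.0
        else:
            gm = np.exp(np.mean(np.log(tail)))
            am = np.mean(tail)
            fit = -n_eff * m * np.log(gm / am)
        vals.append(fit + 0.5 * k * (2 * n - k) * np.log(n_eff))
    return np.asarray(vals)


class TestMdl:
    def test_selects_true_order_on_structured_data(self):
        cfg = sm.SyntheticConfig(
            grid_shape=(24, 24, 24), k_true=3, group_effect=(1.0, 1.0, 1.0),
            noise_sd=0.05, clinical_link=None, seed=11,
        )
        vs, _, _ = sm.synthesize_dataset(cfg)
        mask = sm.build_mask(vs)
        mm = sm.vectorize(vs, mask)
        est = sm.estimate_order_mdl(mm, max_k=10)
        assert est.k_selected == 3

    def test_criterion_matches_brute_force_formula(self, measure):
        est = sm.estimate_order_mdl(measure, max_k=10, decimation=4)
        n_eff = measure.values[:, ::4].shape[1]
        oracle = _mdl_oracle(est.eigenvalues, n_eff, 10)
        np.testing.assert_allclose(est.criterion_values, oracle, rtol=1e-12)
        assert est.k_selected == int(np.argmin(oracle)) + 1

    def test_pure_noise_selects_low_order(self):
        """Unstructured i.i.d. noise never suggests more than 2 components."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 4000))
            est = sm.estimate_order_mdl(X, max_k=10, decimation=1)
            assert est.k_selected <= 2

    def test_max_k_bounds(self, measure):
        with pytest.raises(ValidationError):
            sm.estimate_order_mdl(measure, max_k=measure.n_subjects)


class TestPcaReduce:
    def test_whitened_covariance_is_identity(self, measure):
        wh = sm.pca_reduce(measure, 4)
        cov = wh.whitened @ wh.whitened.T / wh.whitened.shape[1]
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-8)

    def test_full_rank_reconstruction_lossless(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 500))
        wh = sm.pca_reduce(X, 7)
        Xc = sm.center_measure_matrix(X)
        recon = wh.dewhitening @ wh.whitened
        rel = np.linalg.norm(recon - Xc) / np.linalg.norm(Xc)
        assert rel <= 1e-10

    def test_rank_k_model_leaves_only_noise_at_true_order(self):
        """The mean image + rank-k_true reconstruction leaves no structured
        variance: the residual is at most the injected noise level, and the
        model explains the overwhelming share of the row-centered variance."""
        cfg = sm.SyntheticConfig(
            k_true=3, group_effect=(0.0, 0.0, 0.0), noise_sd=0.05,
            clinical_link=None, seed=4,
        )
        vs, _, _ = sm.synthesize_dataset(cfg)
        mm = sm.vectorize(vs, sm.build_mask(vs))
        wh = sm.pca_reduce(mm, 3)
        X = mm.values
        X_rowc = X - X.mean(axis=1, keepdims=True)
        mean_image = X_rowc.mean(axis=0, keepdims=True)
        recon = mean_image + wh.dewhitening @ wh.whitened
        resid = X_rowc - recon
        assert (resid**2).mean() <= cfg.noise_sd**2
        explained = 1 - np.linalg.norm(resid) ** 2 / np.linalg.norm(X_rowc) ** 2
        assert explained >= 0.9

    def test_k_beyond_rank_rejected(self):
        rng = np.random.default_rng(1)
        low_rank = rng.standard_normal((10, 3)) @ rng.standard_normal((3, 200))
        with pytest.raises(ValidationError):
            sm.pca_reduce(low_rank, 8)


def _laplace_sources(k, n, rng):
    s = rng.laplace(0, 1, size=(k, n))
    s -= s.mean(axis=1, keepdims=True)
    s /= s.std(axis=1, keepdims=True)
    return s


def _normalize_rows(W):
    return W / np.linalg.norm(W, axis=1, keepdims=True)


def _is_signed_permutation_of_identity(W, tol):
    """Up to row order and sign, W (row-normalized) is the identity."""
    P = np.abs(_normalize_rows(W))
    rows, cols = np.nonzero(P > 1 - tol)
    return len(set(rows)) == W.shape[0] and len(set(cols)) == W.shape[0]


class TestInfomax:
    def test_independent_inputs_recovered_as_signed_permutation(self):
        rng = np.random.default_rng(3)
        s = _laplace_sources(3, 40000, rng)
        run = sm.infomax_unmix(s, seed=3)
        assert run.converged
        # unit-norm rows: scale is an ICA indeterminacy
        assert _is_signed_permutation_of_identity(run.unmixing, tol=0.05)

    def test_two_mixed_laplace_sources_separated(self):
        rng = np.random.default_rng(3)
        s = _laplace_sources(2, 50000, rng)
        A = np.array([[1.0, 0.5], [0.3, 1.0]])
        X = A @ s
        # whiten manually (2 channels, full order)
        Xc = X - X.mean(axis=1, keepdims=True)
        ev, E = np.linalg.eigh(Xc @ Xc.T / X.shape[1])
        W_white = (E / np.sqrt(ev)).T
        run = sm.infomax_unmix(W_white @ Xc, seed=3)
        # total unmixing back in channel space, scored against the true mixing
        U = run.unmixing @ W_white
        amari = sm.amari_index(U @ A)
        assert amari < 0.05
        _, _, corr = sm.match_sources(s, run.sources)
        assert corr.min() > 0.99

    def test_gaussian_sources_do_not_error(self):
        rng = np.random.default_rng(5)
        g = rng.standard_normal((2, 20000))
        g -= g.mean(axis=1, keepdims=True)
        g /= g.std(axis=1, keepdims=True)
        run = sm.infomax_unmix(g, seed=5)
        assert np.isfinite(run.unmixing).all()  # non-identifiable but defined

    def test_nonfinite_input_rejected(self):
        bad = np.full((2, 100), np.nan)
        with pytest.raises(ValidationError):
            sm.infomax_unmix(bad)


class TestBackReconstruct:
    def test_exact_linear_model_recovered(self):
        # centered mixing and sources: X = A_true S is already centered, so
        # the least-squares fit must return A_true itself
        rng = np.random.default_rng(2)
        S = rng.standard_normal((3, 2000))
        S -= S.mean(axis=1, keepdims=True)
        A_true = rng.standard_normal((10, 3))
        A_true -= A_true.mean(axis=0, keepdims=True)
        X = A_true @ S
        A = sm.back_reconstruct(X, S)
        np.testing.assert_allclose(A, A_true, atol=1e-8)
        np.testing.assert_allclose(A @ S, X, atol=1e-8)

    def test_duplicated_subject_row_duplicates_mixing_row(self):
        rng = np.random.default_rng(6)
        S = rng.standard_normal((2, 500))
        X = rng.standard_normal((5, 2)) @ S
        X2 = np.vstack([X, X[1]])
        A2 = sm.back_reconstruct(X2, S)
        np.testing.assert_allclose(A2[5], A2[1], atol=1e-10)

    def test_residual_bounded_by_discarded_variance(self, measure, decomposition):
        wh = decomposition.whitening
        Xc = sm.center_measure_matrix(measure.values)
        resid = Xc - decomposition.mixing @ decomposition.sources_z
        rel = np.linalg.norm(resid) ** 2 / np.linalg.norm(Xc) ** 2
        assert rel <= 1 - wh.retained_variance + 1e-6


class TestZscoreSignFix:
    def test_rows_standardized(self, decomposition):
        Sz = decomposition.sources_z
        np.testing.assert_allclose(Sz.mean(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(Sz.std(axis=1), 1, atol=1e-6)

    def test_negative_skew_row_flipped_product_invariant(self):
        rng = np.random.default_rng(8)
        # one right-skewed and one left-skewed standardized row
        s_pos = rng.gamma(2, 1, 3000)
        s_neg = -rng.gamma(2, 1, 3000)
        S = np.vstack([s_pos, s_neg])
        S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
        A = rng.standard_normal((7, 2))
        Sz, Az, means, sds = sm.zscore_and_sign_fix(S, A)
        from scipy.stats import skew

        assert skew(Sz, axis=1).min() >= 0
        np.testing.assert_allclose(Az @ Sz, A @ S, atol=1e-12)

    def test_zero_variance_row_rejected(self):
        S = np.vstack([np.ones(100), np.arange(100.0)])
        with pytest.raises(DegenerateComponentError):
            sm.zscore_and_sign_fix(S, np.ones((4, 2)))

    def test_blob_sources_need_no_flip(self):
        """Recovered blob sources are right-skewed, so the sign convention
        leaves them unflipped in almost all seeds."""
        flips = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = sm.SyntheticConfig(seed=seed)
            vs, _, gt = sm.synthesize_dataset(cfg)
            mm = sm.vectorize(vs, sm.build_mask(vs))
            res = sm.run_icasso(mm, 4, n_runs=1, seed=seed)
            ti, ei, corr = sm.match_sources(
                gt.true_sources[:, mm.mask.linear_index], res.sources_z
            )
            # a flip shows up as a negative matched correlation
            signed = np.corrcoef(
                gt.true_sources[:, mm.mask.linear_index], res.sources_z
            )[:4, 4:][ti, ei]
            flips += (signed < 0).sum()
        assert flips / (4 * n_seeds) <= 0.05


class TestIcasso:
    def test_single_run_is_degenerate_icasso(self, measure):
        res = sm.run_icasso(measure, 4, n_runs=1, seed=9)
        np.testing.assert_array_equal(res.stability_iq, np.ones(4))
        assert len(res.runs) == 1

    def test_components_stable_on_structured_data(self):
        cfg = sm.SyntheticConfig(
            k_true=3, group_effect=(0.0, 0.0, 0.0), noise_sd=0.05,
            clinical_link=None, seed=5,
        )
        vs, _, _ = sm.synthesize_dataset(cfg)
        mm = sm.vectorize(vs, sm.build_mask(vs))
        res = sm.run_icasso(mm, 3, n_runs=10, seed=5)
        assert res.stability_iq.min() >= 0.9

    def test_source_recovery_quality(self, measure, dataset, decomposition):
        vs, table, gt = dataset
        _, _, corr = sm.match_sources(
            gt.true_sources[:, measure.mask.linear_index], decomposition.sources_z
        )
        assert corr.mean() >= 0.95

    def test_auto_order_decompose_records_estimate(self, measure):
        res = sm.decompose(measure, k="auto", n_runs=1, seed=2, max_k=8)
        assert res.order_estimate is not None
        assert res.k == res.order_estimate.k_selected == 4
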