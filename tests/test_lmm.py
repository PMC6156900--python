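import numpy as np
import pytest
from scipy.stats import kstest

from famassoc.kinship import KinshipMatrix, exchangeable_family_matrix
from famassoc.lmm import (
    SingularDesignError,
    anova_variance_components,
    fit_all,
    fit_marker,
    gls_fit,
    reml_variance_components,
    restricted_loglik,
)
from famassoc.options import build_covariance_spec
from famassoc.simulate import SimulationConfig, simulate_dataset
from oracles import dense_reml_grid, dense_restricted_loglik


def _family_draw(rng, n_families, size, s2mu, s2eps, within=0.5):
    """Direct draw of one response under the generating model (no package
    simulator), exchangeable sibships, zero mean."""
    fam = np.repeat(np.arange(n_families), size)
    shared = rng.standard_normal(n_families)[fam]
    indiv = rng.standard_normal(n_families * size)
    mu = np.sqrt(s2mu) * (np.sqrt(within) * shared + np.sqrt(1 - within) * indiv)
    return mu + np.sqrt(s2eps) * rng.standard_normal(n_families * size)


class TestGlsFit:
    def test_identity_covariance_intercept_is_mean(self):
        beta, cov = gls_fit(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), np.eye(3))
        assert beta[0] == pytest.approx(2.0)

    def test_point_estimate_invariant_to_covariance_scale(self, rng):
        X = np.column_stack([np.ones(8), rng.standard_normal(8)])
        y = rng.standard_normal(8)
        b1, _ = gls_fit(y, X, np.eye(8))
        b2, _ = gls_fit(y, X, 7.3 * np.eye(8))
        assert b1 == pytest.approx(b2, rel=1e-12)

    def test_matches_textbook_formula_on_random_spd(self, rng):
        X = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        A = rng.standard_normal((6, 6))
        V = A @ A.T + 6 * np.eye(6)
        beta, cov = gls_fit(y, X, V)
        Vi = np.linalg.inv(V)
        beta_naive = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        cov_naive = np.linalg.inv(X.T @ Vi @ X)
        assert np.abs(beta - beta_naive).max() < 1e-10
        assert np.abs(cov - cov_naive).max() < 1e-10

    def test_singular_inputs_raise_with_diagnostic(self, rng):
        X = np.ones((5, 2))  # duplicated column
        with pytest.raises(SingularDesignError, match="condition number"):
            gls_fit(rng.standard_normal(5), X, np.eye(5))
        with pytest.raises(SingularDesignError):
            gls_fit(rng.standard_normal(5), X[:, :1], np.zeros((5, 5)))


class TestRemlSpectral:
    def test_restricted_loglik_matches_dense_oracle(self, rng):
        """Spectral and dense restricted log-likelihoods agree to 1e-8 at
        20 random variance ratios, n = 15."""
        K = exchangeable_family_matrix(5, 3, 0.5).values
        X = np.column_stack([np.ones(15), rng.standard_normal(15)])
        y = rng.standard_normal(15) + 0.3
        for lam in np.exp(rng.uniform(-3, 3, size=20)):
            spectral = restricted_loglik(y, X, K, float(lam), 1.0)
            dense = dense_restricted_loglik(y, X, K, float(lam), 1.0)
            assert spectral == pytest.approx(dense, abs=1e-8)

    def test_estimates_agree_with_dense_grid_oracle(self, rng):
        """On one simulated response the spectral REML optimum matches an
        independent dense grid search over the same ratio range."""
        K = exchangeable_family_matrix(40, 5, 0.5)
        y = _family_draw(rng, 40, 5, s2mu=2.0, s2eps=1.0)
        X = np.ones((200, 1))
        vc = reml_variance_components(y, X, K)
        mu_oracle, eps_oracle = dense_reml_grid(
            y, X, K.values, np.linspace(-4, 4, 600)
        )
        assert vc.sigma2_mu == pytest.approx(mu_oracle, abs=0.05)
        assert vc.sigma2_eps == pytest.approx(eps_oracle, abs=0.05)

    def test_constant_response_gives_zero_components(self):
        K = exchangeable_family_matrix(5, 4, 0.5)
        vc = reml_variance_components(np.full(20, 3.0), np.ones((20, 1)), K)
        assert (vc.sigma2_mu, vc.sigma2_eps) == (0.0, 0.0)
        assert vc.converged

    def test_identity_K_resolves_to_boundary(self, rng):
        """With K = I the ratio is unidentifiable; the documented tie-break
        is sigma2_mu = 0 and sigma2_eps = the residual mean square."""
        y = rng.standard_normal(30)
        X = np.ones((30, 1))
        vc = reml_variance_components(y, X, np.eye(30))
        assert vc.sigma2_mu == 0.0
        assert vc.boundary
        resid = y - y.mean()
        assert vc.sigma2_eps == pytest.approx(resid @ resid / 29, rel=1e-6)

    def test_singular_design_rejected(self, rng):
        with pytest.raises(SingularDesignError):
            reml_variance_components(
                rng.standard_normal(10), np.ones((10, 2)), np.eye(10)
            )


class TestAnovaMom:
    @staticmethod
    def _raw_he_estimate(y, X, K):
        """Unclamped Haseman-Elston moment estimate (independent oracle)."""
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        e = y - X @ beta
        iu = np.triu_indices(len(y), k=1)
        k_off = K[iu]
        return float(np.sum(k_off * e[iu[0]] * e[iu[1]]) / np.sum(k_off**2))

    def test_zero_family_variance_recovered_on_average(self, rng):
        """Data generated under independence: the signed moment estimate
        averages to zero within 3 SE over 100 replicates, and the reported
        estimate is its clamp at zero."""
        K = exchangeable_family_matrix(25, 4, 0.5)
        X = np.ones((100, 1))
        raw, clamped = [], []
        for _ in range(100):
            y = rng.standard_normal(100)
            vc = anova_variance_components(y, X, K)
            clamped.append(vc.sigma2_mu)
            raw.append(self._raw_he_estimate(y, X, K.values))
        raw, clamped = np.array(raw), np.array(clamped)
        assert abs(raw.mean()) <= 3 * raw.std(ddof=1) / 10
        assert np.allclose(clamped, np.maximum(raw, 0.0), atol=1e-10)

    def test_unbiased_but_noisier_than_reml(self, rng):
        """On unbalanced sibships (sizes 2-8) both estimators are centered
        on the truth but the moment estimator has the wider replicate
        spread, since it weights all relative pairs equally."""
        import scipy.linalg as sla

        sizes = [2, 3, 4, 5, 6, 7, 8] * 6
        blocks = []
        for s in sizes:
            b = np.full((s, s), 0.5)
            np.fill_diagonal(b, 1.0)
            blocks.append(b)
        Kv = sla.block_diag(*blocks)
        n = Kv.shape[0]
        K = KinshipMatrix(tuple(f"I{i}" for i in range(n)), Kv)
        L = np.linalg.cholesky(Kv + 1e-10 * np.eye(n))
        X = np.ones((n, 1))
        mom, reml = [], []
        for _ in range(60):
            y = np.sqrt(2.0) * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
            mom.append(anova_variance_components(y, X, K).sigma2_mu)
            reml.append(reml_variance_components(y, X, K).sigma2_mu)
        mom, reml = np.array(mom), np.array(reml)
        for est in (mom, reml):
            assert abs(est.mean() - 2.0) <= 3 * est.std(ddof=1) / np.sqrt(60)
        assert mom.std(ddof=1) > reml.std(ddof=1)

    def test_constant_offdiagonal_K_rejected(self, rng):
        with pytest.raises(ValueError, match="off-diagonal"):
            anova_variance_components(
                rng.standard_normal(10), np.ones((10, 1)), np.eye(10)
            )

    def test_constant_response_gives_zero(self):
        K = exchangeable_family_matrix(5, 2, 0.5)
        vc = anova_variance_components(np.ones(10), np.ones((10, 1)), K)
        assert (vc.sigma2_mu, vc.sigma2_eps) == (0.0, 0.0)


class TestFitMarker:
    def test_kinship_with_identity_K_collapses_to_independence(self, rng):
        n = 60
        ids = tuple(f"I{i}" for i in range(n))
        K = KinshipMatrix.identity(ids)
        y = rng.standard_normal(n) + 0.2
        X = np.ones((n, 1))
        kin = fit_marker(y, X, build_covariance_spec("kinship", K))
        ind = fit_marker(y, X, build_covariance_spec("independence", K))
        assert kin.p_value == pytest.approx(ind.p_value, abs=1e-8)
        assert kin.std_error == pytest.approx(ind.std_error, rel=1e-8)

    def test_representative_option_uses_one_per_family(self, small_config):
        ds = simulate_dataset(small_config)
        table = fit_all(ds, "representative", representative_seed=5)
        assert (table["n_used"] == small_config.n_families).all()

    def test_t_reference_gives_larger_p_than_normal(self, rng):
        n = 12
        ids = tuple(f"I{i}" for i in range(n))
        K = KinshipMatrix.identity(ids)
        spec = build_covariance_spec("independence", K)
        y = rng.standard_normal(n) + 1.0
        X = np.ones((n, 1))
        normal = fit_marker(y, X, spec)
        student = fit_marker(y, X, spec, use_t=True)
        assert student.p_value > normal.p_value
        assert student.estimate == normal.estimate

    def test_statistic_identity_and_p_range(self, small_config):
        ds = simulate_dataset(small_config)
        for option, seed in [("kinship", None), ("independence", None),
                             ("representative", 1)]:
            table = fit_all(ds, option, representative_seed=seed)
            assert np.allclose(
                table["statistic"], table["estimate"] / table["std_error"]
            )
            assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()


class TestFitAll:
    def test_deterministic_given_seeds(self, small_config):
        ds = simulate_dataset(small_config)
        a = fit_all(ds, "representative", representative_seed=3)
        b = fit_all(ds, "representative", representative_seed=3)
        assert a.equals(b)

    def test_one_row_per_marker(self, small_config):
        ds = simulate_dataset(small_config)
        table = fit_all(ds, "kinship")
        assert len(table) == small_config.m_markers
        assert list(table["marker_id"]) == list(ds.marker_ids)

    def test_fit_all_kinship_matches_fit_marker(self, small_config):
        ds = simulate_dataset(small_config)
        table = fit_all(ds, "kinship")
        spec = build_covariance_spec("kinship", ds.kinship)
        for j in (0, 17, 63):
            single = fit_marker(
                ds.responses[:, j], ds.covariates, spec, marker_id=ds.marker_ids[j]
            )
            # batched and single-marker rotations differ by float roundoff,
            # which propagates through the 1e-8 ratio refinement
            row = table.iloc[j]
            assert row["p_value"] == pytest.approx(single.p_value, rel=1e-6)
            assert row["sigma2_mu"] == pytest.approx(
                single.variance_components.sigma2_mu, rel=1e-4, abs=1e-7
            )

    def test_fit_all_ols_matches_fit_marker(self, small_config):
        ds = simulate_dataset(small_config)
        table = fit_all(ds, "independence")
        spec = build_covariance_spec("independence", ds.kinship)
        for j in (0, 55):
            single = fit_marker(ds.responses[:, j], ds.covariates, spec)
            assert table.iloc[j]["p_value"] == pytest.approx(single.p_value, rel=1e-10)

    def test_strong_signals_rank_first_under_kinship(self):
        """With a 3-sigma mean shift the causal markers own the smallest
        kinship-option p-values."""
        cfg = SimulationConfig(
            n_families=60,
            family_size=4,
            m_markers=300,
            m_causal=10,
            effect_delta=3.0 * np.sqrt(2.0),
            seed=8,
        )
        ds = simulate_dataset(cfg)
        table = fit_all(ds, "kinship")
        top10 = set(table.nsmallest(10, "p_value")["marker_id"])
        assert top10 == set(ds.causal_ids)

    def test_null_kinship_p_values_are_uniform(self):
        """Kolmogorov-Smirnov check of p-value uniformity under the null."""
        cfg = SimulationConfig(m_markers=1000, m_causal=0, seed=23)
        ds = simulate_dataset(cfg)
        table = fit_all(ds, "kinship")
        assert kstest(table["p_value"], "uniform").pvalue > 0.01

    def test_anova_mom_variant_runs_and_agrees_roughly(self, small_config):
        ds = simulate_dataset(small_config)
        reml = fit_all(ds, "kinship", vc_method="reml")
        mom = fit_all(ds, "kinship", vc_method="anova_mom")
        # same data, two variance estimators: estimates correlate strongly
        r = np.corrcoef(reml["estimate"], mom["estimate"])[0, 1]
        assert r > 0.99
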