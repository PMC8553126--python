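"""Mixed models: kinship, design building, REML, GLS and the F test."""

import numpy as np
import pytest

from leafgwas import simulate as sim
from leafgwas.lmm import (
    MixedModelScanner,
    MultiVarComp,
    RCBDDesign,
    build_fixed_design,
    f_test,
    gls_fit,
    heritability,
    kinship_fullsib,
    pve_from_rss,
    reml_multivariate,
    reml_univariate,
)


class TestKinship:
    def test_three_clones(self):
        expected = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        assert np.array_equal(kinship_fullsib(3), expected)

    def test_single_clone(self):
        assert np.array_equal(kinship_fullsib(1), np.eye(1))

    def test_closed_form_eigenvalues(self):
        w = np.sort(np.linalg.eigvalsh(kinship_fullsib(10)))
        assert w[-1] == pytest.approx(5.5)
        assert w[:-1] == pytest.approx(np.full(9, 0.5))

    def test_kinship_coefficient_is_quarter(self):
        A = kinship_fullsib(5)
        assert (A[np.triu_indices(5, 1)] / 2 == 0.25).all()

    def test_rejects_empty_family(self):
        with pytest.raises(ValueError):
            kinship_fullsib(0)


def _design(n_blocks=3, n_clones=8, reps=2):
    block = np.repeat(np.arange(n_blocks), n_clones * reps)
    clone = np.tile(np.repeat(np.arange(n_clones), reps), n_blocks)
    return RCBDDesign(block=block, clone=clone, n_blocks=n_blocks,
                      n_clones=n_clones)


class TestFixedDesign:
    def test_two_class_snp_column_count(self):
        d = _design()
        X, keep, g, gcols = build_fixed_design(d, np.array([0, 1] * 4))
        assert X.shape[1] == 1 + 2 + 1  # intercept + 2 blocks + 1 genotype
        assert g == 2 and keep.all() and gcols == [3]

    def test_monomorphic_snp_untestable(self):
        d = _design()
        X, _, g, _ = build_fixed_design(d, np.zeros(8, dtype=int))
        assert X is None and g == 1

    def test_four_class_snp(self):
        d = _design()
        X, _, g, gcols = build_fixed_design(d, np.array([0, 1, 2, 3] * 2))
        assert g == 4 and len(gcols) == 3

    def test_missing_clones_dropped(self):
        d = _design()
        codes = np.array([0, 1, -1, 1, 0, -1, 1, 0])
        X, keep, g, _ = build_fixed_design(d, codes)
        assert keep.sum() == 6 * 3 * 2  # 6 of 8 clones kept, 6 trees each
        assert X.shape[0] == keep.sum()

    def test_empty_class_column_omitted(self):
        d = _design()
        codes = np.array([0, 2, -1, 2, 0, -1, 2, 0])  # class 1 absent
        X, _, g, gcols = build_fixed_design(d, codes)
        assert g == 2 and len(gcols) == 1


class TestHeritability:
    @pytest.mark.parametrize("sg,se,h2", [(1, 1, 0.5), (0, 2, 0.0), (3, 1, 0.75)])
    def test_values(self, sg, se, h2):
        assert heritability(sg, se) == pytest.approx(h2)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)


class TestRemlUnivariate:
    def test_null_genetic_variance_recovered_at_boundary(self):
        trial = sim.TrialConfig(V_G=np.zeros((1, 1)), V_E=np.eye(1), n_blocks=3,
                                cuttings_per_plot=5, survival_rate=1.0, seed=31)
        phen = sim.simulate_rcbd_phenotypes(trial, n_clones=100)
        d = RCBDDesign.from_table(phen)
        vc = reml_univariate(phen["trait_1"].to_numpy(),
                             d.base_design_matrix(), d.clone)
        assert vc.sigma_g2 < 0.05
        assert heritability(vc.sigma_g2, vc.sigma_e2) < 0.05

    def test_matches_statsmodels_with_identity_kinship(self):
        """cov(g) = sigma_g^2 I_c is the vanilla random-intercept model."""
        import statsmodels.api as smapi

        trial = sim.TrialConfig(V_G=np.eye(1), V_E=np.eye(1), n_blocks=2,
                                cuttings_per_plot=4, survival_rate=1.0, seed=5)
        phen = sim.simulate_rcbd_phenotypes(trial, n_clones=40)
        d = RCBDDesign.from_table(phen)
        X = d.base_design_matrix()
        y = phen["trait_1"].to_numpy()
        vc = reml_univariate(y, X, d.clone, A=None)
        md = smapi.MixedLM(y, X, groups=d.clone).fit(reml=True)
        assert vc.sigma_g2 == pytest.approx(float(np.asarray(md.cov_re)[0, 0]), rel=1e-3)
        assert vc.sigma_e2 == pytest.approx(float(md.scale), rel=1e-3)

    def test_matches_dense_grid_oracle_with_fullsib_kinship(self):
        """Direct dense restricted likelihood maximized on a grid agrees."""
        from scipy import optimize as opt
        from scipy.linalg import cho_factor, cho_solve

        trial = sim.TrialConfig(V_G=np.eye(1), V_E=np.eye(1), n_blocks=2,
                                cuttings_per_plot=3, survival_rate=1.0, seed=8)
        phen = sim.simulate_rcbd_phenotypes(trial, n_clones=20)
        d = RCBDDesign.from_table(phen)
        X = d.base_design_matrix()
        y = phen["trait_1"].to_numpy()
        n, p = X.shape
        Z = np.zeros((n, d.n_clones))
        Z[np.arange(n), d.clone] = 1.0
        K = Z @ kinship_fullsib(d.n_clones) @ Z.T

        def neg2(theta):
            sg, se = np.exp(theta)
            V = sg * K + se * np.eye(n)
            cf = cho_factor(V)
            ViX = cho_solve(cf, X)
            W = X.T @ ViX
            b = np.linalg.solve(W, ViX.T @ y)
            r = y - X @ b
            logdet_v = 2 * np.log(np.diag(cf[0])).sum()
            return (logdet_v + np.linalg.slogdet(W)[1]
                    + float(r @ cho_solve(cf, r)))

        res = opt.minimize(neg2, np.log([1.0, 1.0]), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
        sg_o, se_o = np.exp(res.x)
        vc = reml_univariate(y, X, d.clone)
        assert vc.sigma_g2 == pytest.approx(sg_o, rel=1e-4)
        assert vc.sigma_e2 == pytest.approx(se_o, rel=1e-4)

    def test_restricted_likelihood_locally_optimal(self):
        trial = sim.TrialConfig(V_G=np.eye(1), V_E=np.eye(1), n_blocks=3,
                                cuttings_per_plot=4, survival_rate=1.0, seed=12)
        phen = sim.simulate_rcbd_phenotypes(trial, n_clones=60)
        d = RCBDDesign.from_table(phen)
        X = d.base_design_matrix()
        y = phen["trait_1"].to_numpy()
        vc = reml_univariate(y, X, d.clone)
        # the multivariate fitter evaluates the same restricted likelihood:
        # perturbing the optimum must not improve it
        base = reml_multivariate(y[:, None], X, d.clone)
        assert base.log_restricted_likelihood >= vc.log_restricted_likelihood - 1e-6


class TestRemlMultivariate:
    def test_t1_reduces_to_univariate(self, small_trial_phenotypes):
        phen = small_trial_phenotypes
        d = RCBDDesign.from_table(phen)
        X = d.base_design_matrix()
        y = phen["trait_1"].to_numpy()
        uni = reml_univariate(y, X, d.clone)
        mv = reml_multivariate(y[:, None], X, d.clone)
        assert mv.V_G[0, 0] == pytest.approx(uni.sigma_g2, rel=1e-4, abs=1e-8)
        assert mv.V_E[0, 0] == pytest.approx(uni.sigma_e2, rel=1e-4)

    def test_trait_permutation_equivariance(self, small_trial_phenotypes):
        phen = small_trial_phenotypes
        d = RCBDDesign.from_table(phen)
        X = d.base_design_matrix()
        Y = phen[["trait_1", "trait_2"]].to_numpy()
        a = reml_multivariate(Y, X, d.clone)
        b = reml_multivariate(Y[:, ::-1], X, d.clone)
        perm = np.array([[0, 1], [1, 0]], dtype=float)
        # optima agree up to optimizer tolerance
        assert np.allclose(perm @ a.V_G @ perm, b.V_G, atol=0.02)
        assert np.allclose(perm @ a.V_E @ perm, b.V_E, atol=0.02)

    def test_rejects_too_many_traits(self):
        with pytest.raises(ValueError, match="ill-posed"):
            reml_multivariate(np.zeros((10, 6)), np.ones((10, 1)),
                              np.repeat(np.arange(5), 2))


def _dense_V(design, vg, ve):
    n = design.n_trees
    Z = np.zeros((n, design.n_clones))
    Z[np.arange(n), design.clone] = 1.0
    K = Z @ kinship_fullsib(design.n_clones) @ Z.T
    return np.kron(vg, K) + np.kron(ve, np.eye(n))


class TestGlsAndFTest:
    def test_identity_covariance_is_ols(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(12), rng.standard_normal(12)])
        Y = rng.standard_normal((12, 2))
        fit = gls_fit(Y, X, np.eye(24))
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.allclose(fit.B_hat, ols, atol=1e-10)

    def test_intercept_only_gives_trait_means(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((9, 3))
        fit = gls_fit(Y, np.ones((9, 1)), np.eye(27))
        assert np.allclose(fit.B_hat.ravel(), Y.mean(axis=0))

    def test_small_instance_matches_dense_vectorized_solve(self):
        """n=6, t=2 worked instance against an independently assembled
        kron-system normal-equation solve."""
        rng = np.random.default_rng(9)
        n, t = 6, 2
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
        Y = rng.standard_normal((n, t))
        A = rng.standard_normal((n * t, n * t))
        V = A @ A.T / 10 + np.eye(n * t)
        fit = gls_fit(Y, X, V)
        XK = np.kron(np.eye(t), X)
        Vi = np.linalg.inv(V)
        b_oracle = np.linalg.solve(XK.T @ Vi @ XK, XK.T @ Vi @ Y.ravel(order="F"))
        assert np.allclose(fit.B_hat.ravel(order="F"), b_oracle, atol=1e-9)
        r = Y.ravel(order="F") - XK @ b_oracle
        assert fit.RSS == pytest.approx(float(r @ Vi @ r), rel=1e-9)

    def test_f_equals_squared_t_for_single_contrast(self):
        rng = np.random.default_rng(11)
        n = 30
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
        y = rng.standard_normal((n, 1))
        fit = gls_fit(y, X, np.eye(n))
        M = np.array([[0.0, 1.0]])
        res = f_test(fit, M, t=1, n=n, p=2)
        se = np.sqrt(np.linalg.inv(fit.W)[1, 1])
        t_stat = fit.B_hat[1, 0] / se
        assert res.F == pytest.approx(t_stat**2, rel=1e-10)
        assert res.df2 == n - 2

    def test_scanner_agrees_with_dense_path(self, small_trial_phenotypes):
        phen = small_trial_phenotypes
        d = RCBDDesign.from_table(phen)
        Y = phen[["trait_1", "trait_2"]].to_numpy()
        vg = np.array([[1.0, 0.3], [0.3, 0.8]])
        ve = np.array([[1.0, 0.2], [0.2, 1.5]])
        codes = np.random.default_rng(3).integers(0, 2, d.n_clones)
        vc = MultiVarComp(vg, ve, 0.0, 0, True)
        res = MixedModelScanner(Y, d, vc).test_snp(codes)
        X, keep, g, gcols = build_fixed_design(d, codes)
        V = _dense_V(d, vg, ve)
        fit = gls_fit(Y, X, V)
        t, p = 2, X.shape[1]
        M = np.zeros(((g - 1) * t, p * t))
        for tt in range(t):
            for i, col in enumerate(gcols):
                M[tt * (g - 1) + i, tt * p + col] = 1.0
        dense = f_test(fit, M, t=t, n=d.n_trees, p=p)
        assert res.F == pytest.approx(dense.F, rel=1e-8)
        assert res.p_value == pytest.approx(dense.p_value, rel=1e-8)
        assert res.RSS == pytest.approx(fit.RSS, rel=1e-8)
        assert res.df2 == dense.df2

    def test_degrees_of_freedom_arithmetic(self):
        d = _design(n_blocks=3, n_clones=40, reps=2)
        rng = np.random.default_rng(0)
        t = 11
        Y = rng.standard_normal((d.n_trees, t))
        vc = MultiVarComp(np.eye(t), np.eye(t), 0.0, 0, True)
        res = MixedModelScanner(Y, d, vc).test_snp(rng.integers(0, 2, 40))
        p = 1 + 2 + 1
        assert res.q == 11
        assert res.df2 == 11 * (d.n_trees - p)

    def test_trait_rescaling_leaves_f_invariant(self, small_trial_phenotypes):
        phen = small_trial_phenotypes
        d = RCBDDesign.from_table(phen)
        Y = phen[["trait_1", "trait_2"]].to_numpy()
        codes = np.random.default_rng(5).integers(0, 2, d.n_clones)
        vg = np.array([[1.0, 0.3], [0.3, 0.8]])
        ve = np.array([[1.0, 0.2], [0.2, 1.5]])
        S = np.diag([1.0, 7.5])
        res1 = MixedModelScanner(Y, d, MultiVarComp(vg, ve, 0, 0, True)).test_snp(codes)
        res2 = MixedModelScanner(
            Y @ S, d, MultiVarComp(S @ vg @ S, S @ ve @ S, 0, 0, True)
        ).test_snp(codes)
        assert res2.F == pytest.approx(res1.F, rel=1e-9)
        assert res2.pve == pytest.approx(res1.pve, rel=1e-6)

    def test_exact_mode_close_to_p3d_on_null_data(self, small_trial_phenotypes):
        phen = small_trial_phenotypes
        d = RCBDDesign.from_table(phen)
        X0 = d.base_design_matrix()
        Y = phen[["trait_1", "trait_2"]].to_numpy()
        vc = reml_multivariate(Y, X0, d.clone)
        scanner = MixedModelScanner(Y, d, vc)
        codes = np.random.default_rng(8).integers(0, 2, d.n_clones)
        p3d = scanner.test_snp(codes)
        exact = scanner.test_snp(codes, exact=True)
        assert exact.p_value == pytest.approx(p3d.p_value, rel=0.2)


class TestPve:
    def test_bounds(self):
        assert pve_from_rss(1000.0, 1000.0) == 0.0
        assert pve_from_rss(0.0, 1000.0) == 1.0
        assert pve_from_rss(998.0, 1000.0) == pytest.approx(0.002)

    def test_clipping_and_errors(self):
        assert pve_from_rss(1001.0, 1000.0) == 0.0
        with pytest.raises(ValueError):
            pve_from_rss(1.0, 0.0)
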