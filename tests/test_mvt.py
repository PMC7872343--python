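import math

import numpy as np
import pytest
from scipy import integrate, stats

from triscore import (
    CorrelationModel,
    DegenerateModelError,
    TScoreDistribution,
    category_coverage,
    conditional_distribution,
    joint_pdf,
    mahalanobis2,
    marginal_distribution,
)


class TestCorrelationModel:
    def test_matrix_is_symmetric_with_unit_diagonal(self, real_corr_model):
        R = real_corr_model.matrix
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)

    @pytest.mark.parametrize("rhos", [(0.9, 0.9, -0.9), (0.99, -0.99, 0.99), (1.0, 0.0, 0.0)])
    def test_non_positive_definite_rejected(self, rhos):
        with pytest.raises(DegenerateModelError):
            CorrelationModel(*rhos)

    @pytest.mark.parametrize("method", ["symmetric_sqrt", "cholesky"])
    def test_sqrt_factorizes_matrix(self, real_corr_model, method):
        S = real_corr_model.sqrt(method)
        assert np.allclose(S @ S.T, real_corr_model.matrix, atol=1e-12)

    def test_symmetric_sqrt_is_symmetric(self, equicorr06):
        S = equicorr06.sqrt("symmetric_sqrt")
        assert np.allclose(S, S.T)

    def test_from_matrix_round_trip(self, real_corr_model):
        again = CorrelationModel.from_matrix(real_corr_model.matrix)
        assert again == real_corr_model


class TestMahalanobis:
    def test_zero_at_center(self, real_corr_model):
        assert mahalanobis2((0, 0, 0), real_corr_model) == 0.0
        assert mahalanobis2((1.3, -2, 0.4), real_corr_model, center=(1.3, -2, 0.4)) == pytest.approx(0.0, abs=1e-12)

    def test_identity_model_is_euclidean(self, identity_model):
        assert mahalanobis2((-2.5, 0, 0), identity_model) == pytest.approx(6.25)

    def test_equicorrelated_closed_form(self, equicorr06):
        # (1,1,1) is an eigenvector of R with eigenvalue 1+2*rho, so
        # d2((-1,-1,-1)) = 3/(1+2*rho); cross-check by explicit inversion
        d2 = mahalanobis2((-1, -1, -1), equicorr06)
        assert d2 == pytest.approx(3 / 2.2, rel=1e-12)
        x = np.array([-1.0, -1.0, -1.0])
        explicit = x @ np.linalg.inv(equicorr06.matrix) @ x
        assert d2 == pytest.approx(explicit, rel=1e-12)

    def test_sign_flip_symmetry(self, real_corr_model):
        x = np.array([1.7, -0.3, 2.2])
        assert mahalanobis2(x, real_corr_model) == pytest.approx(
            mahalanobis2(-x, real_corr_model), rel=1e-12
        )

    def test_chi2_law_of_normal_sample(self, real_corr_model):
        # d^2 of a zero-centered trivariate normal sample follows chi2_3
        # regardless of the correlation structure
        rng = np.random.default_rng(2024)
        S = real_corr_model.sqrt("symmetric_sqrt")
        x = rng.standard_normal((100_000, 3)) @ S.T
        d2 = mahalanobis2(x, real_corr_model)
        ks = stats.kstest(d2, stats.chi2(df=3).cdf)
        assert ks.pvalue > 0.01


class TestJointPdf:
    def test_standard_normal_mode(self, identity_model):
        dist = TScoreDistribution(identity_model)
        assert joint_pdf((0, 0, 0), dist) == pytest.approx((2 * math.pi) ** -1.5, rel=1e-12)

    @pytest.mark.parametrize("reference_n", [10, math.inf])
    def test_unimodal_at_center(self, real_corr_model, reference_n):
        dist = TScoreDistribution(real_corr_model, reference_n=reference_n)
        rng = np.random.default_rng(7)
        pts = rng.uniform(-4, 4, size=(200, 3))
        assert joint_pdf((0, 0, 0), dist) > joint_pdf(pts, dist).max()

    def test_normal_density_integrates_to_one(self, equicorr06):
        dist = TScoreDistribution(equicorr06)
        g = np.linspace(-8, 8, 121)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
        vals = joint_pdf(pts, dist).reshape(121, 121, 121)
        total = np.trapezoid(np.trapezoid(np.trapezoid(vals, g), g), g)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_student_density_integrates_to_one(self):
        # heavy t(5) tails: extend the grid far beyond +-8 with log spacing
        model = CorrelationModel.equicorrelation(0.4)
        dist = TScoreDistribution(model, reference_n=6)  # dof = 5
        assert dist.dof == 5
        core = np.linspace(-8, 8, 101)
        tail = np.geomspace(8, 2000, 41)
        g = np.unique(np.concatenate([-tail, core, tail]))
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
        vals = joint_pdf(pts, dist).reshape(len(g), len(g), len(g))
        total = np.trapezoid(np.trapezoid(np.trapezoid(vals, g), g), g)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_converges_to_normal_as_reference_grows(self, equicorr06):
        normal = TScoreDistribution(equicorr06)
        g = np.linspace(-4, 4, 9)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
        ref = joint_pdf(pts, normal)
        sups = []
        for m in (10, 100, 10_000):
            dist = TScoreDistribution(equicorr06, reference_n=m)
            sups.append(np.abs(joint_pdf(pts, dist) - ref).max())
        assert sups[0] > sups[1] > sups[2]
        assert sups[2] < 1e-3


class TestMarginal:
    def test_standard_normal_limit(self, identity_model):
        dist = TScoreDistribution(identity_model)
        marg = marginal_distribution(dist, 0)
        assert marg.pdf(0) == pytest.approx(1 / math.sqrt(2 * math.pi), rel=1e-12)

    def test_equicorrelated_marginals_coincide(self, equicorr06):
        dist = TScoreDistribution(equicorr06, reference_n=25)
        x = np.linspace(-3, 3, 7)
        p0 = marginal_distribution(dist, 0).pdf(x)
        for i in (1, 2):
            assert np.allclose(marginal_distribution(dist, i).pdf(x), p0)

    @pytest.mark.parametrize("reference_n", [12, math.inf])
    def test_marginal_matches_quadrature_of_joint(self, real_corr_model, reference_n):
        dist = TScoreDistribution(real_corr_model, reference_n=reference_n)
        marg = marginal_distribution(dist, 1)
        for x in (-2.5, -1.0, 0.0, 0.7, 2.0):
            num, _ = integrate.dblquad(
                lambda z, y: joint_pdf((y, x, z), dist),
                -8, 8, -8, 8, epsabs=1e-8,
            )
            assert num == pytest.approx(marg.pdf(x), abs=1e-5)

    def test_site_index_validated(self, identity_model):
        with pytest.raises(IndexError):
            marginal_distribution(TScoreDistribution(identity_model), 3)


class TestConditional:
    def test_independent_target_reduces_to_marginal(self):
        model = CorrelationModel(0.0, 0.0, 0.7)  # spine independent of neck+hip
        dist = TScoreDistribution(model, reference_n=20)
        cond = conditional_distribution(dist, 0, observed=(-2.0, 1.0))
        marg = marginal_distribution(dist, 0)
        x = np.linspace(-3, 3, 11)
        # same location/scale family up to the dof bump: densities must agree
        # at the center and the scale must be uninflated only in the normal
        # limit, so compare the full normal-limit case exactly
        norm_dist = TScoreDistribution(model)
        cond_n = conditional_distribution(norm_dist, 0, observed=(-2.0, 1.0))
        marg_n = marginal_distribution(norm_dist, 0)
        assert np.allclose(cond_n.pdf(x), marg_n.pdf(x), atol=1e-12)
        assert cond.mean() == pytest.approx(marg.mean(), abs=1e-12)

    @pytest.mark.parametrize("rho", [0.2, 0.6, 0.8])
    @pytest.mark.parametrize("x", [-2.0, -0.5, 1.5])
    def test_normal_theory_conditional_mean(self, rho, x):
        # nu=inf, equicorrelation rho, both observed equal to x:
        # E[T1 | T2 = T3 = x] = 2 rho x / (1 + rho); cross-check by solving
        # the normal equations directly
        model = CorrelationModel.equicorrelation(rho)
        dist = TScoreDistribution(model)
        cond = conditional_distribution(dist, 0, observed=(x, x))
        assert cond.mean() == pytest.approx(2 * rho * x / (1 + rho), rel=1e-12)
        R = model.matrix
        w = np.linalg.solve(R[1:, 1:], np.array([x, x]))
        assert cond.mean() == pytest.approx(R[0, 1:] @ w, rel=1e-12)

    @pytest.mark.parametrize("reference_n", [9, math.inf])
    def test_factorization_joint_equals_conditional_times_block(self, real_corr_model, reference_n):
        dist = TScoreDistribution(real_corr_model, reference_n=reference_n)
        rng = np.random.default_rng(11)
        pts = rng.uniform(-3, 3, size=(10, 3))
        S = dist.scale
        for p in pts:
            for target in (0, 1, 2):
                others = [i for i in range(3) if i != target]
                cond = conditional_distribution(dist, target, observed=p[others])
                if math.isinf(dist.dof):
                    block = stats.multivariate_normal(mean=np.zeros(2), cov=S[np.ix_(others, others)])
                else:
                    block = stats.multivariate_t(loc=np.zeros(2), shape=S[np.ix_(others, others)], df=dist.dof)
                lhs = joint_pdf(p, dist)
                rhs = cond.pdf(p[target]) * block.pdf(p[others])
                assert rhs == pytest.approx(lhs, rel=1e-8)

    def test_degenerate_observed_block_raises(self):
        with pytest.raises((DegenerateModelError, ValueError)):
            conditional_distribution(
                TScoreDistribution(CorrelationModel.equicorrelation(0.5)),
                0, observed=(1.0, float("nan")),
            )


class TestCategoryCoverage:
    def test_normal_limit_closed_form(self, identity_model):
        p_op, p_pen, p_norm = category_coverage(identity_model)
        assert p_op == pytest.approx(0.5 * stats.chi2.sf(6.25, 3), rel=1e-12)
        assert p_pen == pytest.approx(0.5 * (stats.chi2.sf(1, 3) - stats.chi2.sf(6.25, 3)), rel=1e-12)
        assert p_op + p_pen + p_norm == pytest.approx(1.0, abs=1e-15)

    def test_invariant_to_correlation(self, real_corr_model):
        for rho in (0.0, 0.8):
            assert category_coverage(CorrelationModel.equicorrelation(rho)) == category_coverage(real_corr_model)

    def test_finite_dof_uses_scaled_f_law(self):
        p_op, p_pen, p_norm = category_coverage(dof=9)
        assert p_op == pytest.approx(0.5 * stats.f.sf(6.25 / 3, 3, 9), rel=1e-12)
        # heavier tails than the normal limit put more mass outside d=2.5
        assert p_op > category_coverage()[0]
        assert p_op + p_pen + p_norm == pytest.approx(1.0)

    def test_radii_must_be_ordered(self):
        with pytest.raises(ValueError):
            category_coverage(radii=(2.5, 1.0))
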