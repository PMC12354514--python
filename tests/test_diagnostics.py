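"""Curvature measures, critical curvature and Box bias.

Oracles: analytic derivatives of simple test models, the homogeneity
identity d r/d a = r/a for the scale parameter, Monte-Carlo sphere averages
of the directional curvature, and algebraic scaling laws.
"""

import numpy as np
import pytest

from leafgielis import (
    GielisParameters,
    box_bias,
    critical_curvature,
    model_derivatives,
    rms_relative_curvatures,
    sge_radius,
)
from leafgielis.diagnostics import (
    DerivativeArrays,
    curvature_faces,
    diagnose,
    finite_difference_derivatives,
)
from leafgielis.model import fit_leaf
from leafgielis.superformula import SGEVariant


def mc_rms_curvature(faces, n_dirs=100_000, seed=0):
    """Sphere-average oracle: RMS of gamma(d) over uniform directions."""
    if faces.size == 0:
        return 0.0
    p = faces.shape[1]
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_dirs, p))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    vals = np.einsum("kp,mpq,kq->km", d, faces, d)
    return float(np.sqrt(np.mean(np.sum(vals**2, axis=1))))


def linear_arrays(n=30, sigma=0.1):
    t = np.linspace(0.0, 1.0, n)

    def predict(phi):
        return phi[0] + phi[1] * t

    V, W = finite_difference_derivatives(predict, np.array([2.0, -1.0]))
    return DerivativeArrays(V=V, W=W, s=sigma), t


def exponential_arrays(phi=1.0, sigma=0.05, n=10):
    t = np.linspace(0.0, 1.0, n)

    def predict(p):
        return np.exp(p[0] * t)

    V, W = finite_difference_derivatives(predict, np.array([phi]))
    return DerivativeArrays(V=V, W=W, s=sigma), t


class TestFiniteDifferences:
    def test_linear_model_exact(self):
        D, t = linear_arrays()
        np.testing.assert_allclose(D.V[:, 0], 1.0, atol=1e-8)
        np.testing.assert_allclose(D.V[:, 1], t, atol=1e-8)
        assert np.max(np.abs(D.W)) < 1e-8

    def test_exponential_matches_analytic(self):
        D, t = exponential_arrays(phi=1.0)
        np.testing.assert_allclose(D.V[:, 0], t * np.exp(t), rtol=1e-7,
                                   atol=1e-9)
        np.testing.assert_allclose(D.W[:, 0, 0], t**2 * np.exp(t),
                                   rtol=1e-5, atol=1e-7)

    def test_scale_column_homogeneity_oracle(self, fitted_sge3):
        # d r / d a = r / a exactly, by homogeneity in a
        fit, polar = fitted_sge3
        D, mask = model_derivatives(polar, fit.estimate)
        r_hat = sge_radius(polar.theta[mask], fit.estimate)
        np.testing.assert_allclose(D.V[:, 0], r_hat / fit.estimate.a,
                                   rtol=1e-6)

    def test_rank_deficiency_detected(self):
        t = np.linspace(0.0, 1.0, 20)

        def predict(phi):
            return (phi[0] + phi[1]) * t  # perfectly confounded pair

        V, W = finite_difference_derivatives(predict, np.array([1.0, 1.0]))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            DerivativeArrays(V=V, W=W, s=0.1)


class TestCurvatures:
    def test_linear_model_zero_curvature(self):
        D, _ = linear_arrays()
        gamma_N, gamma_T = rms_relative_curvatures(D)
        assert gamma_N < 1e-8 and gamma_T < 1e-8

    def test_closed_form_matches_sphere_average(self, fitted_sge3):
        fit, polar = fitted_sge3
        D, _ = model_derivatives(polar, fit.estimate)
        A_T, A_N, _ = curvature_faces(D)
        gamma_N, gamma_T = rms_relative_curvatures(D)
        assert gamma_N == pytest.approx(mc_rms_curvature(A_N), rel=0.01)
        assert gamma_T == pytest.approx(mc_rms_curvature(A_T), rel=0.01)

    def test_gammas_scale_linearly_in_s(self):
        D, _ = exponential_arrays()
        D2 = DerivativeArrays(V=D.V, W=D.W, s=2.0 * D.s)
        g1 = rms_relative_curvatures(D)
        g2 = rms_relative_curvatures(D2)
        np.testing.assert_allclose(g2, 2.0 * np.asarray(g1), rtol=1e-12)

    def test_intrinsic_invariant_under_reparameterization(self, fitted_sge3):
        fit, polar = fitted_sge3
        D, mask = model_derivatives(polar, fit.estimate)
        gamma_N, gamma_T = rms_relative_curvatures(D)
        theta = polar.theta[mask]
        r_obs = polar.r[mask]

        def predict_cubed(phi):  # a -> a^3 test hook
            pars = GielisParameters.from_free(
                "SGE3", [phi[0] ** (1.0 / 3.0), phi[1]], strict=False)
            return sge_radius(theta, pars)

        phi2 = np.array([fit.estimate.a ** 3, fit.estimate.n1])
        V2, W2 = finite_difference_derivatives(predict_cubed, phi2)
        resid = r_obs - predict_cubed(phi2)
        D2 = DerivativeArrays(V=V2, W=W2,
                              s=float(np.sqrt(resid @ resid / (len(theta) - 2))))
        gamma_N2, gamma_T2 = rms_relative_curvatures(D2)
        assert abs(gamma_N2 - gamma_N) / gamma_N < 1e-3
        assert abs(gamma_T2 - gamma_T) / gamma_T > 0.10


class TestCriticalCurvature:
    def test_reference_value(self):
        # F(2, 2000; 0.05) ~ 3.000 -> K_c ~ 0.5773
        assert critical_curvature(2002, 2) == pytest.approx(0.5773, abs=5e-4)

    def test_monotone_in_p(self):
        # upper-alpha F quantiles fall as the numerator df grows, so the
        # critical curvature 1/sqrt(F) rises with the parameter count
        vals = [critical_curvature(2002, p) for p in range(2, 7)]
        assert np.all(np.diff(vals) > 0)

    def test_alpha_limit(self):
        assert critical_curvature(100, 2, alpha=0.9999) > 50.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            critical_curvature(5, 5)
        with pytest.raises(ValueError):
            critical_curvature(100, 2, alpha=1.5)


class TestBoxBias:
    def test_linear_model_zero_bias(self):
        D, _ = linear_arrays()
        bias, p_b = box_bias(D, np.array([2.0, -1.0]))
        assert np.max(np.abs(bias)) < 1e-8
        assert np.max(np.abs(p_b)) < 1e-8

    def test_bias_scales_with_s_squared(self):
        D, _ = exponential_arrays()
        D2 = DerivativeArrays(V=D.V, W=D.W, s=np.sqrt(2.0) * D.s)
        b1, _ = box_bias(D, np.array([1.0]))
        b2, _ = box_bias(D2, np.array([1.0]))
        np.testing.assert_allclose(b2, 2.0 * b1, rtol=1e-12)

    def test_zero_estimate_rejected(self):
        D, _ = exponential_arrays()
        with pytest.raises(ValueError):
            box_bias(D, np.array([0.0]))


class TestDiagnose:
    def test_noise_free_leaf_near_zero_curvature(self):
        from leafgielis.contour import to_polar
        from leafgielis.simulate import generate_leaf

        p = GielisParameters.from_free("SGE3", [10.0, 0.06])
        leaf = generate_leaf(p, 1000, 0.0, (0.4, 1.0, -1.0), seed=0)
        fit = fit_leaf(leaf, ["SGE3"])[SGEVariant.SGE3]
        polar = to_polar(leaf, fit.pole, fit.axis_angle)
        rep = diagnose(polar, fit)
        assert rep.gamma_N < 1e-4 and rep.gamma_T < 1e-4

    def test_report_identities_and_flags(self, fitted_sge3):
        fit, polar = fitted_sge3
        rep = diagnose(polar, fit)
        np.testing.assert_allclose(
            rep.P_b, 100.0 * rep.bias / fit.free_values, rtol=1e-12)
        assert rep.planar_ok == (rep.gamma_N < rep.K_c)
        assert rep.uniform_ok == (rep.gamma_T < rep.K_c)
        np.testing.assert_array_equal(
            rep.close_to_linear_params, np.abs(rep.P_b) < 1.0)
        assert rep.n_used <= fit.n_obs

    def test_record_layout_for_batch_export(self, fitted_sge3):
        fit, polar = fitted_sge3
        rec = diagnose(polar, fit).to_record()
        assert rec["variant"] == "SGE3"
        assert np.isnan(rec["Pb_n2"]) and np.isnan(rec["Pb_n3"])
        assert np.isfinite(rec["Pb_a"])
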