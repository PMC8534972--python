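"""Closed-form curve models, the coarse-to-fine fitter, and its invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

import angioflow as af
from angioflow import FitModel, GammaVariateParams, LaggedNormalParams, NoBolusError
from angioflow.curvefit import (
    FittedCurve,
    _gamma_variate_values,
    _lagged_normal_values,
    fit,
    fit_gamma_variate,
    fit_lagged_normal,
    fit_polynomial,
)

GV_TRUE = GammaVariateParams(ka=2.0, at_s=1.0, alpha=3.0, beta_s=0.5)
EMG_TRUE = LaggedNormalParams(area=10.0, mu_s=3.0, sigma_s=0.5, lam_per_s=2.0)
T = np.arange(0.0, 8.0001, 0.1)


def _gv_tdc(noise_sigma=0.0, seed=0):
    y = _gamma_variate_values(T, GV_TRUE)
    if noise_sigma:
        y = y + np.random.default_rng(seed).normal(0, noise_sigma * y.max(), y.size)
    return af.TimeDensityCurve(T, y, 0.1)


def test_gamma_variate_vanishes_at_appearance_time():
    assert _gamma_variate_values(np.array([GV_TRUE.at_s]), GV_TRUE)[0] == 0.0
    assert np.all(_gamma_variate_values(np.array([0.0, 0.5]), GV_TRUE) == 0.0)


def test_gamma_variate_peaks_at_at_plus_alpha_beta():
    dense = np.linspace(0, 8, 200001)
    y = _gamma_variate_values(dense, GV_TRUE)
    assert dense[np.argmax(y)] == pytest.approx(GV_TRUE.peak_time_s, abs=1e-3)


def test_gamma_variate_area_matches_quadrature():
    val, _ = quad(lambda x: _gamma_variate_values(np.array([x]), GV_TRUE)[0], 0, 80, limit=200)
    assert val == pytest.approx(GV_TRUE.area, rel=1e-8)


def test_lagged_normal_integrates_to_its_area():
    val, _ = quad(lambda x: _lagged_normal_values(np.array([x]), EMG_TRUE)[0], -20, 80, limit=300)
    assert val == pytest.approx(EMG_TRUE.area, rel=1e-8)


def test_lagged_normal_moments_match_closed_forms():
    dense = np.linspace(-10, 40, 400001)
    y = _lagged_normal_values(dense, EMG_TRUE)
    mass = np.trapezoid(y, dense)
    mean = np.trapezoid(y * dense, dense) / mass
    var = np.trapezoid(y * (dense - mean) ** 2, dense) / mass
    assert mean == pytest.approx(EMG_TRUE.mean_s, rel=5e-3)
    assert var == pytest.approx(EMG_TRUE.variance_s2, rel=5e-3)


def test_lagged_normal_large_lambda_degenerates_to_gaussian():
    # exponential stage -> impulse: the curve mean approaches mu
    p = LaggedNormalParams(area=5.0, mu_s=3.0, sigma_s=0.4, lam_per_s=200.0)
    dense = np.linspace(0, 10, 200001)
    y = _lagged_normal_values(dense, p)
    mean = np.trapezoid(y * dense, dense) / np.trapezoid(y, dense)
    assert mean == pytest.approx(p.mu_s, abs=0.02)


def test_gamma_variate_fit_recovers_generator_parameters():
    fitted = fit_gamma_variate(_gv_tdc())
    p = fitted.params
    assert p.ka == pytest.approx(GV_TRUE.ka, rel=0.02)
    assert p.at_s == pytest.approx(GV_TRUE.at_s, rel=0.02)
    assert p.alpha == pytest.approx(GV_TRUE.alpha, rel=0.02)
    assert p.beta_s == pytest.approx(GV_TRUE.beta_s, rel=0.02)
    assert fitted.rmse < 1e-6 * _gv_tdc().values.max()


def test_lagged_normal_fit_recovers_generator_parameters():
    y = _lagged_normal_values(T, EMG_TRUE)
    fitted = fit_lagged_normal(af.TimeDensityCurve(T, y, 0.1))
    p = fitted.params
    assert p.area == pytest.approx(EMG_TRUE.area, rel=0.02)
    assert p.mu_s == pytest.approx(EMG_TRUE.mu_s, rel=0.02)
    assert p.sigma_s == pytest.approx(EMG_TRUE.sigma_s, rel=0.02)
    assert p.lam_per_s == pytest.approx(EMG_TRUE.lam_per_s, rel=0.02)


def test_noisy_gamma_fit_localizes_the_peak():
    # median over seeds of |fitted peak - generator peak| stays sub-frame
    devs = []
    for seed in range(20):
        fitted = fit_gamma_variate(_gv_tdc(noise_sigma=0.05, seed=seed))
        devs.append(abs(fitted.params.peak_time_s - GV_TRUE.peak_time_s))
    assert np.median(devs) <= 0.2


@pytest.mark.parametrize("fitter", [fit_gamma_variate, fit_lagged_normal])
def test_all_zero_curve_raises_no_bolus(fitter):
    tdc = af.TimeDensityCurve(T, np.zeros_like(T), 0.1)
    with pytest.raises(NoBolusError):
        fitter(tdc)


def test_polynomial_fit_recovers_exact_polynomial():
    coeffs = np.array([0.1, 0.2, -0.3, 0.05, -0.02, 0.01, -0.001])
    y = np.polynomial.polynomial.polyval(T, coeffs)
    fitted = fit_polynomial(af.TimeDensityCurve(T, y, 0.1))
    assert np.allclose(fitted.params.coefficients, coeffs, rtol=1e-6, atol=1e-9)


def test_polynomial_needs_degree_plus_two_samples():
    tdc = af.TimeDensityCurve(np.arange(5) * 0.5, np.ones(5) + np.arange(5), 0.5)
    with pytest.raises(ValueError):
        fit_polynomial(tdc)


def test_higher_degree_never_increases_polynomial_rmse():
    # positive, offset curve so non-negativity clamping stays inactive
    y = 5.0 + _gamma_variate_values(T, GV_TRUE)
    tdc = af.TimeDensityCurve(T, y, 0.1)
    rmse6 = fit_polynomial(tdc, degree=6).rmse
    rmse5 = fit_polynomial(tdc, degree=5).rmse
    assert rmse6 <= rmse5 + 1e-12


def test_polynomial_is_clamped_outside_window_and_below_zero():
    y = 5.0 + _gamma_variate_values(T, GV_TRUE)
    fitted = fit_polynomial(af.TimeDensityCurve(T, y, 0.1), fit_window=(1.0, 6.0))
    vals = fitted.evaluate(np.array([0.0, 7.9, 3.0]))
    assert vals[0] == 0.0 and vals[1] == 0.0 and vals[2] > 0.0


def test_none_model_interpolates_the_raw_samples_exactly():
    tdc = _gv_tdc(noise_sigma=0.1, seed=3)
    wrapped = fit(tdc, FitModel.NONE)
    assert wrapped.rmse == 0.0
    assert np.allclose(wrapped.evaluate(tdc.times_s), tdc.values)


def test_dispatch_matches_direct_fit():
    direct = fit_gamma_variate(_gv_tdc())
    dispatched = fit(_gv_tdc(), FitModel.GAMMA_VARIATE)
    assert dispatched.params == direct.params
    with pytest.raises(ValueError):
        fit(_gv_tdc(), "NOT_A_MODEL")


def test_cross_model_fit_has_finite_positive_rmse():
    fitted = fit(_gv_tdc(), FitModel.LAGGED_NORMAL)
    assert np.isfinite(fitted.rmse) and fitted.rmse > 0.0


@pytest.mark.parametrize("model", [FitModel.GAMMA_VARIATE, FitModel.LAGGED_NORMAL,
                                   FitModel.POLYNOMIAL, FitModel.NONE])
def test_reported_rmse_equals_recomputed_residual(model):
    tdc = _gv_tdc(noise_sigma=0.05, seed=5)
    fitted = fit(tdc, model)
    resid = fitted.evaluate(tdc.times_s) - tdc.values
    assert fitted.rmse == pytest.approx(float(np.sqrt(np.mean(resid**2))), rel=1e-12, abs=1e-15)


@pytest.mark.parametrize("fitter", [fit_gamma_variate, fit_lagged_normal])
def test_fine_refinement_never_increases_rmse(fitter):
    tdc = _gv_tdc(noise_sigma=0.05, seed=7)
    assert fitter(tdc, refine=True).rmse <= fitter(tdc, refine=False).rmse + 1e-12


@pytest.mark.parametrize("fitter", [fit_gamma_variate, fit_lagged_normal])
def test_fitted_reference_curves_are_unimodal(fitter):
    # no recirculation bump: a single interior maximum on a dense grid
    tdc = _gv_tdc(noise_sigma=0.08, seed=9)
    fitted = fitter(tdc)
    dense = np.linspace(0, 8, 4001)
    y = fitted.evaluate(dense)
    d = np.diff(y)
    sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12 * y.max()])) != 0)
    assert sign_changes <= 1


def test_gamma_variate_area_property_vs_quadrature_after_fit():
    fitted = fit_gamma_variate(_gv_tdc())
    val, _ = quad(lambda x: fitted.evaluate(np.array([x]))[0], 0, 100, limit=300)
    assert val == pytest.approx(fitted.params.area, rel=1e-6)


def test_fit_json_export_roundtrips_fields(tmp_path):
    fitted = fit_gamma_variate(_gv_tdc())
    record = af.fit_to_json(fitted, tmp_path / "fit.json")
    assert record["model"] == "GAMMA_VARIATE"
    assert record["params"]["alpha"] == fitted.params.alpha
    import json

    assert json.loads((tmp_path / "fit.json").read_text()) == record
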