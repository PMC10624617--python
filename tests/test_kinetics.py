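import math

import numpy as np
import pytest

from pdpxtal.kinetics import (
    ArrheniusFit,
    ConvexArrheniusModel,
    FitError,
    FlashYieldSeries,
    RateSeries,
    action_trace,
    arrhenius_rate,
    convex_rate,
    cross_correlation_sigma,
    fit_action_trace,
    fit_arrhenius,
    fit_convex_arrhenius,
    fit_flash_yield,
    flash_yield,
)
from pdpxtal.synth.kineticsdata import (
    SyntheticKineticsSpec,
    default_arrhenius_truth,
    default_convex_truth,
    default_flash_yield_truth,
    make_kinetics_series,
)
from pdpxtal.units import R_GAS

R_KJ = R_GAS / 1000.0


# ---------------------------------------------------------------- Arrhenius

def _noise_free_series(truth=None, n=8):
    truth = truth or default_arrhenius_truth()
    t = np.linspace(284.0, 323.0, n)
    return RateSeries(t, arrhenius_rate(t, truth["a1"], truth["a2"],
                                        truth["ea"])), truth


def test_arrhenius_noise_free_exact_recovery():
    series, truth = _noise_free_series()
    fit = fit_arrhenius(series)
    assert fit.ea == pytest.approx(truth["ea"], rel=1e-6)
    assert fit.a1 == pytest.approx(truth["a1"], rel=1e-4)
    assert fit.a2 == pytest.approx(truth["a2"], rel=1e-3)
    assert fit.ea_identifiable


def test_arrhenius_rate_scale_equivariance():
    # multiplying all rates by c multiplies A1, A2 by c; Ea unchanged
    series, truth = _noise_free_series()
    scaled = RateSeries(series.temperatures, 1000.0 * series.rates)
    fit = fit_arrhenius(scaled)
    assert fit.ea == pytest.approx(truth["ea"], rel=1e-6)
    assert fit.a1 == pytest.approx(1000.0 * truth["a1"], rel=1e-4)
    assert fit.a2 == pytest.approx(1000.0 * truth["a2"], rel=1e-3)


def test_arrhenius_requires_enough_points_and_span():
    t4 = np.array([290.0, 295.0, 300.0, 305.0])  # only 15 K span
    with pytest.raises(FitError):
        fit_arrhenius(RateSeries(t4, np.full(4, 1e-3)))
    t3 = np.array([280.0, 300.0, 320.0])
    with pytest.raises(FitError):
        fit_arrhenius(RateSeries(t3, np.full(3, 1e-3)))


def test_arrhenius_flat_channel_not_identifiable():
    # purely temperature-independent rates: the exponential channel is
    # degenerate; fit either raises or flags Ea as non-identifiable
    t = np.linspace(280.0, 320.0, 8)
    series = RateSeries(t, np.full(8, 5e-4))
    try:
        fit = fit_arrhenius(series)
    except FitError:
        return
    assert not fit.ea_identifiable


def test_rate_series_validation():
    with pytest.raises(ValueError):
        RateSeries(np.array([280.0, -5.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        RateSeries(np.array([280.0, 280.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        RateSeries(np.array([280.0, 300.0]), np.array([1.0, 0.0]))


def test_arrhenius_csv_round_trip(tmp_path):
    series, _ = _noise_free_series()
    path = tmp_path / "rates.csv"
    series.to_frame().to_csv(path, index=False)
    back = RateSeries.from_csv(path)
    np.testing.assert_allclose(back.temperatures, series.temperatures)
    np.testing.assert_allclose(back.rates, series.rates)


# --------------------------------------------------------- convex Arrhenius

def test_convex_rate_curvature_in_arrhenius_coordinates():
    # the Boltzmann-weighted two-channel rate is genuinely curved in
    # ln k vs 1/T (a single-channel Arrhenius law is exactly straight),
    # with one consistent curvature sign across the range
    truth = default_convex_truth()
    t = np.linspace(270.0, 340.0, 30)
    lnk = np.log(convex_rate(t, truth["k1"], truth["e1"], truth["k2"],
                             truth["e2"], truth["delta_g"]))
    x = 1.0 / t
    order = np.argsort(x)
    second = np.diff(lnk[order], 2)
    assert (np.abs(second) > 1e-6).all()
    assert len(np.unique(np.sign(second))) == 1
    # reference: a straight-line fit leaves structured residuals
    resid = lnk - np.polyval(np.polyfit(x, lnk, 1), x)
    assert np.abs(resid).max() > 1e-3


def test_convex_fit_recovers_truth_noise_free():
    truth = default_convex_truth()
    t = np.linspace(270.0, 340.0, 15)
    series = RateSeries(t, convex_rate(t, truth["k1"], truth["e1"],
                                       truth["k2"], truth["e2"],
                                       truth["delta_g"]))
    model = fit_convex_arrhenius(series)
    # curvature must be detected: AIC picks the two-channel model ...
    assert isinstance(model, ConvexArrheniusModel)
    assert model.aic_convex < model.aic_simple
    # ... and the fitted curve reproduces the data; the individual
    # parameters are NOT asserted: the 5-parameter model admits distinct
    # parameterizations that match rate data to <0.1%
    np.testing.assert_allclose(model.rate(t), series.rates, rtol=5e-3)
    # interpolation onto unseen temperatures also holds
    t_fine = np.linspace(272.0, 338.0, 40)
    clean = convex_rate(t_fine, truth["k1"], truth["e1"], truth["k2"],
                        truth["e2"], truth["delta_g"])
    np.testing.assert_allclose(model.rate(t_fine), clean, rtol=5e-3)


def test_convex_model_channel_algebra():
    truth = default_convex_truth()
    model = ConvexArrheniusModel(
        prefactors=(truth["k1"], truth["k2"]),
        barriers=(truth["e1"], truth["e2"]), delta_g=truth["delta_g"],
        transition_temperature=None, aic_convex=0.0, aic_simple=0.0)
    t = np.linspace(270.0, 340.0, 7)
    w1, w2 = model.channel_weights(t)
    np.testing.assert_allclose(w1 + w2, 1.0, rtol=1e-12)
    r1, r2 = model.channel_rates(t)
    np.testing.assert_allclose(r1 + r2, model.rate(t), rtol=1e-12)
    np.testing.assert_allclose(
        model.rate(t), convex_rate(t, truth["k1"], truth["e1"], truth["k2"],
                                   truth["e2"], truth["delta_g"]), rtol=1e-12)
    # the two channel contributions cross inside the physical range
    from scipy.optimize import brentq
    t_cross = brentq(lambda x: float(np.subtract(*model.channel_rates(x))),
                     150.0, 500.0)
    assert 150.0 < t_cross < 500.0
    lo, hi = sorted((t_cross - 50.0, t_cross + 50.0))
    r1_lo, r2_lo = model.channel_rates(lo)
    r1_hi, r2_hi = model.channel_rates(hi)
    assert np.sign(r1_lo - r2_lo) != np.sign(r1_hi - r2_hi)


def test_convex_fit_falls_back_to_simple_on_straight_data():
    # pure simple-Arrhenius data: AIC must prefer the 3-parameter model
    truth = default_arrhenius_truth()
    series, _ = _noise_free_series(truth)
    model = fit_convex_arrhenius(series)
    assert isinstance(model, ArrheniusFit)


# ---------------------------------------------------------------- flash yield

def test_flash_yield_low_fluence_slope():
    # dY/dF at F=0 equals phi*sigma_lin
    phi, sl, sn = 0.35, 1.2, 0.15
    eps = 1e-7
    slope = flash_yield(eps, phi, sl, sn) / eps
    assert slope == pytest.approx(phi * sl, rel=1e-5)


def test_flash_yield_unique_interior_maximum():
    truth = default_flash_yield_truth()
    f = np.linspace(0.0, 30.0, 20001)
    y = flash_yield(f, truth["phi"], truth["sigma_lin"], truth["sigma_nl"])
    i = int(np.argmax(y))
    assert 0 < i < len(f) - 1
    # strictly increasing before, strictly decreasing after (coarse check)
    assert (np.diff(y[: i - 5]) > 0).all()
    assert (np.diff(y[i + 5:]) < 0).all()


def test_fit_flash_yield_recovers_truth_and_optimal_fluence():
    truth = default_flash_yield_truth()
    f = np.linspace(0.0, 10.0, 15)
    series = FlashYieldSeries(f, flash_yield(f, truth["phi"],
                                             truth["sigma_lin"],
                                             truth["sigma_nl"]))
    fit = fit_flash_yield(series)
    assert fit.quantum_yield_scale == pytest.approx(truth["phi"], rel=1e-4)
    assert fit.sigma_linear == pytest.approx(truth["sigma_lin"], rel=1e-4)
    assert fit.sigma_nonlinear == pytest.approx(truth["sigma_nl"], rel=1e-4)
    # dense grid-search oracle for the optimal fluence
    grid = np.linspace(1e-4, 30.0, 300001)
    f_star = grid[np.argmax(fit.yield_at(grid))]
    assert fit.optimal_fluence == pytest.approx(f_star, abs=1e-3)


def test_fit_flash_yield_errors():
    with pytest.raises(FitError):
        fit_flash_yield(FlashYieldSeries(np.linspace(0, 1, 4),
                                         np.full(4, 0.1)))
    with pytest.raises(FitError):
        fit_flash_yield(FlashYieldSeries(np.linspace(0, 1, 6), np.zeros(6)))
    with pytest.raises(ValueError):
        FlashYieldSeries(np.array([-1.0, 1.0]), np.array([0.1, 0.1]))
    with pytest.raises(ValueError):
        FlashYieldSeries(np.array([0.0, 1.0]), np.array([0.1, 1.5]))


# --------------------------------------------------------------- action trace

def test_action_trace_limits():
    truth = {"pump_fwhm": 100.0, "dump_fwhm": 100.0,
             "es_lifetime": 7.6, "depth": 0.4}
    d = np.array([-5000.0, 0.0, 1e6])
    s = action_trace(d, truth["pump_fwhm"], truth["dump_fwhm"],
                     truth["es_lifetime"], truth["depth"])
    # far-negative delay: no suppression
    assert s[0] == pytest.approx(1.0, abs=1e-9)
    # at zero delay: half the depth (erf(0)=0) -- lifetime decay is 1 there
    assert s[1] == pytest.approx(1.0 - 0.5 * truth["depth"], abs=1e-12)
    # far-positive delay: excited state has decayed, suppression recovers
    assert s[2] == pytest.approx(1.0, abs=1e-6)


def test_action_trace_monotone_onset():
    s = action_trace(np.linspace(-600.0, 0.0, 50), 100.0, 100.0, 7.6, 0.4)
    assert (np.diff(s) <= 1e-12).all()


def test_cross_correlation_sigma_value():
    # two 100-fs FWHM Gaussians: cross-correlation FWHM = 100*sqrt(2)
    sig = cross_correlation_sigma(100.0, 100.0)
    expected = 100.0 * math.sqrt(2.0) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    assert sig == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        cross_correlation_sigma(0.0, 100.0)


def test_fit_action_trace_recovers_truth():
    d = np.linspace(-600.0, 3000.0, 60)
    s = action_trace(d, 100.0, 100.0, 7.6, 0.4)
    fit = fit_action_trace(d, s)
    assert fit.es_lifetime_ps == pytest.approx(7.6, rel=0.10)
    assert fit.depth == pytest.approx(0.4, rel=0.02)
    assert fit.sigma_cc_fs == pytest.approx(
        cross_correlation_sigma(100.0, 100.0), rel=0.05)


# ------------------------------------------------------------ synthetic data

def test_synthetic_kinetics_deterministic():
    spec = SyntheticKineticsSpec(model="arrhenius", relative_noise=0.05,
                                 seed=11)
    s1, t1 = make_kinetics_series(spec)
    s2, t2 = make_kinetics_series(SyntheticKineticsSpec(
        model="arrhenius", relative_noise=0.05, seed=11))
    np.testing.assert_array_equal(s1.rates, s2.rates)
    assert t1 == t2


def test_synthetic_kinetics_seed_changes_noise_only():
    a = make_kinetics_series(SyntheticKineticsSpec(seed=1))[0]
    b = make_kinetics_series(SyntheticKineticsSpec(seed=2))[0]
    clean = make_kinetics_series(
        SyntheticKineticsSpec(seed=1, relative_noise=0.0))[0]
    np.testing.assert_array_equal(a.temperatures, b.temperatures)
    assert not np.array_equal(a.rates, b.rates)
    # both scatter around the same clean curve
    assert np.abs(a.rates / clean.rates - 1.0).max() < 0.3
    assert np.abs(b.rates / clean.rates - 1.0).max() < 0.3


def test_synthetic_kinetics_grid_validation():
    with pytest.raises(ValueError):
        SyntheticKineticsSpec(model="arrhenius",
                              grid=np.array([200.0, 300.0, 310.0, 320.0]))
    with pytest.raises(ValueError):
        SyntheticKineticsSpec(model="nope")
    with pytest.raises(ValueError):
        SyntheticKineticsSpec(relative_noise=-0.1)
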