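import math

import numpy as np
import pytest
from scipy.integrate import quad

from pdpxtal.synth.tasurface import (
    SyntheticTASpec,
    eads_from_bands,
    make_band_trace,
    make_ta_surface,
)
from pdpxtal.ta import (
    FWHM_TO_SIGMA,
    ChirpModel,
    TAFitError,
    TASurface,
    correct_chirp,
    exp_gauss_convolution,
    fit_single_exponential_band,
    gaussian_cumulative,
    global_fit_sequential,
    sequential_concentrations,
)


# ------------------------------------------------------------ convolution

def test_exp_gauss_convolution_matches_quadrature():
    # oracle: numerical convolution of step-exponential with Gaussian IRF
    tau, sigma, t0 = 3.0, 0.4, 0.2

    def integrand(s, t):
        return (math.exp(-s / tau)
                * math.exp(-((t - t0 - s) ** 2) / (2 * sigma**2))
                / (sigma * math.sqrt(2 * math.pi)))

    for t in (-1.0, 0.0, 0.2, 0.5, 2.0, 10.0):
        expected, _ = quad(integrand, 0.0, 60.0, args=(t,), limit=200)
        got = exp_gauss_convolution(np.array([t]), tau, sigma, t0)[0]
        assert got == pytest.approx(expected, abs=1e-8)


def test_exp_gauss_convolution_delta_irf_limit():
    t = np.linspace(-1.0, 10.0, 50)
    out = exp_gauss_convolution(t, 2.0, 0.0, 0.0)
    expected = np.where(t >= 0, np.exp(-np.maximum(t, 0) / 2.0), 0.0)
    np.testing.assert_allclose(out, expected, atol=1e-12)
    # small sigma converges to the same limit away from t=0
    out_small = exp_gauss_convolution(t, 2.0, 1e-4, 0.0)
    mask = np.abs(t) > 0.01
    np.testing.assert_allclose(out_small[mask], expected[mask], atol=1e-6)


def test_exp_gauss_convolution_long_time_stability():
    # erfcx formulation must not overflow at long delays
    out = exp_gauss_convolution(np.array([1e4]), 5.0, 0.1, 0.0)
    assert np.isfinite(out).all()
    assert out[0] == pytest.approx(math.exp(-1e4 / 5.0 + 0.1**2 / (2 * 25.0)),
                                   rel=1e-6)


def test_gaussian_cumulative_limits():
    t = np.array([-100.0, 0.0, 100.0])
    out = gaussian_cumulative(t, 1.0, 0.0)
    np.testing.assert_allclose(out, [0.0, 0.5, 1.0], atol=1e-12)


# ------------------------------------------------------ sequential chain

def test_sequential_two_compartment_peak_time():
    # Bateman: B(t) peaks at ln(tau1/tau2)/(1/tau2 - 1/tau1) for A->B->0
    tau1, tau2 = 2.0, 12.0
    t = np.linspace(0.0, 60.0, 120001)
    conc = sequential_concentrations((tau1, tau2), 1e-6, 0.0, t)
    k1, k2 = 1.0 / tau1, 1.0 / tau2
    t_peak = math.log(k1 / k2) / (k1 - k2)
    assert t[np.argmax(conc[:, 1])] == pytest.approx(t_peak, abs=2e-3)


def test_sequential_conservation():
    # with a very long terminal lifetime, the population sum approaches the
    # IRF cumulative (everything excited is somewhere in the chain)
    taus = (3.0, 1.0e6)
    t = np.linspace(-2.0, 20.0, 200)
    conc = sequential_concentrations(taus, 150.0, 0.0, t)
    total = conc.sum(axis=1)
    cum = gaussian_cumulative(t, 150.0 * 1e-3 * FWHM_TO_SIGMA, 0.0)
    np.testing.assert_allclose(total, cum, atol=1e-4)


def test_sequential_rejects_degenerate_taus():
    with pytest.raises(ValueError):
        sequential_concentrations((5.0, 5.0), 150.0, 0.0, np.linspace(0, 10, 5))
    with pytest.raises(ValueError):
        sequential_concentrations((-1.0, 5.0), 150.0, 0.0, np.linspace(0, 10, 5))


# ------------------------------------------------------------------ chirp

def test_chirp_zero_identity():
    surface, _ = make_ta_surface(SyntheticTASpec(noise_mod=0.1, seed=4))
    out = correct_chirp(surface, ChirpModel((0.0,)))
    np.testing.assert_array_equal(out.delta_od, surface.delta_od)


def test_chirp_known_quadratic_inversion():
    chirp = ChirpModel((8.0, -0.03, 2.8e-5))
    # a delay grid much finer than the IRF rise, so the interpolation in
    # the round trip (apply chirp, then correct it) is not the bottleneck
    delays = np.concatenate([np.linspace(-1.0, 3.0, 401),
                             np.linspace(3.1, 50.0, 100)])
    spec = SyntheticTASpec(chirp=chirp, noise_mod=0.0, seed=0, delays=delays)
    surface, truth = make_ta_surface(spec)
    clean, _ = make_ta_surface(SyntheticTASpec(noise_mod=0.0, seed=0,
                                               delays=delays.copy()))
    corrected = correct_chirp(surface, chirp)
    mask = np.isfinite(corrected.delta_od)
    err = np.abs(corrected.delta_od[mask] - clean.delta_od[mask])
    peak = np.abs(clean.delta_od).max()
    assert err.max() < 0.01 * peak


def test_chirp_validation():
    with pytest.raises(ValueError):
        ChirpModel((0.0, 1.0, 2.0, 3.0))
    with pytest.raises(ValueError):
        ChirpModel((math.nan,))
    surface, _ = make_ta_surface(SyntheticTASpec())
    with pytest.raises(ValueError):
        correct_chirp(surface, ChirpModel((1e4,)))


# -------------------------------------------------------------- global fit

def test_global_fit_noiseless_recovery():
    spec = SyntheticTASpec(noise_mod=0.0)
    surface, truth = make_ta_surface(spec)
    result = global_fit_sequential(surface, 2, initial_taus=(3.0, 80.0))
    np.testing.assert_allclose(np.sort(result.time_constants),
                               np.sort(truth["time_constants"]), rtol=1e-4)
    assert result.residual_rms < 1e-6 * np.abs(surface.delta_od).max()
    # EADS recovered up to the chain ordering
    wl = surface.wavelengths
    expected = np.array([eads_from_bands(b, wl) for b in spec.eads_bands])
    np.testing.assert_allclose(result.eads, expected, atol=1e-4)


def test_global_fit_single_compartment_rank1():
    spec = SyntheticTASpec(time_constants=(7.6,),
                           eads_bands=(((470.0, 40.0, -8.0),),),
                           noise_mod=0.0)
    surface, truth = make_ta_surface(spec)
    result = global_fit_sequential(surface, 1, initial_taus=(3.0,))
    assert result.time_constants[0] == pytest.approx(7.6, rel=1e-4)
    assert result.residual_rms < 1e-8


def test_global_fit_input_validation():
    surface, _ = make_ta_surface(SyntheticTASpec())
    with pytest.raises(ValueError):
        global_fit_sequential(surface, 5, initial_taus=(1, 2, 3, 4, 5))
    with pytest.raises(ValueError):
        global_fit_sequential(surface, 2, initial_taus=(1.0,))
    tiny = TASurface(np.array([0.0, 1.0, 2.0, 3.0]),
                     np.array([500.0, 510.0]), np.zeros((4, 2)))
    with pytest.raises(TAFitError):
        global_fit_sequential(tiny, 2, initial_taus=(1.0, 5.0))


def test_global_fit_overfit_still_reproduces_data():
    # single-compartment data fitted with two compartments: the extra tau
    # is not identifiable (any second compartment can be absorbed by the
    # EADS), but the fit must still contain the true decay constant and
    # reproduce the surface essentially exactly
    spec = SyntheticTASpec(time_constants=(7.6,),
                           eads_bands=(((470.0, 40.0, -8.0),),),
                           noise_mod=0.0)
    surface, _ = make_ta_surface(spec)
    result = global_fit_sequential(surface, 2, initial_taus=(5.0, 10.0))
    assert result.residual_rms < 1e-6
    assert np.abs(result.time_constants / 7.6 - 1.0).min() < 1e-3


# ------------------------------------------------------------- band trace

def test_band_fit_self_consistency():
    delays, clean, truth = make_band_trace(tau_ps=4.5, relative_noise=0.0)
    fit = fit_single_exponential_band(delays, clean,
                                      irf_fwhm_fs=truth["irf_fwhm"])
    assert fit.tau == pytest.approx(truth["tau"], rel=1e-6)
    assert fit.identifiable


def test_band_fit_flat_trace_not_identifiable():
    delays = np.linspace(-1.0, 25.0, 30)
    fit = fit_single_exponential_band(delays, np.zeros(30))
    assert not fit.identifiable
    assert math.isnan(fit.tau)


def test_band_fit_too_few_points():
    with pytest.raises(TAFitError):
        fit_single_exponential_band(np.linspace(0, 5, 5), np.ones(5))


# ---------------------------------------------------------- synthetic data

def test_ta_surface_deterministic_and_seeded():
    a, _ = make_ta_surface(SyntheticTASpec(noise_mod=0.05, seed=9))
    b, _ = make_ta_surface(SyntheticTASpec(noise_mod=0.05, seed=9))
    c, _ = make_ta_surface(SyntheticTASpec(noise_mod=0.05, seed=10))
    np.testing.assert_array_equal(a.delta_od, b.delta_od)
    assert not np.array_equal(a.delta_od, c.delta_od)


def test_ta_surface_csv_round_trip(tmp_path):
    surface, _ = make_ta_surface(SyntheticTASpec(noise_mod=0.02, seed=1))
    path = tmp_path / "ta.csv"
    surface.to_csv(path)
    back = TASurface.from_csv(path, irf_fwhm=surface.irf_fwhm)
    np.testing.assert_allclose(back.delta_od, surface.delta_od, rtol=1e-12)
    np.testing.assert_allclose(back.delays, surface.delays)
    np.testing.assert_allclose(back.wavelengths, surface.wavelengths)


def test_ta_surface_validation():
    with pytest.raises(ValueError):
        TASurface(np.array([1.0, 0.5]), np.array([500.0, 510.0]),
                  np.zeros((2, 2)))
    with pytest.raises(ValueError):
        TASurface(np.array([0.0, 1.0]), np.array([500.0, 500.0]),
                  np.zeros((2, 2)))
    with pytest.raises(ValueError):
        TASurface(np.array([0.0, 1.0]), np.array([500.0, 510.0]),
                  np.zeros((3, 2)))
    with pytest.raises(ValueError):
        SyntheticTASpec(time_constants=(5.0, 5.0))
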