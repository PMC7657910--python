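"""QENS model, convolution, per-spectrum fits and downstream reductions."""

import numpy as np
import pytest
from scipy.special import voigt_profile

from rbcneutron.constants import HBAR_UEV_PS
from rbcneutron.dataio import QENSSpectrum
from rbcneutron.qens import (ResolutionConvolver, correlation_time, fit_eisf,
                             fit_global_diffusion, fit_spectrum, gamma_global,
                             lorentzian, model_total_sqw,
                             sphere_to_gaussian_msd, subtract_buffer)
from rbcneutron.synthetic import QENSTruth, make_qens

OMEGA = np.arange(-31.0, 31.0001, 0.2)
SG = 1.0 / 2.3548200450309493          # Gaussian sigma for 1.0 µeV FWHM


def _resolution(omega=OMEGA):
    r = np.exp(-(omega**2) / (2 * SG**2))
    return r / np.trapezoid(r, omega)


# ---------------------------------------------------------------------------
# Model function
# ---------------------------------------------------------------------------

def test_zero_internal_width_collapses_to_single_lorentzian():
    for A0 in (0.0, 0.3, 1.0):
        out = model_total_sqw(OMEGA, A0, 0.7, 0.0, 2.0)
        assert out == pytest.approx(2.0 * lorentzian(OMEGA, 0.7), rel=1e-12)


def test_model_peak_value_closed_form():
    A0, gG, gI, scale, a = 0.6, 0.5, 3.0, 7.0, 0.2
    peak = model_total_sqw(np.array([0.0]), A0, gG, gI, scale, a)[0]
    expected = scale * (A0 / (np.pi * gG) + (1 - A0) / (np.pi * (gG + gI))) + a
    assert peak == pytest.approx(expected, rel=1e-12)


def test_model_integral_normalization():
    """Integral over ±200 Gamma recovers the scale to 0.5% (slow tails)."""
    gG, gI, scale = 0.5, 2.0, 3.0
    w = np.linspace(-200 * (gG + gI), 200 * (gG + gI), 400001)
    total = np.trapezoid(model_total_sqw(w, 0.6, gG, gI, scale), w)
    assert total == pytest.approx(scale, rel=5e-3)


def test_model_rejects_invalid_parameters():
    with pytest.raises(ValueError):
        model_total_sqw(OMEGA, 1.2, 0.5, 1.0)
    with pytest.raises(ValueError):
        lorentzian(OMEGA, -0.1)


# ---------------------------------------------------------------------------
# Resolution convolution
# ---------------------------------------------------------------------------

def test_convolution_matches_voigt_oracle():
    """Lorentzian (x) Gaussian must equal the analytic Voigt profile."""
    conv = ResolutionConvolver(OMEGA, _resolution(), oversample=4)
    got = conv.apply(lambda w: lorentzian(w, 0.8))
    expected = voigt_profile(OMEGA, SG, 0.8)
    assert np.max(np.abs(got - expected)) / expected.max() < 1e-4


def test_convolution_of_delta_returns_resolution():
    conv = ResolutionConvolver(OMEGA, _resolution(), oversample=3)
    spike = np.zeros_like(conv.omega_fine)
    spike[np.argmin(np.abs(conv.omega_fine))] = 1.0 / conv.h_fine
    out = conv.apply_to_values(spike)
    assert np.max(np.abs(out - _resolution())) / _resolution().max() < 1e-9


def test_convolution_is_linear_in_scale():
    conv = ResolutionConvolver(OMEGA, _resolution())
    one = conv.apply(lambda w: model_total_sqw(w, 0.5, 0.6, 2.0, 1.0))
    five = conv.apply(lambda w: model_total_sqw(w, 0.5, 0.6, 2.0, 5.0))
    assert five == pytest.approx(5.0 * one, rel=1e-12)


def test_convolution_preserves_integral():
    conv = ResolutionConvolver(OMEGA, _resolution(), oversample=4)
    vals = conv.apply(lambda w: model_total_sqw(w, 0.6, 0.5, 2.0, 1.0))
    direct = model_total_sqw(OMEGA, 0.6, 0.5, 2.0, 1.0)
    assert np.trapezoid(vals, OMEGA) == pytest.approx(
        np.trapezoid(direct, OMEGA), rel=1e-3)


# ---------------------------------------------------------------------------
# Buffer subtraction
# ---------------------------------------------------------------------------

def _spec(S, sigma=None, q=0.91):
    sigma = np.ones_like(S) if sigma is None else sigma
    return QENSSpectrum(q=q, omega=OMEGA, S=S, sigma=sigma,
                        resolution=_resolution())


def test_subtract_buffer_identity_and_self():
    s = _spec(np.abs(np.random.default_rng(0).normal(10, 1, len(OMEGA))))
    out = subtract_buffer(s, s, scale=0.0)
    assert out.S == pytest.approx(s.S)
    zero = subtract_buffer(s, s, scale=1.0)
    assert zero.S == pytest.approx(np.zeros_like(s.S))
    assert zero.sigma == pytest.approx(np.sqrt(2) * s.sigma)


def test_subtract_buffer_recovers_signal(rng):
    """signal + 0.3*buffer - 0.3*buffer == signal, within counting noise."""
    signal = 50 * _resolution() + 5.0
    buffer_true = 30 * lorentzian(OMEGA, 8.0) + 2.0
    worst = 0.0
    for seed in range(20):
        r = np.random.default_rng(seed)
        total = r.poisson(np.maximum(signal + 0.3 * buffer_true, 0) * 50) / 50
        buf = r.poisson(buffer_true * 50) / 50
        sig = np.sqrt(np.maximum(total * 50, 1)) / 50
        sigb = np.sqrt(np.maximum(buf * 50, 1)) / 50
        out = subtract_buffer(_spec(total, sig), _spec(buf, sigb), scale=0.3)
        z = (out.S - signal) / out.sigma
        worst = max(worst, abs(z.mean()))
    assert worst < 0.5     # residual consistent with zero at the noise level


def test_subtract_buffer_grid_mismatch():
    s = _spec(np.ones_like(OMEGA))
    other = QENSSpectrum(q=0.91, omega=OMEGA + 0.05, S=np.ones_like(OMEGA),
                         sigma=np.ones_like(OMEGA))
    with pytest.raises(ValueError):
        subtract_buffer(s, other)


# ---------------------------------------------------------------------------
# Spectrum fitting
# ---------------------------------------------------------------------------

def test_fit_spectrum_noiseless_self_consistency():
    truth = dict(A0=0.62, Gamma_G=0.55, Gamma_I=3.0, scale=1000.0,
                 bkg_a=2.0, bkg_b=0.05)
    conv = ResolutionConvolver(OMEGA, _resolution(), oversample=3)
    model = conv.apply(model_total_sqw, truth["A0"], truth["Gamma_G"],
                       truth["Gamma_I"], truth["scale"], truth["bkg_a"],
                       truth["bkg_b"])
    fit = fit_spectrum(_spec(model))
    for k, v in truth.items():
        assert getattr(fit, k) == pytest.approx(v, rel=1e-5), k


def test_fit_spectrum_label_switching_guard():
    """Swapped narrow/broad initial widths converge to the same solution."""
    conv = ResolutionConvolver(OMEGA, _resolution(), oversample=3)
    model = conv.apply(model_total_sqw, 0.5, 0.8, 2.5, 500.0, 1.0, 0.0)
    single = fit_spectrum(_spec(model), multi_start=False)
    guarded = fit_spectrum(_spec(model), multi_start=True)
    assert guarded.Gamma_G == pytest.approx(0.8, rel=1e-4)
    assert guarded.Gamma_I == pytest.approx(2.5, rel=1e-4)
    assert guarded.Gamma_G == pytest.approx(single.Gamma_G, rel=1e-3)


def test_fit_spectrum_requires_resolution_and_bins():
    s = QENSSpectrum(q=0.9, omega=OMEGA, S=np.ones_like(OMEGA),
                     sigma=np.ones_like(OMEGA))
    with pytest.raises(ValueError):
        fit_spectrum(s)
    mid = len(OMEGA) // 2
    sel = slice(mid - 15, mid + 15)
    short = QENSSpectrum(q=0.9, omega=OMEGA[sel], S=np.ones(30),
                         sigma=np.ones(30),
                         resolution=_resolution(OMEGA)[sel])
    with pytest.raises(ValueError):
        fit_spectrum(short)


def test_per_q_width_unbiased_at_counting_statistics():
    """Gamma_G estimates at EMU-like counts show no systematic bias."""
    truth = QENSTruth(D_eff=10.0e-8)
    n_seeds = 10
    qs = None
    fits = []
    for seed in range(n_seeds):
        spectra, _ = make_qens(truth, window=20.0, step=0.3, seed=seed)
        qs = [s.q for s in spectra]
        fits.append([fit_spectrum(s) for s in spectra])
    for iq, q in enumerate(qs):
        gtruth = float(gamma_global(q, truth.D_eff))
        vals = np.array([fits[s][iq].Gamma_G for s in range(n_seeds)])
        errs = np.array([fits[s][iq].errors["Gamma_G"] for s in range(n_seeds)])
        bias = vals.mean() - gtruth
        sem = np.sqrt(np.mean(errs**2) / n_seeds)
        assert abs(bias) < 3 * sem, f"q={q}: bias {bias} vs sem {sem}"


# ---------------------------------------------------------------------------
# Global diffusion line
# ---------------------------------------------------------------------------

def test_global_diffusion_exact_round_trip():
    q = np.array([0.34, 0.54, 0.73, 0.91, 1.10, 1.28, 1.46, 1.63, 1.79, 1.92])
    D = 10.0e-8                        # cm^2/s  == 1.0e9 Å^2/s
    gamma = gamma_global(q, D)
    assert gamma[-1] == pytest.approx(2.43, abs=0.01)   # width at q = 1.92
    res = fit_global_diffusion(gamma, np.full_like(gamma, 0.01), q, T=288.0)
    assert res.D_eff == pytest.approx(D, rel=1e-12)
    assert res.D_trans == res.D_eff / 1.27


def test_global_diffusion_zero_widths():
    q = np.linspace(0.3, 1.9, 6)
    res = fit_global_diffusion(np.zeros_like(q), np.full_like(q, 0.01), q,
                               T=288.0)
    assert res.D_eff == 0.0


def test_global_diffusion_needs_four_points():
    with pytest.raises(ValueError):
        fit_global_diffusion([1.0, 2.0, 3.0], [0.1] * 3, [0.5, 1.0, 1.5],
                             T=288.0)


# ---------------------------------------------------------------------------
# Internal dynamics and EISF
# ---------------------------------------------------------------------------

def test_correlation_time_values():
    res = correlation_time([2.84])
    assert res.tau == pytest.approx(232, abs=1.0)
    assert correlation_time([2.40]).tau == pytest.approx(274, abs=1.0)
    assert correlation_time([HBAR_UEV_PS]).tau == pytest.approx(1.0, rel=1e-12)


def test_correlation_time_hbar_identity():
    for g in (0.5, 2.84, 658.0):
        res = correlation_time([g, g, g])
        assert res.tau * res.Gamma_mean == pytest.approx(HBAR_UEV_PS, rel=1e-12)


def test_eisf_noiseless_exact_recovery():
    q = np.array([0.34, 0.54, 0.73, 0.91, 1.10, 1.28, 1.46, 1.63, 1.79, 1.92])
    A0 = (1 - 0.50) * np.exp(-1.3 * q**2) + 0.50
    fit = fit_eisf(A0, np.full_like(A0, 1e-4), q)
    assert fit.x2 == pytest.approx(1.3, rel=1e-6)
    assert fit.p_immobile == pytest.approx(0.50, rel=1e-6)
    assert not fit.degenerate


def test_eisf_flat_is_degenerate():
    q = np.linspace(0.3, 1.9, 8)
    fit = fit_eisf(np.ones_like(q), np.full_like(q, 1e-3), q)
    assert fit.degenerate
    assert fit.p_immobile == pytest.approx(1.0, abs=1e-3)


def test_eisf_interval_coverage_sanity():
    """1-sigma coverage for <x^2> lies in a wide sanity band (60-99%)."""
    q = np.array([0.34, 0.54, 0.73, 0.91, 1.10, 1.28, 1.46, 1.63, 1.79, 1.92])
    x2_t, p_t = 1.3, 0.50
    A0_true = (1 - p_t) * np.exp(-x2_t * q**2) + p_t
    err = np.full_like(q, 0.02)
    hits = 0
    n = 100
    for seed in range(n):
        r = np.random.default_rng(seed)
        fit = fit_eisf(np.clip(A0_true + err * r.standard_normal(len(q)),
                               0, 1), err, q)
        if abs(fit.x2 - x2_t) <= fit.x2_err:
            hits += 1
    assert 60 <= 100 * hits / n <= 99


def test_sphere_to_gaussian_msd():
    assert sphere_to_gaussian_msd(2.8) == pytest.approx(1.568, rel=1e-12)
    assert sphere_to_gaussian_msd(0.0) == 0.0
    assert sphere_to_gaussian_msd(np.sqrt(5.0)) == pytest.approx(1.0, rel=1e-12)
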