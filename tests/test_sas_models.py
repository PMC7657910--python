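"""Model-function checks: analytic values, oracles, smearing operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from rbcneutron.dataio import SASCurve
from rbcneutron.sas_models import (ButlerParams, GuinierPorodParams,
                                   YukawaInteraction, butler_empirical,
                                   charge_from_contact_potential,
                                   composite_sans_intensity, debye_length,
                                   guinier_porod, lake_desmear, slit_smear,
                                   sphere_form_factor)

# ---------------------------------------------------------------------------
# Butler empirical
# ---------------------------------------------------------------------------

valid_butler = st.builds(
    ButlerParams,
    I0=st.floats(0.01, 100.0),
    alpha=st.floats(0.01, 0.95),
    xi=st.floats(0.5, 20.0),
    d=st.floats(1.0, 4.5),
)


@given(valid_butler)
@settings(max_examples=50, deadline=None)
def test_butler_peak_value_and_high_q_limit(p):
    """I(2*pi/xi) = I0 exactly; I -> I0*alpha at large q, for any parameters."""
    q_star = 2 * np.pi / p.xi
    assert butler_empirical(np.array([q_star]), p)[0] == pytest.approx(
        p.I0, rel=1e-12)
    assert butler_empirical(np.array([1e8 * q_star]), p)[0] == pytest.approx(
        p.I0 * p.alpha, rel=1e-5, abs=1e-7 * p.I0)


def test_butler_peak_position_brute_force():
    """Dense-grid argmax confirms the peak at q* = 2*pi/xi for xi = 4.61 µm."""
    p = ButlerParams(I0=1.0, alpha=0.1, xi=4.61, d=3.6)
    q = np.linspace(0.2, 10.0, 400001)       # reciprocal µm
    I = butler_empirical(q, p)
    q_peak_um = q[np.argmax(I)]
    assert q_peak_um == pytest.approx(2 * np.pi / 4.61, abs=2.5e-5)
    assert q_peak_um * 1e-4 == pytest.approx(1.363e-4, rel=1e-3)  # Å^-1


def test_butler_domain_errors():
    with pytest.raises(ValueError):
        ButlerParams(I0=1.0, alpha=1.0, xi=4.61, d=3.6)
    with pytest.raises(ValueError):
        ButlerParams(I0=1.0, alpha=-0.2, xi=4.61, d=3.6)
    p = ButlerParams(I0=1.0, alpha=0.1, xi=4.61, d=3.6)
    with pytest.raises(ValueError):
        butler_empirical(np.array([-1.0]), p)


# ---------------------------------------------------------------------------
# Generalized Guinier-Porod
# ---------------------------------------------------------------------------

def test_gp_value_at_origin(gp_truth):
    assert guinier_porod(np.array([0.0]), gp_truth)[0] == gp_truth.scale


def test_gp_branches_agree_at_crossover(gp_truth):
    q1 = gp_truth.q1
    guinier = gp_truth.scale * np.exp(-(q1**2) * gp_truth.Rg**2 / 3)
    assert guinier_porod(np.array([q1]), gp_truth)[0] == pytest.approx(
        guinier, rel=1e-12)


def test_gp_continuity_of_value_and_slope(gp_truth):
    q1 = gp_truth.q1
    eps = 1e-7 * q1
    lo = guinier_porod(np.array([q1 - eps]), gp_truth)[0]
    hi = guinier_porod(np.array([q1 + eps]), gp_truth)[0]
    assert hi == pytest.approx(lo, rel=1e-6)
    dlo = (guinier_porod(np.array([q1 - eps]), gp_truth)[0]
           - guinier_porod(np.array([q1 - 2 * eps]), gp_truth)[0]) / eps
    dhi = (guinier_porod(np.array([q1 + 2 * eps]), gp_truth)[0]
           - guinier_porod(np.array([q1 + eps]), gp_truth)[0]) / eps
    assert dhi == pytest.approx(dlo, rel=1e-4)


def test_gp_crossover_is_smooth_matching_point(gp_truth):
    """Locate numerically where Guinier and Porod log-slopes coincide."""
    Rg, d = gp_truth.Rg, gp_truth.d
    # d ln(Guinier)/d ln q = -2 q^2 Rg^2/3; Porod slope = -d
    q1_num = brentq(lambda q: -2 * q**2 * Rg**2 / 3 + d, 1e-6, 100.0)
    assert gp_truth.q1 == pytest.approx(q1_num, rel=1e-10)
    assert gp_truth.q1 == pytest.approx(np.sqrt(3 * d / 2) / Rg, rel=1e-12)


def test_gp_domain_errors():
    with pytest.raises(ValueError):
        GuinierPorodParams(scale=1.0, Rg=-1.0, d=3.9)
    with pytest.raises(ValueError):
        GuinierPorodParams(scale=1.0, Rg=1.0, d=0.0)


# ---------------------------------------------------------------------------
# Sphere form factor
# ---------------------------------------------------------------------------

def test_sphere_ff_normalization_and_zero():
    assert sphere_form_factor(np.array([0.0]), 23.6)[0] == 1.0
    x0 = brentq(lambda x: np.tan(x) - x, 4.3, 4.6)   # first zero of amplitude
    assert sphere_form_factor(np.array([x0 / 23.6]), 23.6)[0] < 1e-12
    q = np.linspace(0, 1.0, 200)
    F = sphere_form_factor(q, 23.6)
    assert np.all((0 <= F) & (F <= 1))


def test_sphere_ff_matches_numerical_scattering_amplitude():
    """Independent oracle: quadrature of the uniform-sphere amplitude."""
    R, q = 23.6, 0.05
    amp, _ = quad(lambda r: 4 * np.pi * r**2 * np.sinc(q * r / np.pi), 0, R)
    amp /= 4 * np.pi * R**3 / 3
    assert sphere_form_factor(np.array([q]), R)[0] == pytest.approx(
        amp**2, rel=1e-10)


# ---------------------------------------------------------------------------
# Electrostatics
# ---------------------------------------------------------------------------

def test_debye_length_values():
    assert debye_length(0.15) == pytest.approx(7.85, abs=0.01)
    assert debye_length(9.2416) == pytest.approx(1.0, abs=1e-3)
    assert debye_length(0.0375) == pytest.approx(15.70, abs=0.01)
    with pytest.raises(ValueError):
        debye_length(0.0)


def test_charge_reproduces_fitted_surface_charges(horse_yukawa, human_yukawa):
    """Forward charge evaluation matches the fitted Z = 16 and 18 (±1 e)."""
    assert charge_from_contact_potential(horse_yukawa) == pytest.approx(16, abs=1)
    assert charge_from_contact_potential(human_yukawa) == pytest.approx(18, abs=1)


@pytest.mark.parametrize(
    "gamma_c,r_eff,phi,z_expected",
    [(2.5, 23.6, 0.256, 16), (1.9, 24.1, 0.319, 15), (0.1, 25.6, 0.229, 4),
     (3.3, 22.6, 0.249, 18), (3.1, 22.6, 0.279, 17), (1.3, 22.6, 0.224, 12)])
def test_charge_all_fitted_rows(gamma_c, r_eff, phi, z_expected):
    y = YukawaInteraction.from_physical(gamma_c, r_eff, phi, 7.8, T=293.0)
    assert charge_from_contact_potential(y) == pytest.approx(z_expected, abs=1)


def test_charge_zero_potential_and_monotonicity():
    base = dict(r_eff=23.6, phi=0.25, kappa_inv=7.8)
    y0 = YukawaInteraction.from_physical(0.0, **base)
    assert charge_from_contact_potential(y0) == 0.0
    zs = [charge_from_contact_potential(
        YukawaInteraction.from_physical(g, **base))
        for g in (0.5, 1.0, 2.0, 4.0)]
    assert np.all(np.diff(zs) > 0)


# ---------------------------------------------------------------------------
# Composite intensity
# ---------------------------------------------------------------------------

def test_composite_pure_components_and_round_trip(horse_yukawa):
    from rbcneutron.msa import rmsa_structure_factor
    q = np.linspace(0.02, 0.4, 100)
    F = sphere_form_factor(q, 23.6)
    S = rmsa_structure_factor(q, horse_yukawa)
    # I1 = 0, S = 1: pure scaled form factor
    assert composite_sans_intensity(q, 0.0, 2.2, 2.0, F, np.ones_like(q)) \
        == pytest.approx(2.0 * F)
    # I2 = 0: exact power law
    I_pl = composite_sans_intensity(q, 0.5, 2.2, 0.0, F, S)
    slopes = np.diff(np.log(I_pl)) / np.diff(np.log(q))
    assert np.max(np.abs(slopes + 2.2)) < 1e-9
    # algebraic decomposition recovers S
    I = composite_sans_intensity(q, 0.002, 2.2, 0.1, F, S)
    S_back = (I - 0.002 * q ** (-2.2)) / (0.1 * F)
    assert np.max(np.abs(S_back - S)) < 1e-10
    with pytest.raises(ValueError):
        composite_sans_intensity(np.array([0.0, 0.1]), 1.0, 2.0, 0.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Slit smearing / Lake desmearing
# ---------------------------------------------------------------------------

def _curve(q, I, sigma_frac=0.0):
    return SASCurve(q=q, I=I, sigma=sigma_frac * np.abs(I))


def test_smear_preserves_constant():
    q = np.geomspace(1e-4, 1e-2, 60)
    c = _curve(q, np.full_like(q, 3.7))
    sm = slit_smear(c, dq_v=2e-3, tail_d=0.0)
    assert sm.I == pytest.approx(np.full_like(q, 3.7), rel=1e-12)
    assert sm.smeared and sm.dq_v == 2e-3


def test_smear_matches_quadrature_oracle_power_law():
    """q^-4 smearing vs direct adaptive quadrature of the slit kernel."""
    q = np.geomspace(1e-3, 1e-1, 80)
    c = _curve(q, q**-4.0)
    dq_v = 5e-3
    sm = slit_smear(c, dq_v, tail_d=4.0)
    for qi in (3e-3, 1e-2, 5e-2):
        oracle = quad(lambda u: (qi**2 + u**2) ** -2, 0, dq_v,
                      epsrel=1e-12)[0] / dq_v
        got = np.interp(qi, sm.q, sm.I)
        # compare at grid point exactly
        j = np.argmin(np.abs(q - qi))
        oracle_j = quad(lambda u: (q[j]**2 + u**2) ** -2, 0, dq_v,
                        epsrel=1e-12)[0] / dq_v
        assert sm.I[j] == pytest.approx(oracle_j, rel=1e-6)


def test_smearing_lowers_isolated_peak(butler_truth):
    q = np.geomspace(2e-5, 2e-3, 150)
    I = butler_empirical(q / 1e-4, butler_truth)
    sm = slit_smear(_curve(q, I), dq_v=5e-5)
    assert sm.I.max() < I.max()


def test_smear_desmear_round_trip(butler_truth):
    """Lake desmearing inverts the slit kernel to <1% on the central decades."""
    q = np.geomspace(2e-5, 2e-3, 150)
    I = butler_empirical(q / 1e-4, butler_truth)
    c = SASCurve(q=q, I=I, sigma=1e-3 * I)
    ds = lake_desmear(slit_smear(c, dq_v=5e-5))
    central = (q > 4e-5) & (q < 1e-3)
    assert np.max(np.abs(ds.I[central] / I[central] - 1)) < 0.01


def test_desmear_constant_converges_immediately():
    q = np.geomspace(1e-4, 1e-2, 50)
    c = SASCurve(q=q, I=np.full_like(q, 2.0), sigma=np.full_like(q, 0.02),
                 smeared=True, dq_v=1e-3)
    out = lake_desmear(c)
    assert out.meta["desmear_iterations"] == 1
    assert out.I == pytest.approx(c.I, rel=1e-12)


def test_desmear_restores_form_factor_minimum():
    """First diffraction minimum depth restored to within 5% of the local max."""
    R = 23.6
    q = np.geomspace(0.02, 0.6, 200)
    F = sphere_form_factor(q, R)
    c = SASCurve(q=q, I=F, sigma=1e-3 * np.maximum(F, 1e-6))
    sm = slit_smear(c, dq_v=0.08, tail_d=4.0)
    from rbcneutron.sas_models import LakeConfig
    ds = lake_desmear(sm, config=LakeConfig(tail_d=4.0))
    # first minimum of the true curve
    i_min = next(i for i in range(1, len(q) - 1)
                 if F[i] < F[i - 1] and F[i] < F[i + 1])
    i_max2 = i_min + int(np.argmax(F[i_min:]))
    scale = F[i_max2]
    assert abs(sm.I[i_min] - F[i_min]) > 0.05 * scale   # smearing filled it in
    assert abs(ds.I[i_min] - F[i_min]) < 0.05 * scale   # desmearing restored it


def test_desmear_requires_smeared_flag():
    q = np.geomspace(1e-4, 1e-2, 50)
    with pytest.raises(ValueError):
        lake_desmear(SASCurve(q=q, I=np.ones_like(q), sigma=np.zeros_like(q)))
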