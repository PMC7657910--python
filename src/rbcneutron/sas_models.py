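"""Model functions for USANS/SANS curves.

Empirical morphology models for whole-cell (U)SANS, the normalized sphere
form factor, electrostatics helpers for the charged-hard-sphere picture,
the composite SANS intensity, and the slit-smearing/desmearing operators
for Bonse-Hart data.

The structure-factor machinery lives in :mod:`rbcneutron.msa` and is
re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .dataio import SASCurve
from .msa import (  # noqa: F401  (re-export)
    MSAConvergenceError,
    YukawaInteraction,
    oz_msa_oracle,
    percus_yevick_structure_factor,
    rmsa_structure_factor,
)

__all__ = [
    "ButlerParams", "GuinierPorodParams", "YukawaInteraction",
    "butler_empirical", "guinier_porod", "sphere_form_factor",
    "debye_length", "charge_from_contact_potential",
    "rmsa_structure_factor", "percus_yevick_structure_factor",
    "oz_msa_oracle", "composite_sans_intensity",
    "slit_smear", "lake_desmear", "LakeConfig",
]


@dataclass(frozen=True)
class ButlerParams:
    """Parameters of the single-correlation-peak empirical USANS model.

    I0 is the intensity at the peak position q* = 2*pi/xi; alpha in (0, 1)
    sets the high-q plateau I0*alpha relative to the peak; xi is the
    correlation length (micrometres in this package's USANS convention);
    d is the high-q power-law coefficient.
    """

    I0: float
    alpha: float
    xi: float
    d: float

    def __post_init__(self):
        if self.I0 <= 0:
            raise ValueError("I0 must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.xi <= 0:
            raise ValueError("xi must be > 0")
        if not 1 <= self.d <= 4.5:
            raise ValueError("d must lie in [1, 4.5]")


@dataclass(frozen=True)
class GuinierPorodParams:
    """Generalized Guinier-Porod model (globular s = 0 case).

    The crossover q1 = sqrt(3 d / 2) / Rg is derived, not fitted; the
    Guinier and Porod branches match in value and slope there.  ``scale``
    collapses the redundant product of overall and Guinier scales.
    """

    scale: float
    Rg: float
    d: float
    unit: str = "um"

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.Rg <= 0:
            raise ValueError("Rg must be > 0")
        if self.d <= 0:
            raise ValueError("d must be > 0")

    @property
    def q1(self):
        return np.sqrt(1.5 * self.d) / self.Rg


def butler_empirical(q, p: ButlerParams):
    """Empirical one-correlation-peak USANS intensity.

    I(q) = I0 * [alpha/(1-alpha) + 2 x^-d] / [1/(1-alpha) + x^-2d] with
    x = q*xi/(2*pi).  Equals I0 exactly at x = 1 and tends to I0*alpha at
    large q.  ``q`` and ``1/p.xi`` must be in consistent reciprocal units.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    x = q * p.xi / (2 * np.pi)
    # evaluate via x^d to keep large-q limit exact
    xd = x ** p.d
    num = p.alpha / (1 - p.alpha) + 2 / xd
    den = 1 / (1 - p.alpha) + 1 / xd**2
    return p.I0 * num / den


def guinier_porod(q, p: GuinierPorodParams):
    """Generalized Guinier-Porod intensity, continuous with continuous slope.

    Guinier branch scale*exp(-q^2 Rg^2/3) below the analytic crossover q1;
    power law above, with the Porod prefactor fixed by continuity.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    q1 = p.q1
    D = np.exp(-p.d / 2) * q1**p.d
    with np.errstate(divide="ignore"):
        porod = np.where(q > 0, D * q ** (-p.d), np.inf)
    return p.scale * np.where(q <= q1, np.exp(-(q**2) * p.Rg**2 / 3.0), porod)


def sphere_form_factor(q, R):
    """Normalized form factor of a uniform sphere, F(0) = 1.

    F(q) = [3 (sin(qR) - qR cos(qR)) / (qR)^3]^2.  A stand-in for a
    tabulated single-particle form factor; adequate for the compact,
    globular haemoglobin tetramer at SANS resolution.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    x = np.asarray(q, dtype=float) * R
    out = np.empty_like(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    amp = 3 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    out = np.where(small, 1.0 - x**2 / 10.0, amp) ** 2
    return out


def debye_length(ionic_strength):
    """Debye screening length in water at 293 K, in ångström.

    kappa^-1 = 0.304/sqrt(I[M]) nanometres = 3.04/sqrt(I) Å.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be > 0 M")
    return 3.04 / np.sqrt(ionic_strength)


def charge_from_contact_potential(y: YukawaInteraction):
    """Effective surface charge Z (elementary charges) of a macro-ion.

    Inverts the screened-Coulomb contact potential:
    Z = (2 + k) * sqrt(pi*eps*eps0*sigma * U_contact) / e with U_contact in
    joules (contact_potential * kB * T).  Monotone in the contact potential
    and in sigma.
    """
    u_joule = y.contact_potential * constants.KB * y.T
    sigma_m = y.sigma_hc * 1e-10
    return (2 + y.k) * np.sqrt(
        np.pi * y.epsilon * constants.EPS0 * sigma_m * u_joule
    ) / constants.E_CHARGE


def composite_sans_intensity(q, I1, d, I2, F, S):
    """Composite SANS model: power-law forward scattering + F(q)*S(q).

    I(q) = I1*q^-d + I2*F(q)*S(q), with F normalized to F(0) = 1.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q == 0) and d > 0:
        raise ValueError("q = 0 is outside the power-law domain for d > 0")
    F = np.asarray(F, dtype=float)
    S = np.asarray(S, dtype=float)
    return I1 * q ** (-d) + I2 * F * S


# ---------------------------------------------------------------------------
# Slit smearing (infinite-slit kernel with sharp cutoff) and Lake desmearing
# ---------------------------------------------------------------------------

_SM_N = 48
_SM_X, _SM_W = np.polynomial.legendre.leggauss(_SM_N)


def _tail_power_law(curve: SASCurve, decades=1.0):
    """Fit I = A q^-d on the top `decades` of the q range (log-log WLS)."""
    qmax = curve.q[-1]
    mask = curve.q >= qmax / 10**decades
    mask &= curve.I > 0
    if mask.sum() < 3:
        raise ValueError("insufficient positive tail points for extrapolation")
    lx, ly = np.log(curve.q[mask]), np.log(curve.I[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    return np.exp(intercept), -slope


def _make_evaluator(curve: SASCurve, tail_d=None):
    """Log-log interpolation inside the data range; power-law tail beyond."""
    lq, lI = np.log(curve.q), np.log(np.maximum(curve.I, 1e-300))
    if tail_d is None:
        A, d = _tail_power_law(curve)
    else:
        d = tail_d
        A = curve.I[-1] * curve.q[-1] ** d

    def ev(qq):
        qq = np.asarray(qq, dtype=float)
        inside = np.exp(np.interp(np.log(qq), lq, lI))
        tail = A * qq ** (-d)
        return np.where(qq <= curve.q[-1], inside, tail)

    return ev


def slit_smear(curve: SASCurve, dq_v, tail_d=None):
    """Forward infinite-slit smearing operator for Bonse-Hart geometry.

    I_s(q) = (1/dq_v) * int_0^dq_v I(sqrt(q^2 + u^2)) du, evaluated with
    fixed-order Gauss-Legendre quadrature.  Values beyond the measured q
    range are extrapolated with a power law fitted to the top decade
    (or with exponent ``tail_d`` if given).
    """
    if curve.smeared:
        raise ValueError("curve is already slit-smeared")
    if dq_v <= 0:
        raise ValueError("dq_v must be > 0")
    ev = _make_evaluator(curve, tail_d=tail_d)
    u = 0.5 * dq_v * (_SM_X + 1.0)          # nodes on (0, dq_v)
    w = 0.5 * _SM_W                          # weights sum to 1
    qq = np.sqrt(curve.q[:, None] ** 2 + u[None, :] ** 2)
    I_s = ev(qq) @ w
    return curve.copy_with(I=I_s, sigma=curve.sigma.copy(), smeared=True,
                           dq_v=dq_v)


@dataclass(frozen=True)
class LakeConfig:
    """Iterative desmearing knobs: multiplicative Lake updates, stopped on
    reduced chi-square between the re-smeared iterate and the measurement."""

    max_iter: int = 200
    chi2_tol: float = 1.05
    clip_negative: bool = True
    tail_d: float | None = None


def lake_desmear(curve: SASCurve, dq_v=None, config: LakeConfig = LakeConfig()):
    """Iterative (Lake) desmearing of a slit-smeared curve.

    Multiplicative update I_{n+1}(q) = I_n(q) * I_meas(q)/Smear(I_n)(q),
    started from the measured curve, stopped when the reduced chi-square of
    Smear(I_n) against the measurement drops below ``config.chi2_tol`` or
    after ``config.max_iter`` iterations (then the best iterate is returned
    with ``meta['desmear_converged'] = False``).
    """
    if not curve.smeared:
        raise ValueError("curve is not flagged as slit-smeared")
    dq_v = curve.dq_v if dq_v is None else dq_v
    I_meas = curve.I
    # chi2 weights: measured sigma, or 0.1% of I where sigma is zero/absent
    sig = np.where(curve.sigma > 0, curve.sigma, 1e-3 * np.abs(I_meas) + 1e-300)

    I_n = I_meas.copy()
    best, best_chi2 = I_n.copy(), np.inf
    converged = False
    n_done = 0
    for n_done in range(1, config.max_iter + 1):
        point = curve.copy_with(I=np.maximum(I_n, 1e-300), smeared=False,
                                dq_v=None)
        I_sm = slit_smear(point, dq_v, tail_d=config.tail_d).I
        chi2 = float(np.mean(((I_sm - I_meas) / sig) ** 2))
        if chi2 < best_chi2:
            best, best_chi2 = I_n.copy(), chi2
        if chi2 < config.chi2_tol:
            converged = True
            break
        ratio = np.where(I_sm > 0, I_meas / I_sm, 1.0)
        I_n = I_n * ratio
        if config.clip_negative:
            I_n = np.maximum(I_n, 0.0)

    meta = dict(curve.meta)
    meta.update(desmear_converged=converged, desmear_iterations=n_done,
                desmear_chi2_red=best_chi2)
    return curve.copy_with(I=best, smeared=False, dq_v=None, meta=meta)
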