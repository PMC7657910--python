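"""QENS model, resolution convolution and fitting.

The total dynamic structure factor of a protein in solution is modelled as
two superimposed Lorentzians sharing a narrow global-diffusion width,

    S_total(q, w) = A0(q) L(Gamma_G) + [1 - A0(q)] L(Gamma_G + Gamma_I),

where L(Gamma) is the unit-area Lorentzian of HWHM Gamma, A0(q) is the
elastic incoherent structure factor (EISF), Gamma_G(q) = hbar D_eff q^2
carries global (rotation-inflated) diffusion and Gamma_I the internal
diffusive broadening.  The model is numerically convolved with the
measured instrumental resolution and fitted per q with a linear
background.  Downstream reductions: an origin-anchored Gamma_G vs q^2 line
for D_eff, an error-weighted mean of Gamma_I for the internal correlation
time tau = hbar/<Gamma>, and a Gaussian-confinement fit of the EISF,
A0(q) = (1-p) exp(-<x^2> q^2) + p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import CubicSpline
from scipy.signal import fftconvolve

from .constants import CM2_PER_A2, HBAR_UEV_PS, HBAR_UEV_S, ROTATION_FACTOR
from .dataio import QENSSpectrum

__all__ = [
    "PerQFit", "DiffusionResult", "InternalDynamicsResult", "EISFResult",
    "lorentzian", "model_total_sqw", "ResolutionConvolver",
    "convolve_resolution", "subtract_buffer", "fit_spectrum",
    "fit_global_diffusion", "correlation_time", "fit_eisf", "screen_per_q_fits",
    "sphere_to_gaussian_msd", "gamma_global",
]


@dataclass
class PerQFit:
    """Two-Lorentzian fit of one spectrum at fixed q."""

    q: float
    A0: float
    Gamma_G: float       # narrow HWHM, µeV
    Gamma_I: float       # internal HWHM (broad minus narrow), µeV
    scale: float
    bkg_a: float
    bkg_b: float
    errors: dict = field(default_factory=dict)
    chi2_red: float = np.nan
    success: bool = True
    at_bound: bool = False

    @property
    def usable(self):
        """Converged with no width pinned at a bound."""
        return self.success and not self.at_bound


@dataclass
class DiffusionResult:
    """Apparent diffusion coefficient from the Gamma_G(q) = D_eff q^2 line."""

    D_eff: float         # cm^2/s, rotation-inflated
    D_eff_err: float
    T: float
    chi2_red: float
    n_points: int
    rotation_factor: float = ROTATION_FACTOR

    @property
    def D_trans(self):
        """Centre-of-mass self-diffusion, D_eff corrected for rotation."""
        return self.D_eff / self.rotation_factor


@dataclass
class InternalDynamicsResult:
    """q-averaged internal linewidth and correlation time."""

    Gamma_mean: float    # µeV
    Gamma_mean_err: float
    tau: float           # ps, = hbar/<Gamma>
    tau_err: float
    q2_slope_p: float | None = None   # p-value of a Gamma_I ~ q^2 trend


@dataclass
class EISFResult:
    """Gaussian-confinement EISF parameters."""

    x2: float            # mean square displacement, Å^2
    p_immobile: float
    x2_err: float
    p_err: float
    degenerate: bool = False


def lorentzian(omega, gamma):
    """Unit-area Lorentzian of HWHM ``gamma`` (same units as omega)."""
    if gamma < 0:
        raise ValueError("HWHM must be >= 0")
    omega = np.asarray(omega, dtype=float)
    g = max(gamma, 1e-12)
    return (g / np.pi) / (g**2 + omega**2)


def gamma_global(q, D_eff_cm2):
    """Global-diffusion HWHM in µeV: Gamma = hbar * D[Å^2/s] * q[Å^-1]^2."""
    return HBAR_UEV_S * (D_eff_cm2 / CM2_PER_A2) * np.asarray(q) ** 2


def model_total_sqw(omega, A0, Gamma_G, Gamma_I, scale=1.0, bkg_a=0.0,
                    bkg_b=0.0):
    """Two-Lorentzian quasi-elastic model plus linear background.

    scale * [A0 L(Gamma_G) + (1 - A0) L(Gamma_G + Gamma_I)] + a + b*omega.
    With Gamma_I = 0 the two components coincide in a single Lorentzian.
    """
    if not 0 <= A0 <= 1:
        raise ValueError("A0 must lie in [0, 1]")
    omega = np.asarray(omega, dtype=float)
    narrow = lorentzian(omega, Gamma_G)
    broad = lorentzian(omega, Gamma_G + Gamma_I)
    return scale * (A0 * narrow + (1 - A0) * broad) + bkg_a + bkg_b * omega


class ResolutionConvolver:
    """Discrete convolution with a tabulated instrumental resolution.

    The model is evaluated on an oversampled grid extending beyond the data
    window by at least ten resolution widths, convolved with the unit-area
    resolution kernel (trapezoid weights) and resampled onto the data grid.
    """

    def __init__(self, omega, resolution, oversample=3, pad=None):
        omega = np.asarray(omega, dtype=float)
        steps = np.diff(omega)
        if np.ptp(steps) > 1e-6 * steps.mean():
            raise ValueError("omega grid must be uniform for convolution")
        self.omega = omega
        h = steps.mean()
        self.h_fine = h / oversample
        self.oversample = oversample
        res = np.asarray(resolution, dtype=float)
        area = np.trapezoid(res, omega)
        res = res / area
        # resolution width from its variance (FWHM if Gaussian-like)
        mu = np.trapezoid(omega * res, omega)
        var = np.trapezoid((omega - mu) ** 2 * res, omega)
        fwhm = 2.3548 * np.sqrt(max(var, (h / 2) ** 2))
        if pad is None:
            pad = 10.0 * fwhm
        self.n_pad = int(np.ceil(pad / self.h_fine))
        n_fine = (len(omega) - 1) * oversample + 1 + 2 * self.n_pad
        self.omega_fine = (omega[0] - self.n_pad * self.h_fine
                           + self.h_fine * np.arange(n_fine))
        # kernel on centred fine offsets spanning the tabulated range
        # (cubic resampling: the coarse tabulation would otherwise limit
        # convolution accuracy to O(h^2))
        half = int(np.floor((omega[-1] - omega[0]) / 2 / self.h_fine))
        off = self.h_fine * np.arange(-half, half + 1)
        spline = CubicSpline(omega, res, extrapolate=False)
        kern = np.nan_to_num(spline(off + mu), nan=0.0)
        kern = np.maximum(kern, 0.0)
        kern /= np.trapezoid(kern, off)
        self.kernel = kern

    def apply(self, model_fn, *args, **kwargs):
        """Convolve ``model_fn(omega_fine, ...)`` and resample to the data grid."""
        vals = model_fn(self.omega_fine, *args, **kwargs)
        return self.apply_to_values(vals)

    def apply_to_values(self, vals_fine):
        conv = fftconvolve(np.asarray(vals_fine, dtype=float),
                           self.kernel, mode="same") * self.h_fine
        return conv[self.n_pad::self.oversample][:len(self.omega)]


def convolve_resolution(omega_model, model_vals, omega_data, resolution,
                        oversample=3):
    """Convolve a tabulated model with the resolution, on the data grid.

    ``model_vals`` must be tabulated on ``omega_model``, a grid extending
    beyond the data window; values are interpolated onto the internal fine
    grid (a warning-free resampling) before the discrete convolution.
    """
    conv = ResolutionConvolver(omega_data, resolution, oversample=oversample)
    vals_fine = np.interp(conv.omega_fine, omega_model, model_vals)
    return conv.apply_to_values(vals_fine)


def subtract_buffer(sample: QENSSpectrum, buffer: QENSSpectrum, scale=1.0):
    """Subtract a (scaled) solvent spectrum; uncertainties add in quadrature.

    Negative bins are retained, flagged in ``meta['has_negative_bins']``.
    """
    if len(sample.omega) != len(buffer.omega) or np.max(
            np.abs(sample.omega - buffer.omega)) > 1e-9:
        raise ValueError("sample and buffer must share the omega grid")
    S = sample.S - scale * buffer.S
    sigma = np.hypot(sample.sigma, scale * buffer.sigma)
    meta = dict(sample.meta)
    meta["buffer_scale"] = scale
    meta["has_negative_bins"] = bool(np.any(S < 0))
    return QENSSpectrum(q=sample.q, omega=sample.omega, S=S, sigma=sigma,
                        resolution=sample.resolution, meta=meta)


def _fit_one(conv, omega, S, sigma, x0, bounds):
    def resid(x):
        A0, gG, gI, scale, a, b = x
        model = conv.apply(model_total_sqw, A0, gG, gI, scale, a, b)
        return (model - S) / sigma

    return optimize.least_squares(resid, x0, bounds=bounds, method="trf",
                                  xtol=1e-12, ftol=1e-12, gtol=1e-12)


def fit_spectrum(spectrum: QENSSpectrum, oversample=3, multi_start=True):
    """Fit the resolution-convolved two-Lorentzian model to one spectrum.

    Independent per-q bounded weighted least squares; the constraint
    Gamma_I >= 0 orders the two components by construction.  A second
    start with swapped narrow/broad initial widths guards against
    label-switching local minima.
    """
    if spectrum.resolution is None:
        raise ValueError("spectrum has no resolution companion")
    if len(spectrum.omega) < 50:
        raise ValueError("need at least 50 energy bins")
    omega, S = spectrum.omega, spectrum.S
    sigma = np.where(spectrum.sigma > 0, spectrum.sigma,
                     np.max(spectrum.sigma) * 1e-3 + 1e-12)
    conv = ResolutionConvolver(omega, spectrum.resolution,
                               oversample=oversample)
    span = omega[-1] - omega[0]
    scale0 = max(np.trapezoid(S - np.median(S[:5]), omega), 1e-12)
    # widths beyond the window are indistinguishable from the linear
    # background; bounding them keeps the broad component quasi-elastic
    bounds = (np.array([0.0, 1e-4, 0.0, 1e-12, -np.inf, -np.inf]),
              np.array([1.0, span / 2, span / 2, np.inf, np.inf, np.inf]))
    starts = [np.array([0.6, 0.5, 3.0, scale0, max(np.median(S[:5]), 0.0), 0.0])]
    if multi_start:
        starts.append(np.array([0.6, 3.0, 0.5, scale0,
                                max(np.median(S[:5]), 0.0), 0.0]))
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = _fit_one(conv, omega, S, sigma, x0, bounds)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return PerQFit(q=spectrum.q, A0=np.nan, Gamma_G=np.nan,
                       Gamma_I=np.nan, scale=np.nan, bkg_a=np.nan,
                       bkg_b=np.nan, success=False)
    A0, gG, gI, scale, a, b = best.x
    dof = max(len(S) - 6, 1)
    chi2_red = 2 * best.cost / dof
    # covariance from the weighted Jacobian
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.inv(JTJ)
        perr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        perr = np.full(6, np.nan)
    names = ["A0", "Gamma_G", "Gamma_I", "scale", "bkg_a", "bkg_b"]
    # a width pinned at its upper bound means the two-component
    # decomposition was not identifiable for this spectrum
    at_bound = bool(gG > 0.999 * bounds[1][1] or gI > 0.999 * bounds[1][2])
    return PerQFit(q=spectrum.q, A0=A0, Gamma_G=gG, Gamma_I=gI, scale=scale,
                   bkg_a=a, bkg_b=b,
                   errors=dict(zip(names, perr)), chi2_red=chi2_red,
                   success=True, at_bound=at_bound)


def screen_per_q_fits(fits):
    """Drop per-q fits whose decomposition visibly failed.

    Two physics screens: a width pinned at its bound (flagged by
    ``fit_spectrum``), and a violation of EISF monotonicity — A0(q) must
    not increase with q for confined motion, so a fit whose A0 jumps above
    the running minimum by more than three combined sigma took the wrong
    branch of the narrow/broad decomposition.
    """
    out = []
    run_min, run_err = np.inf, 0.0
    for f in sorted([f for f in fits if f.usable], key=lambda f: f.q):
        if f.A0 > run_min + 3 * max(f.errors.get("A0", 0.0), run_err):
            continue
        if f.A0 < run_min:
            run_min, run_err = f.A0, f.errors.get("A0", 0.0)
        out.append(f)
    return out


def fit_global_diffusion(gamma_G, gamma_err, q, T, rotation_factor=ROTATION_FACTOR):
    """Error-weighted origin-anchored line Gamma_G = hbar D q^2.

    Returns the apparent diffusion coefficient in cm^2/s; its
    rotation-corrected value is ``result.D_trans = D_eff/1.27``.
    """
    gamma_G = np.asarray(gamma_G, dtype=float)
    gamma_err = np.asarray(gamma_err, dtype=float)
    q = np.asarray(q, dtype=float)
    ok = np.isfinite(gamma_G) & np.isfinite(gamma_err)
    if ok.sum() < 4:
        raise ValueError("need at least 4 usable (q, Gamma_G) points")
    g, e, qq = gamma_G[ok], gamma_err[ok], q[ok]
    w = 1.0 / np.where(e > 0, e, np.min(e[e > 0]) if np.any(e > 0) else 1.0) ** 2
    q2 = qq**2
    slope = np.sum(w * g * q2) / np.sum(w * q2**2)       # µeV per Å^-2
    base_err = 1.0 / np.sqrt(np.sum(w * q2**2))
    r = g - slope * q2
    chi2_red = float(np.sum(w * r**2) / max(len(g) - 1, 1))
    # per-q width errors are linearized and can understate the real scatter;
    # take the larger of the misfit-scaled error and the
    # heteroscedasticity-robust (sandwich) estimate
    sandwich = (np.sqrt(np.sum((w * q2 * r) ** 2)) / np.sum(w * q2**2)
                * np.sqrt(len(g) / max(len(g) - 1, 1)))
    slope_err = max(base_err * np.sqrt(max(chi2_red, 1.0)), sandwich)
    D_A2_s = slope / HBAR_UEV_S
    return DiffusionResult(D_eff=D_A2_s * CM2_PER_A2,
                           D_eff_err=(slope_err / HBAR_UEV_S) * CM2_PER_A2,
                           T=T, chi2_red=chi2_red, n_points=int(ok.sum()),
                           rotation_factor=rotation_factor)


def correlation_time(gamma_I, gamma_err=None, q=None):
    """Internal correlation time tau = hbar/<Gamma> from per-q linewidths.

    <Gamma> is the error-weighted mean of Gamma_I over q.  If q values are
    supplied, the absence of a Gamma_I ~ q^2 trend (expected for localized
    internal motion) is checked by linear regression and the p-value of the
    slope recorded.
    """
    gamma_I = np.asarray(gamma_I, dtype=float)
    ok = np.isfinite(gamma_I)
    if ok.sum() < 1:
        raise ValueError("need at least one finite Gamma_I")
    g = gamma_I[ok]
    if gamma_err is not None:
        e = np.asarray(gamma_err, dtype=float)[ok]
        w = 1.0 / np.where(e > 0, e, np.inf) ** 2
        if not np.any(np.isfinite(w) & (w > 0)):
            w = np.ones_like(g)
    else:
        w = np.ones_like(g)
    gmean = float(np.sum(w * g) / np.sum(w))
    # quote the spread over q, not the standard error of the mean: the
    # internal width is a q-averaged effective quantity and per-sample
    # tables report it with its dispersion
    if len(g) > 1:
        gerr = float(np.sqrt(np.sum(w * (g - gmean) ** 2) / np.sum(w)
                             * len(g) / (len(g) - 1)))
    else:
        gerr = float(1.0 / np.sqrt(np.sum(w))) if gamma_err is not None else 0.0
    slope_p = None
    if q is not None and ok.sum() >= 3:
        reg = stats.linregress(np.asarray(q, dtype=float)[ok] ** 2, g)
        slope_p = float(reg.pvalue)
    tau = HBAR_UEV_PS / gmean
    tau_err = tau * gerr / gmean
    return InternalDynamicsResult(Gamma_mean=gmean, Gamma_mean_err=gerr,
                                  tau=tau, tau_err=tau_err, q2_slope_p=slope_p)


def fit_eisf(A0, A0_err, q):
    """Gaussian-confinement fit A0(q) = (1-p) exp(-<x^2> q^2) + p."""
    A0 = np.asarray(A0, dtype=float)
    q = np.asarray(q, dtype=float)
    ok = np.isfinite(A0)
    if ok.sum() < 4:
        raise ValueError("need at least 4 EISF points")
    A, qq = A0[ok], q[ok]
    err = np.asarray(A0_err, dtype=float)[ok]
    err = np.where(err > 0, err, np.max(err) * 1e-3 + 1e-9)

    def model(qv, x2, p):
        return (1 - p) * np.exp(-x2 * qv**2) + p

    popt, pcov = optimize.curve_fit(
        model, qq, A, p0=[1.0, 0.5], sigma=err, absolute_sigma=True,
        bounds=([0.0, 0.0], [np.inf, 1.0]), maxfev=20000)
    # inflate the covariance when the fit misses beyond the supplied errors
    resid = (model(qq, *popt) - A) / err
    chi2_red = float(np.sum(resid**2) / max(len(A) - 2, 1))
    perr = np.sqrt(np.diag(pcov) * max(chi2_red, 1.0))
    # flat A0: x2 unidentifiable, p absorbs the level
    spread = np.ptp(A)
    degenerate = spread < 3 * np.median(err) or popt[0] < 1e-6
    return EISFResult(x2=popt[0], p_immobile=popt[1], x2_err=perr[0],
                      p_err=perr[1], degenerate=bool(degenerate))


def sphere_to_gaussian_msd(r):
    """Convert a diffusion-in-a-sphere radius to the Gaussian-model MSD.

    <x^2> = r^2/5 (r in Å, result in Å^2).
    """
    if r < 0:
        raise ValueError("radius must be >= 0")
    return r**2 / 5.0
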