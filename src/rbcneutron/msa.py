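"""Structure factors for charged hard-sphere (Yukawa) fluids.

Implements the mean spherical approximation (MSA) for a hard-core
one-Yukawa fluid via the Baxter-Wertheim factorization,

    1 - rho*c^(q) = Q^(q) Q^(-q),

with the factor function

    Q(r) = q0(r) + D exp(-z r),        q0 supported on (0, sigma),
    q0'(x) = a x + b + ct exp(-z x),   x = r/sigma in (0, 1),

whose five parameters (a, b, ct, D, Hz) satisfy a small algebraic system
derived from the MSA closure (g(r) = 0 inside the core, c(r) = -beta*u(r)
outside).  The system is solved numerically with continuation from the
Percus-Yevick (zero-charge) limit, to which it reduces exactly.

When the MSA pair correlation at contact is negative the standard
rescaling construction is applied: the hard core is inflated at fixed
number density until g(sigma*+) = 0 and the structure factor of the
rescaled system is returned (RMSA).

A brute-force numerical Ornstein-Zernike solver with the MSA closure
(`oz_msa_oracle`) is provided as an independent verification route; it is
used only in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.fft import dst

__all__ = [
    "YukawaInteraction",
    "MSAConvergenceError",
    "percus_yevick_structure_factor",
    "rmsa_structure_factor",
    "oz_msa_oracle",
]


class MSAConvergenceError(RuntimeError):
    """Raised when the MSA parameter solve or the rescaling search fails.

    Carries diagnostics in ``.details``.
    """

    def __init__(self, message: str, **details):
        super().__init__(message)
        self.details = details


@dataclass(frozen=True)
class YukawaInteraction:
    """State of a screened-Coulomb (hard-core one-Yukawa) interaction.

    The pair potential in units of kB*T is

        beta*U(x) = gamma * exp(-k x) / x   for x = r/sigma > 1,
        beta*U(x) = inf                     for x < 1,

    so ``contact_potential`` = gamma*exp(-k) is the potential at particle
    contact in kB*T units.

    Parameters
    ----------
    contact_potential : float
        Contact potential gamma*exp(-k), in kB*T.  >= 0 (repulsive).
    k : float
        Dimensionless screening kappa*sigma.
    sigma_hc : float
        Hard-core diameter sigma = 2*R_eff, in ångström.
    phi : float
        Particle volume fraction, in [0, 0.74).
    kappa_inv : float
        Debye screening length, ångström.  Must satisfy k = sigma_hc/kappa_inv.
    T : float
        Temperature, kelvin.
    epsilon : float
        Solvent dielectric constant.
    """

    contact_potential: float
    k: float
    sigma_hc: float
    phi: float
    kappa_inv: float = field(default=None)  # type: ignore[assignment]
    T: float = 293.0
    epsilon: float = 80.0

    def __post_init__(self):
        if self.kappa_inv is None:
            object.__setattr__(self, "kappa_inv", self.sigma_hc / self.k)
        if self.contact_potential < 0:
            raise ValueError("contact_potential must be >= 0 (repulsive Yukawa)")
        if self.k <= 0:
            raise ValueError("screening parameter k must be > 0")
        if self.sigma_hc <= 0:
            raise ValueError("hard-core diameter must be > 0")
        if not 0 <= self.phi < 0.74:
            raise ValueError(f"volume fraction {self.phi} outside [0, 0.74)")
        if abs(self.k - self.sigma_hc / self.kappa_inv) > 1e-6 * self.k:
            raise ValueError("inconsistent k, sigma_hc and kappa_inv")

    @classmethod
    def from_physical(cls, contact_potential, r_eff, phi, kappa_inv,
                      T=293.0, epsilon=80.0):
        """Build from effective radius (Å) and Debye length (Å)."""
        sigma = 2.0 * r_eff
        return cls(contact_potential=contact_potential, k=sigma / kappa_inv,
                   sigma_hc=sigma, phi=phi, kappa_inv=kappa_inv, T=T,
                   epsilon=epsilon)


# ---------------------------------------------------------------------------
# Percus-Yevick hard spheres (analytic)
# ---------------------------------------------------------------------------

def percus_yevick_structure_factor(q_sigma, phi):
    """Analytic Percus-Yevick S(q) for hard spheres.

    Parameters
    ----------
    q_sigma : array_like
        Dimensionless momentum transfer q*sigma.
    phi : float
        Volume fraction.
    """
    s = np.asarray(q_sigma, dtype=float)
    eta = float(phi)
    if not 0 <= eta < 0.74:
        raise ValueError("phi outside [0, 0.74)")
    if eta == 0.0:
        return np.ones_like(s)
    al = (1 + 2 * eta) ** 2 / (1 - eta) ** 4
    be = -6 * eta * (1 + eta / 2) ** 2 / (1 - eta) ** 4
    ga = eta * al / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sn, cs = np.sin(s), np.cos(s)
        f1 = (sn - s * cs) / s**3
        f2 = (2 * s * sn + (2 - s**2) * cs - 2) / s**4
        f3 = (-(s**4) * cs + 4 * ((3 * s**2 - 6) * cs + (s**3 - 6 * s) * sn + 6)) / s**6
        nc = -24 * eta * (al * f1 + be * f2 + ga * f3)
    # q -> 0 limit (series)
    small = s < 1e-4
    if np.any(small):
        nc0 = -24 * eta * (al / 3 + be / 4 + ga / 6)
        nc = np.where(small, nc0, nc)
    return 1.0 / (1.0 - nc)


# ---------------------------------------------------------------------------
# MSA via Baxter factorization
# ---------------------------------------------------------------------------

_GL_N = 96
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GL_N)
#: Gauss-Legendre nodes/weights mapped to (0, 1)
_T = 0.5 * (_GL_X + 1.0)
_W = 0.5 * _GL_W


def _q0(t, a, b, ct, z):
    """Core factor function q0(t) on (0,1), with q0(1) = 0."""
    return (0.5 * a * (t**2 - 1.0) + b * (t - 1.0)
            - (ct / z) * (np.exp(-z * t) - np.exp(-z)))


def _residuals(x, K, z, eta):
    a, b, ct, D, Hz = x
    ez = np.exp(-z)
    q0t = _q0(_T, a, b, ct, z)
    a0 = _W @ q0t
    b0 = _W @ (_T * q0t)
    Ghat = _W @ (q0t * np.exp(-z * _T)) + D / (2 * z)
    # M = -int_0^1 q0(t) [e^-z((1-t)/z + 1/z^2) - e^-z(t+1)(1/z + 1/z^2)] dt
    #     + D*Jz*e^-2z/(2z)
    kern = ez * ((1 - _T) / z + 1 / z**2) - np.exp(-z * (_T + 1)) * (1 / z + 1 / z**2)
    Jz = -ez * (1 / z + 1 / z**2) - np.exp(z) * (1 / z - 1 / z**2)
    M = -(_W @ (q0t * kern)) + D * Jz * ez**2 / (2 * z)
    r1 = z * D * (1 - 12 * eta * Ghat) + K * np.exp(z)
    r2 = a - 1 + 12 * eta * (a0 + D / z)
    r3 = b - 12 * eta * (b0 + D / z**2)
    r4 = ct - z * D + 12 * eta * D * (ez * (1 / z + 1 / z**2) + Hz)
    r5 = Hz - 0.5 * D * ez**2 - 12 * eta * (M + Ghat * Hz - D * Hz * ez**2 / (2 * z))
    return np.array([r1, r2, r3, r4, r5])


def _py_guess(eta):
    a = (1 + 2 * eta) / (1 - eta) ** 2
    b = -3 * eta / (2 * (1 - eta) ** 2)
    return a, b


def _solve_coeffs(K, z, eta, x0=None):
    """Solve the 5-parameter MSA system; continuation in K on failure."""
    if x0 is None:
        a, b = _py_guess(eta)
        x0 = np.array([a, b, 0.0, 0.0, 0.0])
        if K > 0:
            # linearized D from the tail-matching equation at the PY point
            Ghat0 = (_W @ (_q0(_T, a, b, 0.0, z) * np.exp(-z * _T)))
            denom = z * (1 - 12 * eta * Ghat0)
            if abs(denom) > 1e-12:
                x0[3] = -K * np.exp(z) / denom
    scale = max(1.0, abs(K) * np.exp(z))

    def _accept(sol):
        return np.max(np.abs(sol.fun)) < 1e-9 * scale

    sol = optimize.root(_residuals, x0, args=(K, z, eta), method="hybr",
                        options={"xtol": 1e-13})
    if _accept(sol):
        return sol.x
    # continuation: ramp the coupling up from zero
    a, b = _py_guess(eta)
    x = np.array([a, b, 0.0, 0.0, 0.0])
    for frac in np.linspace(0.1, 1.0, 10):
        sol = optimize.root(_residuals, x, args=(frac * K, z, eta),
                            method="hybr", options={"xtol": 1e-13})
        if not _accept(sol):
            raise MSAConvergenceError(
                "MSA parameter solve failed during continuation",
                K=K, z=z, eta=eta, frac=frac, residual=sol.fun.tolist())
        x = sol.x
    return x


def _structure_factor_from_coeffs(q_sigma, coeffs, z, eta):
    """S(q*sigma) = 1/|Q^(s)|^2 from the solved factor function."""
    a, b, ct, D, _ = coeffs
    s = np.atleast_1d(np.asarray(q_sigma, dtype=float))
    q0t = _q0(_T, a, b, ct, z)
    phase = np.exp(1j * np.outer(s, _T))  # (nq, nGL)
    T0 = phase @ (_W * q0t)
    Qhat = 1.0 - 12 * eta * (T0 + D / (z - 1j * s))
    return 1.0 / np.abs(Qhat) ** 2


def _contact_value(coeffs, z, eta):
    """Pair correlation at contact, g(sigma+)."""
    a, b, ct, D, Hz = coeffs
    ez = np.exp(-z)
    q0t = _q0(_T, a, b, ct, z)
    c2 = _W @ ((1 - _T) * q0t)
    i0 = (1 - np.exp(-2 * z)) / z
    i1 = (1 - np.exp(-2 * z) * (1 + 2 * z)) / z**2
    c2 += D * (i0 - i1)
    h1 = z * D * ez - 12 * eta * (c2 + D * ez * Hz)
    return 1.0 + h1


def _scaled_params(y: YukawaInteraction, t: float):
    """Map (K, z, eta) to the system with core inflated by factor t >= 1.

    Number density is held fixed, so eta* = eta t^3; the physical potential
    is re-expressed relative to the inflated core: z* = z t and
    K* = (K/t) exp(-z (t - 1)).
    """
    K, z, eta = y.contact_potential, y.k, y.phi
    return (K / t) * np.exp(-z * (t - 1.0)), z * t, eta * t**3


def rmsa_structure_factor(q_grid, y: YukawaInteraction, return_details=False):
    """Rescaled-MSA structure factor of a charged hard-sphere fluid.

    Parameters
    ----------
    q_grid : array_like
        Momentum transfer in reciprocal ångström (positive).
    y : YukawaInteraction
        Interaction state; ``y.sigma_hc`` sets the length scale.
    return_details : bool
        If True, also return a dict with the rescaling factor and the
        contact value of the (possibly rescaled) solution.

    Returns
    -------
    S : ndarray
        Structure factor on ``q_grid``; S >= 0 and S -> 1 at large q.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q_grid must be positive")
    if y.phi == 0:
        S = np.ones_like(q)
        return (S, {"rescale": 1.0, "g_contact": 1.0}) if return_details else S

    K, z, eta = y.contact_potential, y.k, y.phi
    coeffs = _solve_coeffs(K, z, eta)
    g1 = _contact_value(coeffs, z, eta)
    t = 1.0
    if g1 < 0:
        # inflate the core until the contact value vanishes
        def gfun(tt):
            Ks, zs, es = _scaled_params(y, tt)
            return _contact_value(_solve_coeffs(Ks, zs, es), zs, es)

        t_hi, g_hi = 1.0, g1
        eta_cap = 0.72
        t_max = (eta_cap / eta) ** (1 / 3)
        for tt in np.linspace(1.0, t_max, 40)[1:]:
            g_hi = gfun(tt)
            t_hi = tt
            if g_hi >= 0:
                break
        if g_hi < 0:
            raise MSAConvergenceError(
                "rescaling search found no non-negative contact value "
                "before the packing cap", K=K, z=z, eta=eta, t_max=t_max,
                g_at_cap=g_hi)
        t = optimize.brentq(gfun, t_hi - (t_max - 1.0) / 39, t_hi,
                            xtol=1e-10) if g_hi > 0 else t_hi
        Ks, zs, es = _scaled_params(y, t)
        coeffs = _solve_coeffs(Ks, zs, es)
        g1 = _contact_value(coeffs, zs, es)
        z_eval, eta_eval = zs, es
    else:
        z_eval, eta_eval = z, eta

    S = _structure_factor_from_coeffs(q * y.sigma_hc * t, coeffs, z_eval, eta_eval)
    S = np.maximum(S, 0.0)
    if return_details:
        return S, {"rescale": t, "g_contact": float(g1)}
    return S


# ---------------------------------------------------------------------------
# Numerical OZ solver with the MSA closure (verification oracle)
# ---------------------------------------------------------------------------

def oz_msa_oracle(y: YukawaInteraction, q_grid=None, n_r=2**15, dr=None,
                  mixing=0.5, tol=1e-10, max_iter=5000):
    """Brute-force MSA structure factor from the Ornstein-Zernike equation.

    Solves the OZ equation with the MSA closure (c(r) = -beta*U(r) outside
    the hard core, h(r) = -1 inside) by Picard iteration with mixing on a
    fine radial grid, and returns S(q) = 1/(1 - rho_n c^(q)) interpolated
    onto ``q_grid`` (in reciprocal ångström; defaults to the internal grid
    in units of 1/sigma).  Used only as a test oracle.
    """
    sigma = y.sigma_hc
    eta = y.phi
    if dr is None:
        dr = 40.96 / n_r  # r_max ~ 41 sigma, in units of sigma
    r = dr * np.arange(1, n_r + 1)
    dq = np.pi / ((n_r + 1) * dr)
    qs = dq * np.arange(1, n_r + 1)   # q in units of 1/sigma
    rho = 6 * eta / np.pi             # number density, sigma^-3

    core = r < 1.0
    with np.errstate(over="ignore"):
        beta_u = np.where(core, 0.0, y.contact_potential * np.exp(-y.k * (r - 1.0)) / r)

    def fwd(f):
        # 4*pi/q * int r f sin(qr) dr
        return (2 * np.pi * dr / qs) * dst(r * f, type=1)

    def inv(F):
        # 1/(2 pi^2 r) * int q F sin(qr) dq
        return (dq / (4 * np.pi**2 * r)) * dst(qs * F, type=1)

    # initial guess: PY-like core, closure tail
    c = np.where(core, -1.0, -beta_u)
    for it in range(max_iter):
        chat = fwd(c)
        denom = 1.0 - rho * chat
        if np.any(denom <= 0):
            raise MSAConvergenceError("OZ iteration left the physical branch",
                                      iteration=it)
        gamma_hat = rho * chat**2 / denom
        gam = inv(gamma_hat)
        c_new = np.where(core, -1.0 - gam, -beta_u)
        delta = np.max(np.abs(c_new - c))
        c = (1 - mixing) * c + mixing * c_new
        if delta < tol:
            break
    else:
        raise MSAConvergenceError("OZ-MSA iteration did not converge",
                                  max_iter=max_iter, delta=float(delta))

    S_internal = 1.0 / (1.0 - rho * fwd(c))
    if q_grid is None:
        return qs / sigma, S_internal
    q_grid = np.asarray(q_grid, dtype=float)
    return np.interp(q_grid * sigma, qs, S_internal)
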