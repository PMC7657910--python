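"""Crowded-solution relations between viscosity, diffusion and concentration.

Short-time self-diffusion of a globular protein in a concentrated solution
follows the hard-particle viscosity law

    eta(c)/eta0 = exp( [eta] c / (1 - (k/v) [eta] c) ),

with intrinsic viscosity [eta] (l/g) and self-crowding ratio k/v
(v = 2.5 is the Einstein coefficient for ideal spheres, so k/v = 0.4 for
ideal hard spheres; deviations encode shape, hydration and hydrodynamics).
Diffusion is its reciprocal, D(c) = D0 * eta0/eta(c), which inverts in
closed form to give the concentration from a measured diffusion
coefficient.  QENS apparent diffusion coefficients carry a rotational
contribution; for spheres they exceed centre-of-mass diffusion by the
factor 1.27 and are divided by it before inversion.

Concentrations are handled in g/l, numerically equal to mg/ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HARD_SPHERE_H_SLOPE, ROTATION_FACTOR, UPSILON_HB

__all__ = [
    "CrowdingParams", "relative_viscosity", "diffusion_at_concentration",
    "concentration_from_diffusion", "hydrodynamic_function",
    "hard_sphere_H", "volume_change", "expected_lysate_concentration",
    "phi_from_concentration",
]


@dataclass(frozen=True)
class CrowdingParams:
    """Haemoglobin crowding parameters.

    intrinsic_viscosity : [eta], litres per gram (default 2.94e-3, the
        neutron-spin-echo value for Hb); k_over_v : dimensionless
        self-crowding ratio (default 0.52); D0 : dilute-limit diffusion
        coefficient in cm^2/s at temperature ``T_K``.
    """

    intrinsic_viscosity: float = 2.94e-3
    k_over_v: float = 0.52
    D0: float = 46.8e-8
    T_K: float = 288.0

    def __post_init__(self):
        if min(self.intrinsic_viscosity, self.k_over_v, self.D0, self.T_K) <= 0:
            raise ValueError("all crowding parameters must be positive")

    @property
    def c_max(self):
        """Concentration pole of the viscosity law, mg/ml."""
        return 1.0 / (self.k_over_v * self.intrinsic_viscosity)


def relative_viscosity(c, p: CrowdingParams = CrowdingParams()):
    """eta(c)/eta0 for concentration c in mg/ml (= g/l)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(c >= p.c_max):
        raise ValueError(
            f"concentration at or beyond the viscosity pole "
            f"c_max = v/(k*[eta]) = {p.c_max:.1f} mg/ml")
    x = p.intrinsic_viscosity * c
    return np.exp(x / (1.0 - p.k_over_v * x))


def diffusion_at_concentration(c, p: CrowdingParams = CrowdingParams()):
    """D(c) = D0 / (eta(c)/eta0), cm^2/s."""
    return p.D0 / relative_viscosity(c, p)


def concentration_from_diffusion(D_measured_eff, p: CrowdingParams = CrowdingParams(),
                                 rotation_factor: float = ROTATION_FACTOR):
    """Invert the crowding law: concentration (mg/ml) from a QENS D_eff.

    The measured apparent coefficient is divided by ``rotation_factor``
    (1.27 for spheres; pass 1.0 for a rotation-free measurement), then

        c = ln(D0/D) / ( ln(D0/D) * (k/v) * [eta] + [eta] ).
    """
    D = np.asarray(D_measured_eff, dtype=float) / rotation_factor
    if np.any(D <= 0):
        raise ValueError("measured diffusion coefficient must be > 0")
    if np.any(D > p.D0 * (1 + 1e-12)):
        raise ValueError(
            "rotation-corrected D exceeds D0: would imply negative "
            "concentration")
    L = np.log(p.D0 / np.minimum(D, p.D0))
    eta_i = p.intrinsic_viscosity
    return L / (L * p.k_over_v * eta_i + eta_i)


def hydrodynamic_function(D, D0):
    """H = D/D0, the crowding-induced slow-down of self-diffusion."""
    if D <= 0 or D0 <= 0:
        raise ValueError("D and D0 must be positive")
    return D / D0


def hard_sphere_H(phi):
    """Short-time hard-sphere prediction H = 1 - 1.831*phi."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1.0 / HARD_SPHERE_H_SLOPE):
        raise ValueError(
            f"phi outside [0, {1.0 / HARD_SPHERE_H_SLOPE:.3f}] "
            "(H would be negative)")
    return 1.0 - HARD_SPHERE_H_SLOPE * phi


def volume_change(c_ref, c_new):
    """Fractional cell-volume change implied by a concentration change.

    With a fixed number of molecules per cell, V_new/V_ref = c_ref/c_new;
    returns c_ref/c_new - 1 (positive = expansion relative to reference).
    """
    if c_ref <= 0 or c_new <= 0:
        raise ValueError("concentrations must be positive")
    return c_ref / c_new - 1.0


def expected_lysate_concentration(haematocrit, c_cell):
    """Hb concentration after full lysis of a suspension, mg/ml."""
    if not 0 < haematocrit <= 1:
        raise ValueError("haematocrit must lie in (0, 1]")
    return haematocrit * c_cell


def phi_from_concentration(c, upsilon=UPSILON_HB):
    """Volume fraction from concentration (mg/ml): phi = c * upsilon / 1000."""
    return np.asarray(c, dtype=float) * upsilon / 1000.0
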