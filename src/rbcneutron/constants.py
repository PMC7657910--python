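"""Physical constants and fixed material parameters.

All quantities are module-level and treated as read-only.  Units are chosen
to match the conventions of the analysis: energies in µeV for spectroscopy,
lengths in ångström for scattering vectors, concentrations in mg/ml (= g/l).
"""

from types import MappingProxyType

#: Reduced Planck constant, eV·s
HBAR_EV_S = 6.582119569e-16
#: Reduced Planck constant, µeV·s
HBAR_UEV_S = HBAR_EV_S * 1e6
#: Reduced Planck constant, µeV·ps
HBAR_UEV_PS = HBAR_UEV_S * 1e12

#: Boltzmann constant, J/K
KB = 1.380649e-23
#: Elementary charge, C
E_CHARGE = 1.602176634e-19
#: Vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

#: Partial specific volume of haemoglobin, ml/g
UPSILON_HB = 0.75

#: Ratio of the QENS apparent diffusion coefficient to pure centre-of-mass
#: self-diffusion for uncorrelated rotational + translational diffusion of a
#: spherical particle.
ROTATION_FACTOR = 1.27

#: Default solvent dielectric constant (water at 293 K)
EPSILON_WATER = 80.0

#: Hard-sphere short-time hydrodynamic slope: H(phi) = 1 - 1.831 phi
HARD_SPHERE_H_SLOPE = 1.831

#: cm^2/s per Å^2/s
CM2_PER_A2 = 1e-16

PHYSICAL_CONSTANTS = MappingProxyType(
    {
        "hbar_eV_s": HBAR_EV_S,
        "hbar_ueV_s": HBAR_UEV_S,
        "kB_J_per_K": KB,
        "e_C": E_CHARGE,
        "eps0_F_per_m": EPS0,
        "upsilon_ml_per_g": UPSILON_HB,
        "rotation_factor": ROTATION_FACTOR,
    }
)
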