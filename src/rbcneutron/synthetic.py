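"""Seeded synthetic USANS/SANS/QENS generators with recorded ground truth.

Each generator is a pure function of (truth, seed): identical inputs give
bit-identical datasets.  Random streams are split per dataset component
(signal, buffer, resolution) so adding one component never shifts another.

The grids and noise emulate the instruments the analysis targets: a
Bonse-Hart USANS camera (q ~ 2e-5 - 2e-3 Å^-1, slit smearing optional), a
pinhole/TOF SANS instrument (q ~ 0.01 - 0.45 Å^-1, counting statistics,
interaction peak near 0.1 Å^-1 over a power-law background) and a
backscattering spectrometer (q = 0.34 - 1.92 Å^-1, energy window ±31 µeV
at 0.2 µeV bins or ±20 µeV at 0.3 µeV, Gaussian resolution of 1.0 µeV
FWHM, Poisson counting noise with ~2 % relative error at the elastic
peak, as accumulated in a many-hour run).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass

import numpy as np

from .dataio import QENSSpectrum, SASCurve
from .msa import YukawaInteraction, rmsa_structure_factor
from .qens import ResolutionConvolver, gamma_global, model_total_sqw
from .sans import make_form_factor
from .sas_models import (ButlerParams, GuinierPorodParams, butler_empirical,
                         composite_sans_intensity, guinier_porod, slit_smear)
from .usans import UM_TO_INV_A

__all__ = ["SyntheticTruth", "QENSTruth", "make_usans", "make_sans",
           "make_qens", "make_sans_kinetic_series", "EMU_Q_VALUES"]

#: Backscattering detector-bank q values (Å^-1)
EMU_Q_VALUES = (0.34, 0.54, 0.73, 0.91, 1.10, 1.28, 1.46, 1.63, 1.79, 1.92)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record attached to every generated dataset."""

    generator: str
    params: dict
    grid: dict
    noise: dict
    seed: int

    def to_json(self):
        return json.dumps(_jsonable(asdict(self)), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text):
        d = json.loads(text)
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if is_dataclass(obj):
        return _jsonable(asdict(obj))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _rng(seed, component):
    """Independent named substream: stable across added components."""
    tag = int.from_bytes(hashlib.sha256(component.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


# ---------------------------------------------------------------------------
# USANS
# ---------------------------------------------------------------------------

def make_usans(params, q_grid=None, smear=False, dq_v=5e-5, noise_frac=0.02,
               seed=0):
    """Synthetic USANS curve from Butler or Guinier-Porod truth.

    ``params`` carries lengths in µm; the curve q grid is in Å^-1
    (default 120 log-spaced points over 2e-5 - 2e-3).  Noise is
    multiplicative Gaussian of fraction ``noise_frac``; the sigma column
    records the generating width.  With ``smear`` the model curve is
    slit-smeared with vertical half-width ``dq_v`` before noise.
    """
    if q_grid is None:
        q_grid = np.geomspace(2e-5, 2e-3, 120)
    q_um = q_grid / UM_TO_INV_A
    if isinstance(params, ButlerParams):
        I = butler_empirical(q_um, params)
        name = "usans_butler"
    elif isinstance(params, GuinierPorodParams):
        I = guinier_porod(q_um, params)
        name = "usans_guinier_porod"
    else:
        raise TypeError("params must be ButlerParams or GuinierPorodParams")
    curve = SASCurve(q=q_grid, I=I, sigma=np.zeros_like(I))
    if smear:
        curve = slit_smear(curve, dq_v)
    sigma = noise_frac * np.abs(curve.I)
    noise = _rng(seed, "usans.signal").standard_normal(len(curve))
    I_obs = curve.I * (1.0 + noise_frac * noise)
    out = curve.copy_with(I=I_obs, sigma=sigma)
    truth = SyntheticTruth(
        generator=name, params=_jsonable(asdict(params)),
        grid={"q_min": float(q_grid[0]), "q_max": float(q_grid[-1]),
              "n": len(q_grid), "smear": bool(smear),
              "dq_v": float(dq_v) if smear else None},
        noise={"kind": "multiplicative-gaussian", "frac": noise_frac},
        seed=seed)
    return out, truth


# ---------------------------------------------------------------------------
# SANS
# ---------------------------------------------------------------------------

def make_sans(yukawa: YukawaInteraction, I1=2e-4, d=2.2, I2=None,
              form_factor="sphere:23.6", q_grid=None, peak_rel_err=0.02,
              seed=0, component="sans.signal"):
    """Synthetic SANS curve: Eq-style composite model + counting noise.

    Counting-statistics noise sigma_i = f*sqrt(I_peak*I_i) scaled so the
    relative error at the interaction peak equals ``peak_rel_err``.
    ``I2`` defaults to a value giving a peak intensity of order 0.1
    (arbitrary absolute units).
    """
    if q_grid is None:
        q_grid = np.linspace(0.01, 0.45, 150)
    F = make_form_factor(form_factor)(q_grid)
    S = rmsa_structure_factor(q_grid, yukawa)
    if I2 is None:
        I2 = 0.1
    I = composite_sans_intensity(q_grid, I1, d, I2, F, S)
    i_pk = int(np.argmax(I2 * F * S))
    sigma = peak_rel_err * np.sqrt(np.maximum(I, 0.0) * I[i_pk])
    noise = _rng(seed, component).standard_normal(len(q_grid))
    I_obs = I + sigma * noise
    curve = SASCurve(q=q_grid, I=I_obs, sigma=sigma)
    truth = SyntheticTruth(
        generator="sans_composite",
        params={"I1": I1, "d": d, "I2": I2,
                "yukawa": _jsonable(asdict(yukawa)),
                "form_factor": form_factor if isinstance(form_factor, str)
                else "tabulated"},
        grid={"q_min": float(q_grid[0]), "q_max": float(q_grid[-1]),
              "n": len(q_grid)},
        noise={"kind": "counting", "peak_rel_err": peak_rel_err},
        seed=seed)
    return curve, truth


def make_sans_kinetic_series(yukawa: YukawaInteraction, times, step_at=None,
                             phi_step=-0.05, seed=0, **kwargs):
    """Kinetic series of SANS curves at the given times (hours).

    Constant truth by default; with ``step_at`` the volume fraction jumps
    by ``phi_step`` for t >= step_at (emulating the onset of cell lysis,
    which dilutes part of the protein into a second compartment).
    """
    curves, truths = [], []
    for i, t in enumerate(times):
        y = yukawa
        if step_at is not None and t >= step_at:
            y = YukawaInteraction.from_physical(
                yukawa.contact_potential, yukawa.sigma_hc / 2,
                max(yukawa.phi + phi_step, 1e-3), yukawa.kappa_inv,
                T=yukawa.T, epsilon=yukawa.epsilon)
        c, tr = make_sans(y, seed=seed, component=f"sans.kinetic.{i}",
                          **kwargs)
        curves.append(c)
        truths.append(tr)
    return curves, truths


# ---------------------------------------------------------------------------
# QENS
# ---------------------------------------------------------------------------

def _gaussian_resolution(omega, fwhm=1.0):
    sg = fwhm / 2.3548200450309493
    r = np.exp(-(omega**2) / (2 * sg**2))
    return r / np.trapezoid(r, omega)


@dataclass(frozen=True)
class QENSTruth:
    """Generating parameters for a QENS spectrum set."""

    D_eff: float                    # cm^2/s (rotation-inflated apparent)
    x2: float = 1.3                 # Å^2, Gaussian-confinement MSD
    p: float = 0.50                 # immobile fraction
    Gamma_I: float = 2.84           # µeV, internal HWHM (q-independent)
    bkg_a: float = 0.02             # flat background, fraction of peak
    bkg_b: float = 0.0              # linear background slope, /µeV
    T: float = 288.0


def make_qens(truth: QENSTruth, q_values=EMU_Q_VALUES, window=31.0,
              step=0.2, resolution_fwhm=1.0, peak_counts=2500.0, seed=0,
              noise=True, buffer_fraction=0.0, oversample=3):
    """Synthetic per-q QENS spectra with companion resolution spectrum.

    Per q: A0(q) = (1-p) exp(-x2 q^2) + p, Gamma_G = hbar D_eff q^2; the
    two-Lorentzian model is convolved with a Gaussian resolution of the
    given FWHM (via the same numerical operator the fits use) and scaled
    so the elastic-peak expectation is ``peak_counts`` (Poisson noise;
    2500 counts gives the ~2 % peak relative error of a long run).
    With ``buffer_fraction`` > 0, a broad solvent component of that
    relative amplitude is added and also returned separately.

    Returns (spectra, truth_record) or (spectra, buffer_spectra, truth_record).
    """
    omega = np.arange(-window, window + step / 2, step)
    res = _gaussian_resolution(omega, resolution_fwhm)
    conv = ResolutionConvolver(omega, res, oversample=oversample)
    spectra, buffers = [], []
    for iq, q in enumerate(q_values):
        A0 = (1 - truth.p) * np.exp(-truth.x2 * q**2) + truth.p
        gG = float(gamma_global(q, truth.D_eff))
        shape = conv.apply(model_total_sqw, A0, gG, truth.Gamma_I, 1.0)
        scale = peak_counts / shape.max()
        model = scale * shape + truth.bkg_a * peak_counts \
            + truth.bkg_b * peak_counts * omega
        rng = _rng(seed, f"qens.signal.{iq}")
        counts = rng.poisson(np.maximum(model, 0.0)).astype(float) if noise \
            else model
        # sigma column records the generating width (expected counts), not
        # the observed counts: weighting by observed counts biases
        # least-squares fits of counting data
        sigma = np.sqrt(np.maximum(model, 1.0)) if noise \
            else np.full_like(model, 1.0)
        spectra.append(QENSSpectrum(q=q, omega=omega, S=counts, sigma=sigma,
                                    resolution=res,
                                    meta={"T": truth.T, "scale": scale}))
        if buffer_fraction > 0:
            # solvent: broad Lorentzian (fast D2O dynamics), flat-ish
            buf_model = buffer_fraction * peak_counts * conv.apply(
                model_total_sqw, 0.0, 12.0, 0.0, 1.0) * 12 * np.pi / 2
            rng_b = _rng(seed, f"qens.buffer.{iq}")
            bcounts = rng_b.poisson(np.maximum(buf_model, 0.0)).astype(float) \
                if noise else buf_model
            bsigma = np.sqrt(np.maximum(bcounts, 1.0)) if noise \
                else np.full_like(buf_model, 1.0)
            buffers.append(QENSSpectrum(q=q, omega=omega, S=bcounts,
                                        sigma=bsigma, resolution=res))
    record = SyntheticTruth(
        generator="qens_two_lorentzian",
        params=_jsonable(asdict(truth)),
        grid={"q_values": list(q_values), "window_ueV": window,
              "step_ueV": step, "resolution_fwhm_ueV": resolution_fwhm},
        noise={"kind": "poisson", "peak_counts": peak_counts,
               "enabled": bool(noise), "buffer_fraction": buffer_fraction},
        seed=seed)
    if buffer_fraction > 0:
        return spectra, buffers, record
    return spectra, record
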