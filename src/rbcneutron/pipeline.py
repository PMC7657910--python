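"""Umbrella analysis chain: USANS -> SANS -> QENS -> crowding.

Runs the full morphology/interaction/dynamics analysis on a bundle of
inputs (synthetic by default, files when configured) and emits a single
JSON-ready report in which the intracellular haemoglobin concentration is
estimated twice and compared: from the SANS structure-factor volume
fraction (c = phi/upsilon) and from the QENS diffusion coefficient via
the crowding inversion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from . import constants
from .crowding import CrowdingParams, concentration_from_diffusion, \
    hydrodynamic_function, phi_from_concentration
from .dataio import read_sas
from .qens import correlation_time, fit_eisf, fit_global_diffusion, \
    fit_spectrum, screen_per_q_fits
from .sans import SANSConfig, fit_sans
from .sas_models import ButlerParams, GuinierPorodParams
from .synthetic import QENSTruth, make_qens, make_sans, make_usans
from .msa import YukawaInteraction
from .usans import fit_usans

__all__ = ["AnalysisConfig", "run_full_chain"]


@dataclass
class AnalysisConfig:
    """Configuration of the full analysis chain.

    Defaults reproduce physiological conditions: 0.15 M ionic strength,
    upsilon = 0.75 ml/g, the measured Hb crowding parameters, and the
    dilute-limit diffusion coefficient at the horse-sample temperature.
    File paths, when set, replace the synthetic stage inputs.
    """

    seed: int = 0
    temperature_K: float = 288.0
    ionic_strength_M: float = 0.15
    epsilon: float = 80.0
    upsilon_ml_per_g: float = constants.UPSILON_HB
    kappa_inv_A: float = 7.8
    crowding: CrowdingParams = field(default_factory=CrowdingParams)
    rotation_factor: float = constants.ROTATION_FACTOR
    # synthetic truths (used when no files are given)
    usans_butler: ButlerParams = field(
        default_factory=lambda: ButlerParams(I0=1.0, alpha=0.1, xi=4.61, d=3.6))
    usans_gp: GuinierPorodParams = field(
        default_factory=lambda: GuinierPorodParams(scale=1.0, Rg=1.15, d=3.9))
    sans_yukawa: YukawaInteraction = field(
        default_factory=lambda: YukawaInteraction.from_physical(
            2.5, 23.6, 0.256, 7.8))
    sans_powerlaw: tuple = (2e-4, 2.2)
    sans_I2: float = 0.1
    form_factor: str = "sphere:23.6"
    qens_truth: QENSTruth = field(
        default_factory=lambda: QENSTruth(D_eff=10.0e-8))
    qens_window_ueV: float = 31.0
    qens_step_ueV: float = 0.2
    # optional file inputs
    usans_file: str | None = None
    sans_file: str | None = None
    include_usans: bool = True
    include_sans: bool = True
    include_qens: bool = True

    @classmethod
    def from_file(cls, path):
        """Read a flat ``key = value`` plain-text configuration."""
        kv = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {raw!r}")
                k, v = (s.strip() for s in line.split("=", 1))
                kv[k] = v
        cfg = cls()
        simple = {f: type(getattr(cfg, f)) for f in (
            "seed", "temperature_K", "ionic_strength_M", "epsilon",
            "upsilon_ml_per_g", "kappa_inv_A", "rotation_factor",
            "qens_window_ueV", "qens_step_ueV", "form_factor",
            "usans_file", "sans_file", "include_usans", "include_sans",
            "include_qens")}
        for k, v in kv.items():
            if k in ("usans_file", "sans_file", "form_factor"):
                setattr(cfg, k, v)
            elif k in ("include_usans", "include_sans", "include_qens"):
                setattr(cfg, k, v.lower() in ("1", "true", "yes"))
            elif k == "seed":
                cfg.seed = int(v)
            elif k in simple:
                setattr(cfg, k, float(v))
            elif k == "qens_D_eff":
                cfg.qens_truth = QENSTruth(D_eff=float(v))
            elif k == "crowding_D0":
                cfg.crowding = CrowdingParams(
                    intrinsic_viscosity=cfg.crowding.intrinsic_viscosity,
                    k_over_v=cfg.crowding.k_over_v, D0=float(v),
                    T_K=cfg.crowding.T_K)
            else:
                raise ValueError(f"unknown config key {k!r}")
        return cfg


def _stage_usans(cfg: AnalysisConfig):
    if cfg.usans_file:
        curve = read_sas(cfg.usans_file)
        fits = {"butler": fit_usans(curve, "butler")}
    else:
        curve_b, _ = make_usans(cfg.usans_butler, noise_frac=0.02,
                                seed=cfg.seed)
        curve_g, _ = make_usans(cfg.usans_gp, noise_frac=0.02,
                                seed=cfg.seed + 1)
        fits = {"butler": fit_usans(curve_b, "butler"),
                "guinier_porod": fit_usans(curve_g, "guinier_porod")}
    out = {}
    for name, r in fits.items():
        rec = {"model": r.model, "chi2_red": r.chi2_red,
               "params": {k: float(v) for k, v in asdict(r.params).items()
                          if isinstance(v, (int, float))}}
        if r.model == "butler":
            rec["xi_um"] = float(r.xi)
            rec["q_star_per_um"] = float(r.q_star)
        else:
            rec["Rg_um"] = float(r.params.Rg)
            rec["R_eff_sphere_um"] = float(r.R_eff_sphere)
            rec["V_cell_fl"] = float(r.V_cell)
        out[name] = rec
    return out


def _stage_sans(cfg: AnalysisConfig):
    scfg = SANSConfig(ionic_strength=cfg.ionic_strength_M,
                      T=cfg.sans_yukawa.T, epsilon=cfg.epsilon,
                      fix_reff=cfg.sans_yukawa.sigma_hc / 2,
                      kappa_inv_A=cfg.kappa_inv_A)
    if cfg.sans_file:
        curve = read_sas(cfg.sans_file)
    else:
        I1, d = cfg.sans_powerlaw
        curve, _ = make_sans(cfg.sans_yukawa, I1=I1, d=d, I2=cfg.sans_I2,
                             form_factor=cfg.form_factor, seed=cfg.seed)
    fit = fit_sans(curve, cfg.form_factor, scfg)
    return {
        "I1": float(fit.I1), "d": float(fit.d), "I2": float(fit.I2),
        "contact_potential_kBT": float(fit.yukawa.contact_potential),
        "R_eff_A": float(fit.yukawa.sigma_hc / 2),
        "phi": float(fit.yukawa.phi),
        "Z_e": float(fit.Z),
        "c_mg_ml": float(fit.c),
        "chi2_red": float(fit.chi2_red),
        "flags": fit.flags,
    }


def _stage_qens(cfg: AnalysisConfig):
    spectra, _ = make_qens(cfg.qens_truth, window=cfg.qens_window_ueV,
                           step=cfg.qens_step_ueV, seed=cfg.seed)
    fits = [fit_spectrum(s) for s in spectra]
    ok = screen_per_q_fits(fits)
    diff = fit_global_diffusion([f.Gamma_G for f in ok],
                                [f.errors["Gamma_G"] for f in ok],
                                [f.q for f in ok], T=cfg.temperature_K,
                                rotation_factor=cfg.rotation_factor)
    internal = correlation_time([f.Gamma_I for f in ok],
                                [f.errors["Gamma_I"] for f in ok],
                                [f.q for f in ok])
    eisf = fit_eisf([f.A0 for f in ok], [f.errors["A0"] for f in ok],
                    [f.q for f in ok])
    return {
        "D_eff_cm2_s": float(diff.D_eff),
        "D_eff_err_cm2_s": float(diff.D_eff_err),
        "D_trans_cm2_s": float(diff.D_trans),
        "Gamma_mean_ueV": float(internal.Gamma_mean),
        "tau_ps": float(internal.tau),
        "x2_A2": float(eisf.x2),
        "p_immobile": float(eisf.p_immobile),
        "n_q_used": len(ok),
    }, diff


def run_full_chain(config: AnalysisConfig):
    """Execute every configured stage; partial failures flag, not abort.

    Returns a report dict; ``report['status']`` maps stage -> ok/failed/
    skipped, and the summary compares c_SANS with c_QENS.
    """
    report = {
        "units": {"q": "1/A", "length": "A", "energy": "ueV",
                  "D": "cm^2/s", "c": "mg/ml", "V_cell": "fl",
                  "xi": "um", "tau": "ps"},
        "constants": {
            "hbar_ueV_s": constants.HBAR_UEV_S,
            "rotation_factor": config.rotation_factor,
            "upsilon_ml_per_g": config.upsilon_ml_per_g,
            "intrinsic_viscosity_l_per_g": config.crowding.intrinsic_viscosity,
            "k_over_v": config.crowding.k_over_v,
            "D0_cm2_s": config.crowding.D0,
            "kappa_inv_A": config.kappa_inv_A,
        },
        "seed": config.seed,
        "status": {},
    }
    c_sans = c_qens = None
    stages = (("usans", config.include_usans, _stage_usans),
              ("sans", config.include_sans, _stage_sans))
    for name, enabled, fn in stages:
        if not enabled:
            report["status"][name] = "skipped"
            continue
        try:
            report[name] = fn(config)
            report["status"][name] = "ok"
        except Exception as exc:   # stage failure -> partial report
            report["status"][name] = f"failed: {exc}"
    if report["status"].get("sans") == "ok":
        c_sans = report["sans"]["c_mg_ml"]

    if config.include_qens:
        try:
            qens_rec, diff = _stage_qens(config)
            report["qens"] = qens_rec
            c_qens = float(concentration_from_diffusion(
                diff.D_eff, config.crowding,
                rotation_factor=config.rotation_factor))
            report["qens"]["c_mg_ml"] = c_qens
            report["qens"]["H_short_time"] = float(hydrodynamic_function(
                diff.D_trans, config.crowding.D0))
            report["status"]["qens"] = "ok"
        except Exception as exc:
            report["status"]["qens"] = f"failed: {exc}"
    else:
        report["status"]["qens"] = "skipped"

    summary = {}
    if c_sans is not None:
        summary["c_SANS_mg_ml"] = c_sans
        summary["phi_SANS"] = float(phi_from_concentration(c_sans))
    if c_qens is not None:
        summary["c_QENS_mg_ml"] = c_qens
        summary["phi_QENS"] = float(phi_from_concentration(c_qens))
    if c_sans is not None and c_qens is not None:
        summary["relative_discrepancy"] = abs(c_sans - c_qens) / (
            0.5 * (c_sans + c_qens))
    report["summary"] = summary
    ok = [v for v in report["status"].values() if v != "skipped"]
    report["exit_status"] = 0 if all(v == "ok" for v in ok) else 3
    return report


def report_to_json(report, path=None):
    text = json.dumps(report, indent=2, sort_keys=True, default=float)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
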