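#!/usr/bin/env python
"""Fit QENS spectra: global Hb diffusion, internal dynamics, EISF.

Per sample, every spectrum is fitted with the resolution-convolved
two-Lorentzian model; usable per-q fits feed three reductions: the
origin-anchored Gamma_G = hbar*D_eff*q^2 line (apparent diffusion
coefficient), the q-averaged internal width and correlation time
tau = hbar/<Gamma>, and the Gaussian-confinement EISF fit giving the
mean-square displacement <x^2> and immobile fraction p.  Writes
results/qens_dynamics.json.
"""

import json
from pathlib import Path

import numpy as np

from rbcneutron.dataio import read_qens
from rbcneutron.qens import (correlation_time, fit_eisf, fit_global_diffusion,
                             fit_spectrum, screen_per_q_fits)
from rbcneutron.synthetic import SyntheticTruth

BASE = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_data"


def main():
    out = {}
    for d in sorted(DATA.glob("qens_*")):
        if not d.is_dir():
            continue
        name = d.name.replace("qens_", "")
        truth = SyntheticTruth.from_json((d / "truth.json").read_text())
        res_tab = np.loadtxt(d / "resolution.dat")
        spectra = []
        for f in sorted(d.glob("q*.dat")):
            s = read_qens(f)
            s.resolution = np.interp(s.omega, res_tab[:, 0], res_tab[:, 1])
            spectra.append(s)
        ok = screen_per_q_fits([fit_spectrum(s) for s in spectra])
        T = truth.params["T"]
        diff = fit_global_diffusion([f.Gamma_G for f in ok],
                                    [f.errors["Gamma_G"] for f in ok],
                                    [f.q for f in ok], T=T)
        internal = correlation_time([f.Gamma_I for f in ok],
                                    [f.errors["Gamma_I"] for f in ok],
                                    [f.q for f in ok])
        eisf = fit_eisf([f.A0 for f in ok], [f.errors["A0"] for f in ok],
                        [f.q for f in ok])
        out[name] = {
            "T_K": T,
            "D_eff_1e-8_cm2_s": diff.D_eff * 1e8,
            "D_eff_err_1e-8_cm2_s": diff.D_eff_err * 1e8,
            "D_truth_1e-8_cm2_s": truth.params["D_eff"] * 1e8,
            "Gamma_mean_ueV": internal.Gamma_mean,
            "Gamma_spread_ueV": internal.Gamma_mean_err,
            "tau_ps": internal.tau,
            "x2_A2": eisf.x2, "p_immobile": eisf.p_immobile,
            "eisf_degenerate": eisf.degenerate,
            "n_q_used": len(ok),
            "Gamma_I_flat_in_q2_p": internal.q2_slope_p,
        }
        print(f"{name}: D_eff = {diff.D_eff*1e8:.1f} ± "
              f"{diff.D_eff_err*1e8:.1f} e-8 cm²/s "
              f"(truth {truth.params['D_eff']*1e8:.1f}), "
              f"tau = {internal.tau:.0f} ps, <x²> = {eisf.x2:.2f} Å², "
              f"p = {eisf.p_immobile:.2f}")
    (BASE / "qens_dynamics.json").write_text(json.dumps(out, indent=2,
                                                        default=float))
    print(f"wrote {BASE / 'qens_dynamics.json'}")


if __name__ == "__main__":
    main()
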