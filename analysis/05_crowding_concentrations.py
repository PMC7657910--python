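#!/usr/bin/env python
"""Invert fitted diffusion coefficients to intracellular concentrations.

Takes the apparent diffusion coefficients from 04 (falling back to the
measured reference values if 04 has not been run), corrects each for
rotational diffusion (factor 1.27), inverts the crowded-solution law to
c in mg/ml, and derives the hydrodynamic slow-down H = D/D0, implied
cell-volume changes between conditions, and the lysate concentration
expected from the haematocrit.  Writes results/crowding_concentrations.json.
"""

import json
from pathlib import Path

from rbcneutron.crowding import (CrowdingParams, concentration_from_diffusion,
                                 expected_lysate_concentration, hard_sphere_H,
                                 hydrodynamic_function, phi_from_concentration,
                                 volume_change)

BASE = Path(__file__).resolve().parents[1] / "results"

# reference apparent diffusion coefficients (1e-8 cm^2/s) and conditions
REFERENCE = {
    "horse_physiological": (10.0, 288.0),
    "horse_valinomycin": (5.5, 288.0),
    "human_physiological": (8.0, 298.0),
    "human_monensin": (16.6, 298.0),
    "human_lysate": (19.0, 298.0),
}
D0 = {288.0: 46.8e-8, 298.0: 63.4e-8}


def main():
    fitted = {}
    qens_path = BASE / "qens_dynamics.json"
    if qens_path.exists():
        qens = json.loads(qens_path.read_text())
        fitted = {k: (v["D_eff_1e-8_cm2_s"], v["T_K"]) for k, v in qens.items()}
    out = {"samples": {}}
    cs = {}
    for name, (d_ref, T) in REFERENCE.items():
        d_eff, T = fitted.get(name, (d_ref, T))
        p = CrowdingParams(D0=D0[T], T_K=T)
        c = float(concentration_from_diffusion(d_eff * 1e-8, p))
        cs[name] = c
        out["samples"][name] = {
            "D_eff_1e-8_cm2_s": d_eff, "T_K": T,
            "c_mg_ml": c, "phi": float(phi_from_concentration(c)),
            "H_short_time": hydrodynamic_function(d_eff * 1e-8 / 1.27, D0[T]),
        }
        print(f"{name}: D_eff = {d_eff:.1f} e-8 cm²/s -> c = {c:.0f} mg/ml")

    lys_phi = float(phi_from_concentration(cs["human_lysate"]))
    out["comparisons"] = {
        "volume_change_horse_valinomycin":
            volume_change(cs["horse_physiological"], cs["horse_valinomycin"]),
        "volume_change_human_monensin":
            volume_change(cs["human_physiological"], cs["human_monensin"]),
        "H_lysate_measured": out["samples"]["human_lysate"]["H_short_time"],
        "H_lysate_hard_sphere_prediction": float(hard_sphere_H(
            round(lys_phi, 2))),
        "expected_lysate_c_range_mg_ml": [
            expected_lysate_concentration(0.6, cs["human_physiological"]),
            expected_lysate_concentration(0.7, cs["human_physiological"])],
    }
    vc = out["comparisons"]
    print(f"valinomycin shrinks horse RBCs by "
          f"{-100*vc['volume_change_horse_valinomycin']:.0f}% in volume; "
          f"monensin expands human RBCs by "
          f"{100*vc['volume_change_human_monensin']:.0f}%")
    print(f"lysate: measured H = {vc['H_lysate_measured']:.2f} vs "
          f"hard-sphere prediction {vc['H_lysate_hard_sphere_prediction']:.2f}"
          " - hydrodynamic interactions are stronger than the ideal "
          "hard-sphere picture")
    (BASE / "crowding_concentrations.json").write_text(
        json.dumps(out, indent=2, default=float))
    print(f"wrote {BASE / 'crowding_concentrations.json'}")


if __name__ == "__main__":
    main()
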