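#!/usr/bin/env python
"""Generate the synthetic datasets every later stage analyses.

Writes, under results/data/: two USANS curves (a rouleaux-type curve with
a correlation peak and a shrunken-sphere Guinier-Porod curve), one SANS
curve per fitted sample condition (horse/human, physiological and
ionophore-treated, using the fitted charged-hard-sphere parameters as
ground truth), and one QENS spectrum set per measured sample.  Each
dataset carries a truth.json record so recovery can be audited.
"""

import json
from pathlib import Path

import numpy as np

from rbcneutron.dataio import write_qens, write_sas
from rbcneutron.msa import YukawaInteraction
from rbcneutron.sas_models import ButlerParams, GuinierPorodParams
from rbcneutron.synthetic import QENSTruth, make_qens, make_sans, make_usans

OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_data"
SEED = 20201014

# morphology truths (lengths in µm)
USANS_TRUTHS = {
    "human_physiological": ButlerParams(I0=1.0, alpha=0.1, xi=4.61, d=3.6),
    "human_monensin": ButlerParams(I0=1.0, alpha=0.1, xi=5.28, d=3.8),
    "human_valinomycin": GuinierPorodParams(scale=1.0, Rg=1.15, d=3.9),
}

# charged-hard-sphere truths (contact potential kBT, R_eff Å, phi)
SANS_TRUTHS = {
    "horse_physiological": (2.5, 23.6, 0.256),
    "horse_valinomycin": (1.9, 24.1, 0.319),
    "horse_monensin": (0.1, 25.6, 0.229),
    "human_physiological": (3.3, 22.6, 0.249),
    "human_valinomycin": (3.1, 22.6, 0.279),
    "human_monensin": (1.3, 22.6, 0.224),
}

# apparent diffusion truths (cm^2/s, <Gamma_I> µeV, T K, window µeV, step)
QENS_TRUTHS = {
    "horse_physiological": (10.0e-8, 2.84, 288.0, 31.0, 0.2),
    "horse_valinomycin": (5.5e-8, 2.34, 288.0, 31.0, 0.2),
    "human_physiological": (8.0e-8, 2.40, 298.0, 20.0, 0.3),
    "human_monensin": (16.6e-8, 3.68, 298.0, 20.0, 0.3),
    "human_lysate": (19.0e-8, 2.48, 298.0, 20.0, 0.3),
}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name, params in USANS_TRUTHS.items():
        curve, rec = make_usans(params, noise_frac=0.02, seed=SEED)
        write_sas(curve, OUT / f"usans_{name}.dat")
        (OUT / f"usans_{name}.truth.json").write_text(rec.to_json())
    for name, (gamma_c, r_eff, phi) in SANS_TRUTHS.items():
        y = YukawaInteraction.from_physical(gamma_c, r_eff, phi, 7.8, T=293.0)
        curve, rec = make_sans(y, form_factor=f"sphere:{r_eff}", seed=SEED)
        write_sas(curve, OUT / f"sans_{name}.dat")
        (OUT / f"sans_{name}.truth.json").write_text(rec.to_json())
    for name, (d_eff, gamma_i, T, window, step) in QENS_TRUTHS.items():
        truth = QENSTruth(D_eff=d_eff, Gamma_I=gamma_i, T=T)
        spectra, rec = make_qens(truth, window=window, step=step, seed=SEED)
        d = OUT / f"qens_{name}"
        d.mkdir(exist_ok=True)
        for i, s in enumerate(spectra):
            write_qens(s, d / f"q{i:02d}.dat")
        np.savetxt(d / "resolution.dat",
                   np.column_stack([spectra[0].omega, spectra[0].resolution]))
        (d / "truth.json").write_text(rec.to_json())
        manifest = {"samples": [f"q{i:02d}.dat" for i in range(len(spectra))],
                    "resolution": "resolution.dat", "temperature": T}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote synthetic datasets to {OUT}")


if __name__ == "__main__":
    main()
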