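# rbcneutron

Neutron-scattering analysis of red-blood-cell (RBC) shape and of
haemoglobin (Hb) interactions and diffusion inside the cell, built as a
reusable Python library plus a set of numbered analysis scripts.

Red blood cells hold Hb at ~330 mg/ml — a volume fraction of about 0.25 —
so Hb molecules constantly obstruct each other ("macromolecular
crowding"). Three neutron techniques see three aspects of this system,
and this package implements the full analysis chain for all of them:

- **USANS** (ultra-small-angle neutron scattering, q ≈ 1e-5–1e-3 Å⁻¹):
  whole-cell morphology. Suspensions of biconcave discocytes stack into
  rouleaux, producing a correlation peak at q\* = 2π/ξ that is fitted with
  an empirical one-peak model; shrunken spherical cells show a
  micrometre-scale Guinier regime fitted with the generalized
  Guinier–Porod model, giving R = √(5/3)·R_g and V = 4πR³/3.
  Slit-smearing of Bonse–Hart data and iterative (Lake) desmearing are
  provided.
- **SANS** (q ≈ 0.01–0.45 Å⁻¹): Hb–Hb interactions. The intensity is
  decomposed as I(q) = I₁q^(−d) + I₂·F(q)·S(q); the structure factor
  S(q) is the **rescaled mean spherical approximation (RMSA)** for
  charged hard spheres with a screened-Coulomb (Yukawa) potential
  βU(x) = γe^(−kx)/x. The MSA is solved through the Baxter–Wertheim
  factorization (an independent numerical Ornstein–Zernike solver serves
  as a test oracle), with the standard core-inflation rescaling when the
  contact pair correlation goes negative. The fitted volume fraction
  converts to concentration via c = φ/υ (υ = 0.75 ml/g), and the contact
  potential to an effective charge Z = (2+k)·√(πεε₀σ·γe^(−k)·k_BT)/e.
- **QENS** (backscattering, q = 0.34–1.92 Å⁻¹, 1.0 µeV resolution): Hb
  dynamics. Spectra are fitted with a resolution-convolved
  two-Lorentzian model S(q,ω) = A₀L(Γ_G) + (1−A₀)L(Γ_G+Γ_I) + linear
  background. Γ_G(q) = ħD_eff·q² gives the apparent diffusion
  coefficient; ⟨Γ_I⟩ gives the internal correlation time τ = ħ/⟨Γ⟩; the
  EISF A₀(q) = (1−p)e^(−⟨x²⟩q²) + p gives the confinement geometry.
- **Crowding inversion**: D_eff/1.27 (rotational correction for
  spheres) is inverted through 1/D(c) = (1/D₀)·exp([η]c/(1−(k/v)[η]c))
  to the intracellular concentration, closing the loop: SANS and QENS
  estimate the same c by independent physics.

A seeded synthetic-data module emulates all three instruments (grids,
counting statistics, slit geometry, resolution function) with recorded
ground truth, so the entire chain is testable offline.

## Worked example

Invert a measured apparent diffusion coefficient (horse RBCs,
physiological state, 288 K) to the intracellular Hb concentration:

```
$ rbcneutron crowding invert --deff 10.0e-8 --d0 46.8e-8
{
  "c_mg_ml": 314.6296440107925,
  "H": 0.16824819974426272,
  "phi": 0.2359722330080944
}
```

D_eff = 10.0e-8 cm²/s is first divided by 1.27 (rotation), then the
crowding law gives c ≈ 315 mg/ml — a volume fraction of 0.24, and a
short-time hydrodynamic function H = D/D₀ = 0.17, i.e. Hb in the cell
diffuses six times slower than at infinite dilution.

Run the whole chain on a synthetic bundle:

```
$ rbcneutron run-all --seed 2 --out report.json
usans: ok
sans: ok
qens: ok
c_SANS vs c_QENS relative discrepancy: 6.71%
```

The report contains the fitted morphology (ξ = 4.6 µm correlation
length; V ≈ 14 fl shrunken-cell volume), the interaction parameters
(contact potential, Z, φ) and the QENS reductions (D_eff, τ, ⟨x²⟩, p),
with the two concentration estimates side by side.

The numbered scripts under `analysis/` run the same stages as a
narrative study (simulate → morphology → interactions → dynamics →
concentrations → integrated chain) and write their tables under
`results/`.

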