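# Methods

This note documents the models, numerical choices and limitations of the
package. Symbols follow the README.

## Charged-hard-sphere structure factor (RMSA)

Hb–Hb interactions are modelled as hard spheres of diameter σ = 2R_eff
with a repulsive screened-Coulomb tail, βU(x) = γe^(−kx)/x for
x = r/σ > 1, where k = κσ and κ⁻¹ is the Debye length (0.304/√I nm;
7.8 Å at 0.15 M, the physiological saline used throughout). The mean
spherical approximation (MSA) closure — g(r) = 0 inside the core,
c(r) = −βU(r) outside — is solved with the Baxter–Wertheim
factorization: 1 − ρĉ(q) = Q̂(q)Q̂(−q), with the one-Yukawa ansatz

    Q(r) = q0(r) + D e^(−z r),     q0'(x) = a x + b + c̃ e^(−z x) on (0, 1),

and q0(1) = 0. Substituting the ansatz into Baxter's two real-space
equations and matching the basis functions {1, x, e^(−zx)} (the
x·e^(−zx) terms cancel identically) yields five algebraic relations in
(a, b, c̃, D, H_z), where H_z is the Laplace transform of r·h(r) over
the tail region. The system is bilinear and is solved with a
quasi-Newton root finder (tolerance 1e-13), warm-started from the
Percus–Yevick (PY) coefficients and, for strong coupling, by
continuation in the contact potential. At γ = 0 the solution reduces
exactly to PY hard spheres, which is also the analytic oracle used in
tests (agreement ≤ 1e-9). Integrals of q0 over the core are evaluated
with 96-point Gauss–Legendre quadrature, exact to machine precision for
the basis involved; S(q) = 1/|Q̂(qσ)|² is therefore non-negative by
construction and approaches 1 at large q.

**Rescaling.** When the MSA contact value g(σ⁺) < 0 (strong coupling at
low volume fraction), the standard rescaling is applied: at fixed number
density the core is inflated, σ* = tσ with t ≥ 1, which maps
(γ_c, z, η) → (γ_c e^(−z(t−1))/t, zt, ηt³); the smallest t with
g(σ*⁺) = 0 is found by scan + bracketed root search (tolerance 1e-10 in
t) and the structure factor of the rescaled system is returned. The
search is capped at η* = 0.72; exceeding the cap raises a convergence
error with diagnostics.

**Verification oracle.** `oz_msa_oracle` solves the same closure by
Picard iteration of the Ornstein–Zernike equation on a radial grid
(2^15 points, dr = σ/800, r_max ≈ 41σ, mixing 0.5, tolerance 1e-10)
using sine transforms. The two independent routes agree to ≤ 2e-3 at
weak coupling and ≤ 2.5e-3 at the physiological parameter set; the
residual difference is dominated by the oracle's O(dr) treatment of the
core discontinuity.

With the physiological parameters (2.5 k_BT, R_eff = 23.6 Å, φ = 0.256,
κ⁻¹ = 7.8 Å) the S(q) maximum sits at 0.124 Å⁻¹, between the packing
scale 2π/d ≈ 0.105 Å⁻¹ of the corresponding number density and the
hard-sphere limit — the repulsion at this screening is too weak to pull
the peak fully to the coordination-shell position.

## SANS decomposition and joint fit

I(q) = I₁q^(−d) + I₂F(q)S(q). The form factor is supplied as a
normalized table (cubic interpolation) or the analytic uniform sphere;
synthetic work uses a 23.6 Å sphere, matching the effective Hb radius —
at SANS resolution the compact tetramer is well approximated by a
sphere below the first form-factor minimum. The joint fit is a bounded
trust-region least-squares over {I₁, d, I₂, γ_c, R_eff, φ} with 1/σ²
weights, five jittered starts (the I₁/I₂ amplitude trade-off is
shallow), followed by an unbounded Levenberg–Marquardt polish: the
trade-off valley is so flat that bounded TRF steps stall ~1% from the
optimum on noiseless data, while the polish reaches machine precision.
κ⁻¹ is fixed by the ionic strength (or set explicitly), never fitted.

With R_eff free, the (φ, R_eff, γ_c) set is weakly identifiable at
counting-statistics noise: draws exist where the likelihood prefers a
~20 % smaller φ with a smaller core and larger charge. Recovery studies
and the default pipeline therefore pin R_eff at the known form-factor
radius, the same treatment applied to datasets that cannot constrain it
independently; the free-R_eff path remains available and is exact on
noiseless data.

Uncertainty on the experimental structure factor
S_exp = (I − I₁q^(−d))/(I₂F) is propagated to first order; the range is
truncated where F drops below 1e-3, and consumers should mask points
whose propagated relative error explodes near the form-factor zero.

Kinetic series are fitted per time point with shared configuration; the
time-averaged ⟨C⟩ is the unweighted mean, and drift is flagged when the
linear trend of c(t) is significant at α = 0.05 (a step change, e.g.
lysis onset, also triggers this test).

## USANS morphology

The correlation-peak model
I(q) = I₀[α/(1−α) + 2x^(−d)]/[1/(1−α) + x^(−2d)], x = qξ/2π, equals I₀
exactly at the peak and plateaus at I₀α at high q; ξ is initialized
from the intensity argmax. The generalized Guinier–Porod model uses the
globular (s = 0) branch pair with the analytic crossover
q₁ = √(3d/2)/R_g, continuous in value and slope; R_g is initialized
from a Guinier line on the lowest decade. Model choice uses
small-sample-corrected AIC — peak presence/absence is the qualitative
discriminator between rouleaux-forming and sphered samples. The derived
volume V = 4πR³/3 assumes isolated spheres; at high haematocrit,
interparticle correlations bias R_g low and the naive volume may be
several-fold too small, so it is reported with that caveat.

**Smearing.** The infinite-slit operator
I_s(q) = (1/Δq_v)∫₀^{Δq_v} I(√(q²+u²))du uses 48-point Gauss–Legendre
quadrature with a power-law tail (fitted on the top decade, or a
configured exponent) beyond the data range. Desmearing is the
multiplicative Lake iteration started from the measured curve, stopped
at reduced χ² < 1.05 against the re-smeared iterate or 200 iterations
(both configurable); negative intermediate intensities are clipped by
default. On a noiseless peak-type curve the smear/desmear round trip is
accurate to well under 1 % over the central decades for slit widths
commensurate with the simulated q window.

## QENS model and reductions

The fitting model is the resolution-convolved two-Lorentzian form with
a linear background (the purely elastic δ-term never appears for
in-solution samples; background positivity is not enforced). The
convolution evaluates the model on a 3× oversampled grid extended ten
resolution widths beyond the window, convolves with the unit-area
kernel (cubic resampling of the tabulated resolution; trapezoid
normalization) and resamples; against an analytic Voigt profile the
operator is accurate to 2.4e-5 of the peak. Per-q fits are independent
bounded least squares with a swapped-width second start as a
label-switching guard; Γ_I ≥ 0 orders the components by construction,
and both widths are bounded at half the energy window — a broader
component is indistinguishable from the linear background, and a width
pinned at its bound marks the fit unusable.

`screen_per_q_fits` additionally drops fits that violate EISF
monotonicity (A₀ rising with q by more than three combined sigma),
the signature of the narrow/broad decomposition collapsing onto the
wrong branch at high q where Γ_G approaches Γ_G+Γ_I.

D_eff comes from the error-weighted, origin-anchored line
Γ_G = ħD_eff q² (an intercept option exists for diagnostics); its error
is the larger of the misfit-scaled analytic error and a sandwich
estimate, since linearized per-q errors can understate the real
scatter. ⟨Γ_I⟩ is the error-weighted mean over q, quoted with its
spread over q (not the standard error of the mean — the spread is the
convention such per-sample tables use and honestly reflects the
q-to-q variation of an effective width); τ = ħ/⟨Γ⟩ with
ħ = 6.582119569e-10 µeV·s, and a regression p-value records whether
Γ_I(q) is flat in q², as localized internal motion requires. The EISF
fit A₀(q) = (1−p)e^(−⟨x²⟩q²) + p is bounded (⟨x²⟩ ≥ 0, p ∈ [0,1]) with
χ²-inflated errors, and a flat A₀ is flagged degenerate (⟨x²⟩
unidentifiable). The sphere-model conversion ⟨x²⟩ = r²/5 links to
diffusion-in-a-sphere analyses.

Buffer subtraction is bin-wise with quadrature-combined errors and a
configurable scale (default 1.0 — transmission or volume-fraction
weighting is not specified for these samples); negative bins are kept
and flagged.

## Crowding relations

η(c)/η₀ = exp([η]c/(1−(k/v)[η]c)) with the measured Hb parameters
[η] = 2.94e-3 l/g and k/v = 0.52 as defaults ([η] and k/v are strongly
coupled, so the theoretical [η] = 3.60e-3 l/g is metadata only, never
substituted); the law has a pole at c_max = v/(k[η]) ≈ 654 mg/ml which
is named in error messages. D(c) = D₀·η₀/η(c) inverts in closed form;
measured QENS coefficients are first divided by the rotation factor
1.27 (spherical particles; overridable). Concentrations are held in g/l
(= mg/ml) throughout. D₀ = 46.8e-8 cm²/s at 288 K and 63.4e-8 cm²/s at
298 K are consumed as scalar inputs.

## Synthetic data

Generators are pure functions of (truth, seed); random streams are
split per component via hashed substream keys so adding a component
never shifts another. USANS: 120 log-spaced points over 2e-5–2e-3 Å⁻¹,
multiplicative Gaussian noise (default 2 %), optional slit smearing
with default half-width 5e-5 Å⁻¹ (chosen commensurate with the
simulated q window so that smearing is strong enough to matter and the
inverse problem remains well-posed). SANS: 150 points over
0.01–0.45 Å⁻¹, counting-statistics noise σ ∝ √I scaled to 2 % relative
error at the interaction peak, power-law amplitude set so forward
scattering and coherent signal are comparable at the peak. QENS: the
backscattering bank (10 q values, 0.34–1.92 Å⁻¹), ±31 µeV window at
0.2 µeV bins (or ±20 at 0.3), Gaussian resolution of 1.0 µeV FWHM,
Poisson noise at ~2500 expected counts at the elastic peak (≈2 %
relative error, the statistics of a many-hour run); the recorded σ
column is the generating (expected-count) width, since weighting by
observed counts biases least-squares fits of counting data. Noise
levels are calibrated so the generating model scores χ²_red = 1.0 ±
0.15 against its own output.

What the generators do **not** emulate: multiple scattering, detector
efficiency and angle-dependent resolution variations, wavelength-spread
smearing, sample-environment backgrounds, and any attractive component
of the Hb–Hb potential. Passing recovery tests therefore demonstrates
the correctness and calibration of the estimators under the stated
noise model, not robustness to every systematic present in real
reductions.

## Known limitations

- At the largest diffusion coefficients (lysate-like, ~19e-8 cm²/s)
  with the restricted ±20 µeV window, the narrow (≈4.6 µeV) and broad
  (≈7.1 µeV) widths overlap at high q and the two-Lorentzian
  decomposition becomes weakly identifiable at 2 % counting statistics:
  for some noise draws the global cost minimum is a collapsed solution
  whose Γ_G overshoots by ~15 % with an underestimated error. The
  screens above remove the flagrant cases; a residual ~1–3 % upward
  bias in D_eff remains for such samples.
- The RMSA is repulsive-only; attractive Hb–Hb interactions, which the
  structure-factor fits hint at above the first maximum, are out of
  scope.
- The USANS volume chain assumes dilute spheres (see above).
- Real vanadium resolution functions are accepted as tables; only a
  Gaussian is synthesized.
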