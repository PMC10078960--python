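# Methods

This note documents the models implemented in `thoraxvar`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The variability model

Each of 15 thorax properties is driven by a unitless scaling coordinate
`s`, varied over `[−2, 2]`. For properties with population SD estimates,
`s` is in SD units; for the costal cartilage modulus it interpolates
percentiles; for the three soft tissues it interpolates between bounding
experimental characterisations.

| coordinate | expression | units |
|---|---|---|
| shape_pc1..6 | `C_i(s) = μ + P_i σ_i s` | mm |
| cort_thickness | `T(s) = exp(ln T_nom + 0.22 s)` (⇔ factor `e^{0.22 s}`) | mm |
| rib_width | `W(s) = W_nom + 1.36 s` | mm |
| rib_height | `H(s) = H_nom + 1.96 s` | mm |
| cort_material | `E = 14.7 + 2.0 s` GPa, `σ_Y = 100.7 + 12.9 s` MPa, `P = 1.94 + 0.5 s` GPa | — |
| trab_material | `E = 25.7 + 46.7 g`, `σ_Y = 0.42 + 0.65 g`, `P = 5.66 + 11.9 g` MPa, `g = 0.95 s / 4` | — |
| cartilage | `E_eff = 21.4 + 1.15 s² + 9.05 s` MPa | — |
| adipose / muscle | Ogden `μ`, `ν`, Prony `G_i` interpolated linearly (see `material_table()`) | Pa / kPa |

Design notes:

* **Trabecular shared term.** The shared scaling term is implemented as
  `g(s) = 0.95·s/4`. This is the reading that keeps all three parameters
  strictly positive over the range (plastic modulus reaches 0.0075 MPa at
  `s = −2`) and spans 95% of the reported parameter range; it is exposed
  as a configurable hook (`scale_trabecular(s, g=...)`) for users who
  prefer another convention.
* **Width/height coefficients.** The per-SD convention (1.36 and 1.96 mm
  per unit `s`) is the default, so `s = ±2` produces the ±2.7 mm and
  ±3.9 mm offsets that correspond to ±2 SD of the sixth-rib minimum and
  maximum area moments of inertia. The alternative reading (2.72/3.92 mm
  per unit `s`) is available as `RAW_PRINTED_CONVENTION`.
* **Thickness.** One multiplicative factor `e^{0.22 s}` scales every nodal
  thickness of all 24 ribs simultaneously; 0.22 is the across-subject SD
  of per-subject log-mean cortical thickness.
* **Units** are kept exactly as the source literature prints them (GPa,
  MPa, Pa, kPa mixed); the material dataclasses expose `*_mpa` accessors
  where a single unit system is needed (e.g. the bi-linear stress curve).

**Population weighting.** Eleven coordinates (shape modes, the three
geometry coordinates, both bone materials) are standard normal truncated
to `[−2, 2]` and renormalised. The cartilage coordinate maps percentiles:
`s = ±2` corresponds to the 5th/95th percentile, so its density is normal
with SD `2/z_{0.95} ≈ 1.216`, truncated to the range. The three
soft-tissue coordinates are uniform (`1/4`) — an explicit equal weighting,
because their ranges span different test setups rather than a sampled
population. All densities integrate to 1 over the range (checked to
1e−8).

## 2. Shape model and thickness fits

Ribcages are 24 centroidal curves (12 levels × 2 sides, vertebral end
first, fixed point count per level). PCA is mean-centred SVD on the
stacked coordinate vectors; component score SDs use the n−1 denominator;
components are sign-fixed so the largest-magnitude loading is positive
(the sign is otherwise arbitrary and `s` semantics must be reproducible);
left and right ribs share one coordinate vector, so modes are
whole-ribcage. Curves are assumed pre-aligned (the synthetic generator
produces aligned data; rigid alignment of real data is the user's
responsibility).

The average-male filter keeps subjects with age > 18 years (strict) and
height/weight in the closed bands 1.72–1.82 m and 72–82 kg; subjects with
missing metadata are excluded with a logged warning.

Thickness maps are fitted per subject by the log-moment estimators
(mean and ML standard deviation of `ln T`), which are the exact
log-normal MLE — chosen over generic optimisation for determinism. A
constant map is degenerate (`σ_log = 0`) and flagged. `population_mu_sd`
is the n−1 sample SD of fitted log-means.

## 3. Surrogate thorax

The surrogate maps a parameter vector to per-rib peak strains:

    ε_r = M_r · c_r / (E · I_r) · A_soft · A_cart

* `I_r`: second moment of an elliptical annulus about the section's major
  (height) axis, so rib *width* is the cubed dimension — under both belt
  loading (frontal) and lateral door/airbag loading (near-side) the ribs
  bend in the plane where width dominates. `c_r = W/2` is the extreme
  fiber; the tensile side is cutaneous in frontal and pleural in
  near-side loading, which for the symmetric annulus changes only the
  recorded convention, not the magnitude.
* Nominal sections: `W_nom = 15.2`, `H_nom = 16.8`, `t_nom = 1.0` mm at a
  mid-level rib, scaled per level by `0.88 + 0.02·level`. These defaults
  follow from a closed-form analysis of the *local log-strain
  sensitivities* at the cut-point, so that they order as beam physics
  dictates:
  thickness (≈ 0.22·∂lnI/∂ln t ≈ 0.18 per unit s) above cortical modulus
  (2.0/14.7 ≈ 0.14) above width (≈ 0.12), mirroring the expected
  dominance of flexural-rigidity parameters.
* Load shares: frontal — bilateral ribs 2–8 peaking at 4–6 (belt/airbag
  path); near-side — struck-side (left) ribs 3–9 peaking laterally.
  Shape modes redistribute the shares through smooth per-level patterns
  with small weights (0.008–0.030 per SD), renormalised so the total
  moment budget is conserved.
* `A_soft`, `A_cart`: exponential attenuation with per-coordinate slopes
  ≤ 0.01 per unit s (≤ ~4% strain modulation over the full range) for the
  soft-tissue, cartilage and trabecular coordinates. These are deliberate
  modelling choices making the non-rigidity parameters weak but nonzero;
  they are config data on `LoadCase`, not discovered results.
* **Calibration.** The per-case moment budget is the root of
  `NFR2+(cut-point) = target` (default 0.51), found by bisection with
  bracket expansion; strains are linear in the budget and NFR2+ strictly
  increasing, so the root is unique. The anchor value is a study
  condition, not a prediction.
* Mass conservation of soft-tissue density under geometric change is
  book-kept by the factor `1/(1+ΔV/V)`.

The surrogate is deterministic (bit-identical strains for identical
inputs) and makes **no fidelity claim** about any finite-element model;
it exists so the statistical pipeline can be exercised and so direction
and rank properties have a documented, physics-consistent test bed. Real
simulation results drop in through `TabulatedStrainModel`, which reads
the same (parameter vector → 24 strains) CSV contract.

## 4. Risk model

Per-rib fracture probability is a probit in log strain with a linear age
shift: `p = Φ((ln ε − (b0 + b_age·age))/σ)`. Published coefficient sets
for strain-based rib risk functions are not redistributed here; the
default (`b0 = −3.7`, `b_age = −0.011`, `σ = 0.4`) is a documented
placeholder giving a ~1.5% median fracture strain at age 45 and risk
increasing with age, with the absolute level absorbed by load
calibration. Supply published coefficients via `RiskFunction` or the JSON
config. Age is fixed at 45 years by default. Strains below 1e−12 map to
p = 0.

NFR2+ assumes independent per-rib fractures (the standard aggregation
assumption when only per-rib maxima are available) and is computed as
1 − P(0) − P(1) with prefix/suffix products, stable for p near 0 and 1;
a 2^n enumeration oracle (n ≤ 20) guards it in tests, alongside an
independent Poisson-binomial tail from scipy.

## 5. Sensitivity analysis

M-DRM approximates the model by a normalised product of one-dimensional
cuts through the cut-point (all `s = 0`). With `ν_i = E[h_i]`,
`τ_i = E[h_i²]` and `r_i = τ_i/ν_i²`:

    S_i  = (r_i − 1)/(∏ r − 1)
    S_ij = (r_i − 1)(r_j − 1)/(∏ r − 1)
    S_Ti = 1 − (∏_{k≠i} r_k − 1)/(∏ r − 1)
    V_Y  = h0^{2(1−n)} (∏ τ − ∏ ν²)

These are the exact Sobol indices of the product-form surrogate, hence
exact for multiplicative models (verified to 1e−10) and approximate
otherwise. Expectations use Gauss–Legendre nodes on each coordinate's
range with explicit density weighting, renormalised per parameter
(`weight ∝ w_GL · f(s)`); five points per parameter by default
(degree-nine exactness), 76 evaluations for the 15-parameter space.
Gauss–Legendre-with-density was preferred over distribution-specific
rules (e.g. Gauss–Hermite) because every coordinate here is truncated to
a finite range; the weighting convention is visible in the serialised
design table.

Numerical conventions: a cut-point output of zero or a vanishing cut mean
`ν_i` makes the product form undefined and raises a degeneracy error;
`∏r − 1` below n·1e−14 is reported as a constant model with zero indices;
`r_i` is floored at 1 (Jensen) to absorb quadrature round-off; outputs
within 1e−6 of the risk bounds trigger a saturation warning. Rankings
sort by descending `S_Ti`, then `S_i`, then name. Second-order indices
come from the same design at no extra model evaluations — a property of
the product form.

**Known limitation (measured, and deliberately left visible).** The
product form cannot represent strongly additive responses with large
coefficient of variation. For the Ishigami benchmark every
one-dimensional cut through the input mean is identically zero (the
degenerate case above), and at the documented fallback cut-point
(π/2, π/2, π/2) the M-DRM first-order indices differ from the analytic
values by up to ≈ 0.24 — far outside Monte-Carlo error. The test suite
asserts the dual-route agreement anyway and the Ishigami case fails,
by design: it quantifies exactly how far the approximation can drift on
interaction-heavy additive models. For the thorax risk model, which is a
smooth monotone response to a load-scaled severity, the approximation
behaves like the multiplicative/additive cases (cross-checked in tests);
results should still be read as indicative rankings, not exact variance
shares.

The Monte-Carlo oracle uses Saltelli's A/B/AB_i design with the
Saltelli-2010 first-order and Jansen total estimators, distribution-exact
sampling per coordinate, a fixed seed, and standard errors from the
per-sample estimator spread.

## 6. Synthetic data

The generators produce every input the pipeline reads, with ground truth
emitted in sidecars so recovery tests do not depend on the code under
test.

* **Rib curves**: smooth semi-elliptical arcs with level-dependent span
  and depth (monotone growth to rib 7, decline to rib 12), caudal droop
  and a small out-of-plane twist; left/right are exact mirrors. These are
  statistical stand-ins, not CT reconstructions — no claim of anatomical
  fidelity.
* **Populations**: subject = template + Σ σ_j z_ij M_j + noise, with six
  smooth orthonormal modes (SDs 30, 22, 16, 11, 8, 6 mm), independent
  standard-normal scores, and isotropic residual noise of 0.08 mm per
  coordinate. The noise level is a generator calibration: with ~1440
  coordinate dimensions and n = 89 subjects, spiked-covariance analysis
  gives a 6th-mode subspace error of ≈ 3° at 0.08 mm but > 10° at
  0.3 mm, so larger noise would make the generating subspace genuinely
  unidentifiable at the study's sample size. The cost is a residual
  spectrum much thinner than CT data (first six modes explain ~99% of
  variance here versus ~90% in real populations) — passing recovery tests
  therefore demonstrate estimator correctness, not robustness to
  realistic residual anatomy.
* **Metadata** is sampled uniformly over windows wider than the
  average-male criteria (ages 16–60, heights 1.68–1.86 m, weights
  68–86 kg) so the inclusion filter always has both accepts and rejects.
* **Thickness maps**: per-subject log-mean ~ N(ln 0.7 mm, 0.22), nodal
  log-SD 0.35, 33 subjects × 2000 nodes by default; `population_mu_sd`
  recovery is tested against the 3-standard-error band
  0.22/√(2·32) ≈ 0.0275.
* **Test functions**: multiplicative (`∏(1+a_i x_i)`, uniform),
  shifted additive linear (truncated normal), Ishigami (a = 7, b = 0.1,
  uniform on [−π, π]) and constant — each with exact Sobol indices
  computed in closed form at build time.

All generators are bit-reproducible under a fixed seed; the main analysis
pipeline itself contains no random state.

## 7. Problem sizes and runtime

The default study is deliberately small: 76 surrogate evaluations per
load case (152 total), oracle validation at 65,536 Saltelli samples on
3-to-4-dimensional analytic functions, PCA recovery at n = 89 subjects ×
1440 coordinates, and thickness recovery at 33 × 2000 nodes. The full
test suite runs in a few seconds on one CPU; these sizes were chosen to
match the emulated study's sample sizes where stated and otherwise to
keep statistical tolerances (3–4 SE) meaningful.

## 8. Out of scope

No finite-element solving, mesh morphing, contact or occupant-kinematics
modelling; morph targets are emitted as point sets only. No solver
keyword-file emission. No constitutive time integration of the
Ogden/Prony soft-tissue models (parameters are produced and logged). No
rib-level fracture location prediction, and no alternative dependence
structures (copulas) for the NFR2+ aggregation.
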