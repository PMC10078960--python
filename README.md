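# thoraxvar

Population variability of the human thorax and its influence on
probabilistic rib fracture risk prediction.

Rib fractures remain one of the most frequent serious injuries of vehicle
occupants, and the risk of sustaining them under a given thoracic load
varies strongly between individuals: ribcage shape, rib cross-sectional
dimensions, cortical bone thickness and bone/soft-tissue material
properties all differ across the population. Finite-element human body
models (HBMs) predict rib fracture risk at the tissue level, but each model
is a single fixed individual. `thoraxvar` is a library for asking, in a
reproducible and testable way, *which* thorax property variations matter
most for occupant-level rib fracture risk — the information needed to
decide which parameters are worth building into population-variability HBM
studies.

It is aimed at injury-biomechanics and vehicle-safety researchers, and at
anyone who needs a worked, tested implementation of variance-based
sensitivity analysis on an expensive black-box model with a one-at-a-time
quadrature design.

## What the package computes

**Parameter space.** Fifteen unitless scaling coordinates `s ∈ [−2, 2]`
drive the variability model: six ribcage-shape principal-component scores,
cortical thickness, rib cross-sectional width and height, cortical and
trabecular bone material, costal cartilage modulus, and three soft-tissue
materials (adipose, skeletal muscle, intercostal muscle). For normal
coordinates `s` counts standard deviations (e.g. cortical bone
`E = 14.7 + 2.0·s` GPa, nodal thickness scaled by `exp(0.22·s)`); the
cartilage coordinate interpolates the 5th–95th percentile of a log-normal
modulus distribution (`21.4 + 1.15·s² + 9.05·s` MPa); the soft-tissue
coordinates interpolate bounding experimental characterisations and are
weighted uniformly.

**Shape and thickness statistics.** A statistical shape model of rib
centroidal curves, `C_i(s) = μ + P_i σ_i s`, fitted by PCA to populations
of average-male ribcages (selected by age > 18 y, height 1.72–1.82 m,
weight 72–82 kg), and per-subject log-normal fits of nodal cortical
thickness maps whose log-mean spread across subjects gives the thickness
scaling SD σ_μ.

**Risk.** Per-rib peak strain maps to fracture probability through an
age-adjusted probit in log strain, `p = Φ((ln ε − (b0 + b_age·age))/σ)`
(age fixed at 45 years by default), and per-rib probabilities aggregate,
assuming independence, into **NFR2+** — the probability of two or more
fractured ribs (a Poisson-binomial upper tail).

**Sensitivity.** Variance-based Sobol indices estimated by the
multiplicative dimensional reduction method (M-DRM): the model is
approximated around the all-average cut-point by a normalised product of
one-dimensional cuts, so first-order `S_i`, second-order `S_ij` and total
`S_Ti` indices follow from one-dimensional Gauss–Legendre integrals with
explicit density weighting. A full 15-parameter study costs `15·N_GP + 1`
model evaluations per load case (76 at the default five-point rule) versus
`3^15 ≈ 14.3 million` for a three-level full factorial. A seeded
Saltelli/Jansen Monte-Carlo oracle is included for validating the
estimator on analytic test functions.

**Surrogate thorax.** Crash simulation itself is replaced by a documented,
deterministic surrogate: beam bending of elliptical-annulus rib sections
(`ε = M·c / (E·I)` with weak, configurable modulation from the remaining
parameters), with per-case load magnitudes calibrated so the cut-point
model predicts a stated NFR2+ (51% by default). The surrogate is a test
harness for the statistics, not a validated biomechanical model; users
with real simulation results substitute them via the tabulated-strain
adapter (`thoraxvar.surrogate.TabulatedStrainModel`).

## Worked example

```python
from thoraxvar import StudyConfig, run_study

report = run_study(StudyConfig())
for case, bundle in report.cases.items():
    result = bundle["result"]
    magnitude = report.calibrated_cases[case].load_magnitude
    print(f"{case}: calibrated moment budget {magnitude:,.0f} N*mm, "
          f"{bundle['n_evaluations']} model evaluations")
    for name in result.ranking()[:4]:
        print(f"  {name:<16} S_i = {result.S[name]:.3f}   S_Ti = {result.S_T[name]:.3f}")
```

prints

```
frontal: calibrated moment budget 270,060 N*mm, 76 model evaluations
  cort_thickness   S_i = 0.277   S_Ti = 0.428
  cort_material    S_i = 0.194   S_Ti = 0.319
  rib_width        S_i = 0.176   S_Ti = 0.294
  rib_height       S_i = 0.117   S_Ti = 0.205
near_side: calibrated moment budget 171,018 N*mm, 76 model evaluations
  cort_thickness   S_i = 0.314   S_Ti = 0.429
  cort_material    S_i = 0.210   S_Ti = 0.304
  rib_width        S_i = 0.182   S_Ti = 0.267
  rib_height       S_i = 0.116   S_Ti = 0.177
```

Reading: in both impact directions the surrogate attributes the largest
shares of NFR2+ risk variance to cortical bone thickness, cortical bone
material and rib cross-sectional width — the three parameters that control
the flexural rigidity of the ribs. The gap between `S_i` and `S_Ti`
signals substantial interaction effects among these parameters. Since the
strain model is a surrogate, the rank order is the meaningful output, not
the absolute index values.

The same study is available from the shell:

```sh
thoraxvar run --ngp 5 --out results/study
thoraxvar synth population --n 89 --seed 1 --out data/pop
thoraxvar oracle --function ishigami --n 65536 --seed 1
```

## Layout

- `thoraxvar.parametric_model` — parameter space, scaling expressions, densities
- `thoraxvar.shape_model` — rib-curve PCA, thickness log-normal fits, filters
- `thoraxvar.surrogate` — elliptical-annulus beam surrogate, load calibration
- `thoraxvar.risk_model` — probit risk function, NFR2+ aggregation
- `thoraxvar.sensitivity` — Gauss designs, M-DRM indices, Monte-Carlo oracle
- `thoraxvar.synthetic_data` — population/thickness generators, test functions
- `thoraxvar.workbench` — study orchestration and reports; `thoraxvar.cli`

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
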