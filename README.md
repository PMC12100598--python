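# tubulaxs

Parametric models of tubulin supramolecular assemblies and the machinery
to fit their solution scattering.

Besides microtubules, αβ-tubulin heterodimers can assemble into
*inverted helical tubules* (a single left-handed helix of dimers with the
lumen-facing surface pointing outward), *conical spiral tubules* (stacked
conical spirals whose radius shrinks from R_max to R_min over n turns),
and 2-D *bundles* of such tubules — hexagonal (γ = 120°) for parallel
packing, oblique (γ = 105°) for mixed parallel/antiparallel packing.
Small-angle X-ray scattering (SAXS) of these suspensions is exquisitely
sensitive to the tubule radii, the helical pitch and the bundle lattice
constant, and time-resolved SAXS of assembly reactions can be decomposed
into population fractions of an initial and a final state.

`tubulaxs` is for structural biophysicists who want to go from a handful
of geometric parameters to a model scattering curve — and back, from a
measured or synthetic curve to radii, pitches and mass fractions:

- **geometry** — pose builders for helical tubules, conical spiral
  tubules, bundle lattices and plain microtubule cylinders.  A pose is a
  dimer center (nm) plus Tait–Bryan angles (deg,
  A = A_x(α)·A_y(β)·A_z(γ)); conical spirals place dimers at equal
  arc-length steps L_dim using the closed-form arc length
  S(t) = 1/(2C)[u√(u²+k²) + k²·asinh(u/k)], u = Ct − R_max, k² = C² + A²,
  solved by bisection to a 10⁻¹⁴ nm tolerance.  Derived quantities
  include the cone angle θ = arctan((R_max − R_min)/V_h) and the oblique
  lattice distances b₁ = √(2a²(1−cos γ)) = 1.59a, b₂ = 1.22a.
- **scattering** — coarse-grained bead models (buffer 334 e/nm³,
  hydration shell 364 e/nm³ × 0.28 nm, protein ≈ 410 e/nm³) and the
  orientationally averaged Debye sum
  I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ)/(q rᵢⱼ), exact up to a few thousand
  beads and histogram-accelerated beyond.
- **state_fitting** — per-curve weighted two-state fits
  I(q, t) ≈ f_A·A(q) + f_B·B(q) with closure and non-negativity, SVD
  component counting, isosbestic-point detection, background subtraction.
- **structure_fit** — non-negative mixture fits over component libraries
  (coefficients are tubulin mass fractions) and grid scans of geometric
  parameters with a scale-free weighted χ² objective.
- **synthetic_data** — a built-in two-ellipsoid tubulin dimer (no PDB
  download needed), seeded multiplicative-noise curves and lag-phase
  (logistic) kinetic series with serialized ground truth.
- **io / cli** — plain-text "dol" pose files, 3-column SAXS curves, PDB
  subunits (via gemmi), YAML configs, and a `tubulaxs` command with
  `build-helix`, `build-cone`, `build-bundle`, `build-mt`, `scatter`,
  `fit-two-state`, `svd`, `isosbestic`, `fit-structure`, `simulate`.

See `docs/methods.md` for the model conventions, numerical choices and
limitations.

## Worked example

```python
import numpy as np
import tubulaxs as tx
import tubulaxs.scattering as sc

# a conical spiral tubule: R_max 22 nm -> R_min 14 nm over 3 turns,
# pitch 12 nm, two conical repeats stacked every 10 nm
spec = tx.ConicalSpiralSpec(R_max=22.0, R_min=14.0, p=12.0, n=3,
                            V_h=10.0, N_spirals=2)
asm, derived = tx.build_conical_spiral_tubule(spec)
print(len(asm), round(derived.theta_cone, 1))   # 86 dimers, 38.7 deg cone

# its scattering curve, using the built-in two-ellipsoid dimer
dimer = tx.make_synthetic_dimer()                # 456 beads
q = sc.default_q_grid(0.02, 3.0, 100)
tubule_curve = sc.assembly_intensity(asm, dimer, q)

# a noisy synthetic assembly reaction and its two-state decomposition
basis_a = sc.debye_intensity(dimer, q)                      # dimer-rich
basis_b = tx.SAXSCurve(q, tubule_curve.I / len(asm))        # assembled
scen = tx.KineticScenario(times=tuple(np.linspace(0, 240, 12)),
                          tau_lag=60, rate=0.08,
                          noise=tx.NoiseModel(0.02, 0.0, seed=1))
family, f_true = tx.make_kinetic_series(scen, basis_a, basis_b)
fit = tx.two_state_fit(family, basis_a, basis_b)
print(np.round(fit.f_b, 3))
print(round(fit.r2_global, 4))
```

prints

```
86 38.7
[0.008 0.045 0.213 0.606 0.896 0.985 0.992 0.995 0.999 0.997 0.997 0.998]
0.9996
```

The recovered fractions trace the generating lag-phase trajectory
(true values 0.008, 0.045, 0.213, 0.607, 0.899, …) to a few parts in a
thousand at 2 % multiplicative noise, with a global R² of 0.9996.

The same from the shell:

```sh
tubulaxs build-cone --r-max 22 --r-min 14 --p 12 --n 3 --v-h 10 \
    --n-spirals 2 --out cone.dol
tubulaxs scatter --dol cone.dol --out cone.dat
tubulaxs simulate --seed 1 --out-prefix kinetics
```

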