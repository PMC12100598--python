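# Methods

## Scope and model overview

`tubulaxs` models the supramolecular assemblies that αβ-tubulin
heterodimers form in solution — microtubules, *inverted helical tubules*
(a single left-handed helix of dimers with the lumen-facing surface
pointing outward), *conical spiral tubules* (stacked conical spirals whose
radius shrinks from R_max to R_min), and 2-D bundles of such tubules — and
computes their small-angle X-ray scattering (SAXS) so that structural
parameters and population fractions can be fitted to measured or synthetic
curves.

Every assembly is an ordered list of subunit poses: the dimer
center-of-mass position (nm) and a Tait–Bryan orientation
(α, β, γ in degrees, composed as A = A_x(α)·A_y(β)·A_z(γ)).  Pose lists
round-trip through plain-text "dol" files.

## Geometry

**Inverted helical tubule.**  Dimers sit on a helix of radius r and pitch
p: x_i = r cos θ_i, y_i = r sin θ_i, z_i = i·p·L_dim/L_turn with
L_turn = √(4π²r² + p²).  The default azimuthal step is θ_dim = L_dim/r
(the dimer length laid along the equatorial circle).  A second mode,
`spacing="arc"`, advances θ_dim = 2π·L_dim/L_turn so the step measured
along the 3-D helical line is exactly L_dim; this is the C → 0 limit of
the conical construction below, and the two modes agree exactly at p = 0
and to O((p/L_turn)²) otherwise.  The subunit count is
i_max = ⌊(h/p)(L_turn/L_dim) + 1⌋ (a ring of ⌊2πr/L_dim⌋ dimers when
p = 0); count expressions carry a 1e-9 tie guard so exact integer ratios
are not lost to the last bit of rounding.  Orientations tilt the dimer
along the local tangent, α = 90° − asin(p/L_turn), and swing it around the
axis, β = θ_i, γ = 0.  The builder emits the equations' native sense of
rotation; a handedness flag mirrors y (and negates β) for the enantiomer.

**Conical spiral tubule.**  The spiral is
((R_max − C t) cos t, (R_max − C t) sin t, A t) with C = (R_max − R_min)/(2πn)
and A = p/(2π).  Dimers are placed at equal arc-length increments L_dim:
the arc length has the closed form

    S(t) = 1/(2C) [ u√(u² + k²) + k² asinh(u/k) ]  evaluated u = −R_max … Ct − R_max,

k² = C² + A².  The naive antiderivative difference loses ~R²/C digits as
C → 0, so for the usual case (radius everywhere positive) an algebraically
equivalent cancellation-free rearrangement is used; C = 0 falls back to
the circular-helix formula t·√(R_max² + A²).  Agreement with adaptive
quadrature of the speed integrand is ~1e-13 nm over random parameters.
Each t_i solves S(t_i) − S(t_{i−1}) = L_dim by bisection with a doubling
bracket above t_{i−1}; the default arc tolerance is 1e-14 nm, with the
caveat that evaluating S in float64 limits certified increments to about
eps·S_total, so the search terminates at machine resolution in t.  The
sequence stops at t = 2πn, giving ⌊S(2πn)/L_dim⌋ + 1 dimers.  Tilt uses
the per-dimer rise: α_i = 90° − asin(A·Δt_i/L_dim) with
Δt_i = t_{i+1} − t_i (the last dimer reuses the previous increment),
β_i = t_i, γ_i = 0.  N_spirals copies stack at spacing V_h along z and the
tubule is shifted by −z_max/2 to center it.  The cone opening angle is
θ = arctan((R_max − R_min)/V_h).

**Bundles.**  Hexagonal mode (γ = 120°) replicates a tubule at
R_n = n₁a₁ + n₂a₂ and keeps copies inside the disc ‖R_n‖ ≤ cutoff
(default a·n_max, boundary ties included).  Oblique antiparallel mode
(γ = 105°) builds two interleaved sublattices of parallel tubules with
primitive vectors 2a(1,0) and b_j(cos(90°+γ/2), sin(90°+γ/2)), where
b₁ = √(2a²(1−cos γ)) = 1.59a and b₂ = √(2a²(1−cos(180°−γ))) = 1.22a; the
second sublattice is shifted by (a, 0) and flipped antiparallel
(α = 180°), and every copy receives the in-plane alignment rotation
γ = atan2(R_n·ŷ, R_n·x̂).  The b₁ spacing is the default: it puts the four
nearest antiparallel neighbors at exactly distance a and the two nearest
parallel neighbors at |2a·x̂ + b₁·ê| ≈ 1.22a, reproducing the
4-antiparallel + 2-parallel coordination of the oblique tubulin bundles;
the b₂ spacing is selectable but places antiparallel neighbors at 0.74a,
inside the non-penetration bound.  Non-penetration guards (a ≥ 2r + T_dim
hexagonal; a ≥ R_max + R_min + T_dim oblique) raise before building.

**Microtubule.**  N_p straight protofilaments equally spaced on a cylinder
of radius r, each a vertical dimer stack with a fixed axial rise; this is
a reference geometry for basis curves, not a fitted lattice (no seam, no
helical rise mismatch).

## Scattering

Subunits and assemblies are coarse-grained into spherical beads carrying
*effective excess electrons* (contrast vs buffer × volume share).  The
orientationally averaged intensity is the Debye sum
I(q) = Σ_ij f_i f_j sinc(q r_ij), f_i = n_i·Φ(qR_i), with Φ the uniform
sphere amplitude — exact for the bead representation.  Defaults follow
aqueous protein SAXS: buffer 334 e/nm³, hydration shell 364 e/nm³ and
0.28 nm thick, protein 410 e/nm³; q grid 0.02–3 nm⁻¹ (log-spaced, 400
points by default).  Atomic form-factor q dependence is ignored in this
SAXS window: beads carry constant excess electrons.

Coarse-graining fills the envelope (union of ellipsoids, or binned atoms)
on a cubic grid of one bead diameter.  Boundary cells are weighted by the
occupied volume fraction (sub-grid sampling) and placed at the occupied
centroid; both steps remove the jagged-surface error floor and the
residual dipole term of a center-in/center-out mask.  Total excess
electrons are normalized to the analytic envelope volume, so I(0) is
independent of discretization.  Accuracy against the closed-form sphere:
intensity-weighted profile deviation 1.5e-3 → 1.2e-4 over qR ≤ 8 on a
bead-radius ladder 0.45 → 0.2 nm (monotone), with pointwise error < 1%
below the first form-factor zero.  Pointwise relative error *at* the
form-factor zeros is unbounded for any approximant and is not a meaningful
metric.

The pair sum is evaluated exactly up to 3000 beads (numba-accelerated
when available, chunked numpy otherwise) and by a blocked pair-distance
histogram above that (bin 0.02 nm; each bin contributes at its weighted
mean distance, cancelling the first-order binning error; observed
agreement with the exact path ~2e-4 relative).  A reduced mode collapses
each subunit to one volume-equivalent bead for very large bundles (valid
at low q; forward intensity preserved to ~1e-4).

## State fitting

Curve families (shared q grid) are decomposed as linear combinations of
two basis states with per-curve weighted least squares (1/σ² when σ is
present, else uniform).  Closure (f_A + f_B = 1) and non-negativity are on
by default, matching fraction trajectories that sum to one; the
unconstrained mode is kept for diagnostics.  Collinear bases raise.

SVD rank: when σ is known, the intensity matrix is column-scaled by the
rms σ of each q bin — a diagonal scaling that preserves rank exactly while
flattening the noise spectrum — and the effective rank counts singular
values above the variance-profile operator-norm bound
(√max-row-sum + √max-col-sum of the scaled variances, ×1.5 safety).
Without σ, the floor is 3× the median of the trailing half of the
spectrum.  A naive plateau criterion on the raw matrix miscounts rank for
multiplicative noise because the noise magnitude tracks I(q) over orders
of magnitude.

Isosbestic points — q values where all curves of a two-state mixing
series cross — are local minima of the across-curve relative spread
(std/mean) below a tolerance (default 1%).  Crossings closer than the
grid resolution merge; identical curves degenerate to "every q", which is
returned as such.  Background (supernatant) subtraction interpolates the
blank onto the sample grid, restricts to the overlap, and combines σ in
quadrature.

## Structure fitting

`mixture_fit` decomposes a curve over a component library (free dimer,
short tubule, bundle, …) by non-negative least squares.  Component curves
are divided by their dimer counts first, so coefficients weight tubulin
*mass*; reported fractions are the coefficients renormalized to sum to 1,
with the global intensity scale kept free (model curves are
arbitrary-scale relative to measured intensity).

`scan_structure_params` grid-searches geometric parameters, rebuilding the
assembly and its Debye curve per grid point (cached across scans), and
minimizes weighted χ² after fitting a free scale — hence invariant to the
target's overall scale.  χ² uses σ when present, else a 1% relative
pseudo-σ.  Optional Nelder-Mead refinement exists but is off by default:
the objective is stepwise in parameters that change discrete subunit
counts.

## Synthetic data

The synthetic dimer is two tangent ellipsoids along z (the α and β
monomers), semi-axes (T_dim/2, T_dim/2, L_dim/4), default
L_dim = 8 nm × T_dim = 5 nm — the conventional size of the tubulin
heterodimer — at 410 e/nm³, a typical protein electron density (only the
buffer and shell densities are constrained by the experimental
conventions; 410 is this package's choice and is configurable).  Noise is
multiplicative Gaussian (default 2% relative, emulating
steady-state error bars) plus an optional additive floor; the σ column is
populated with the nominal uncertainty, and all draws are seeded.
Kinetic series mix a dimer-rich and an assembled basis following a
logistic lag-phase trajectory f_B(t) = expit(k(t − τ_lag)) (the lag-phase
shape is a modeling choice; default τ_lag = 60 s, k = 0.1 s⁻¹).

What the generators do *not* emulate: instrument smearing, detector
geometry, absolute-intensity calibration, inter-curve correlated drifts,
and structural polydispersity (one parameter set per component).  Passing
recovery tests therefore demonstrates the correctness of the estimators
under the stated noise model, not their robustness to every artifact of
measured data.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale sizes chosen as the
smallest problems that still exercise each claim: 60–600 point q grids,
tubules of 10–50 dimers, a coarse synthetic dimer (~50 beads), 7-tubule
hexagonal bundles (reduced beads), 100-mixture/50-replicate recovery
ensembles, and a 10-point radius ladder with a 0.25 nm scan grid.  Count
expressions use a 1e-9 tie guard; bisection brackets double until the
target is enclosed; degenerate inputs (r = p = 0, empty models, all-zero
targets, collinear bases, disjoint q ranges) raise typed errors.

## Known limitations

- The hybrid atomic/voxel scattering engine used for the published atomic
  models is out of scope; the Debye bead sum is exact for the
  coarse-grained representation but smooths atomic detail above
  q ≈ 3 nm⁻¹.
- The microtubule model is a plain cylinder lattice (no B-lattice seam or
  protofilament-number-dependent helicity).
- The dimer's internal reference orientation (which face points at the
  lumen) is not constrained by the pose conventions alone; β carries the
  azimuthal alignment, and any fixed intrinsic offset of the subunit model
  cancels in the orientationally averaged intensity of identical copies.
- Fitted "mass fractions" assume equal dimer mass in all components and
  per-dimer normalized component curves; other conventions rescale the
  coefficients.
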