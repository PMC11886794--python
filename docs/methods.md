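# Methods

## Geometry model

A single-axis tilt geometry maps voxel indices to continuous detector
coordinates. Axes follow the MRC convention — arrays are `(z, y, x)` for
volumes and `(tilt, y, x)` for stacks — and continuous coordinates place
the center of an n-sample axis at `(n − 1)/2` (0-based), which keeps the
forward and adjoint operators symmetric under flips and avoids half-pixel
drift. For a voxel with centered offsets `(dx, dy, dz)`, tilt `θ`
(nominal angle plus a global tilt offset) and pitch `α`:

```
p_col = dx·cosθ + dy·sinα·sinθ + (dz + s)·cosα·sinθ + c_col
p_row = dy·cosα − (dz + s)·sinα + c_row
```

where `s` is the z-shift in voxels. Conventions: positive tilt rotates
the specimen right-handedly about +y; the detector column increases with
volume x at zero tilt; the pitch (a constant specimen-mounting rotation
about x) is applied before the tilt; the z-shift translates the
reconstruction slab along the beam axis before any rotation, so it is
invisible at zero tilt. Angles live in degrees in files and user
parameters and are converted to radians exactly once. Effective tilts at
or beyond 90° are rejected as degenerate.

Because `p_row = iy` identically when `α = 0`, the projection operator
block-decouples across y at zero pitch; that identity is the basis of the
slab engine below and is asserted bit-for-bit in the tests.

## Projection operators

The forward projector is voxel-driven: each voxel splats its value onto
the four nearest detector pixels with bilinear weights that sum to one;
splats falling off the detector are discarded. The backprojector gathers
with the same weights, i.e. it is the exact adjoint by construction —
realized through one sparse matrix per tilt angle, so `⟨Ax, y⟩ = ⟨x, Aᵀy⟩`
holds to round-off for every geometry. Zero-weight entries are dropped
from the matrices; this is what makes the zero-pitch y-decoupling exact
rather than approximate. A bilinear (2×2) footprint keeps the adjoint
cheap and exact; storage is O(4·n_voxels) per angle, which bounds the
practical problem size of this CPU implementation to desk scale (tens of
millions of voxels).

## Filters

FBP/WBP filter each projection row (along the detector-column axis) in
1D Fourier space. Rows are padded to the next power of two at least
twice the row length; the pad replicates the row's boundary value rather
than inserting zeros, so a constant row stays constant around the circle
and filters to exactly zero (the ramp kills DC) instead of acquiring the
boxcar edge response of zero insertion. Responses, with `f` in cycles
per sample and cutoff `f_c ∈ (0, 0.5]`:

- `ramp`: `|f|`, zero beyond `f_c`;
- `ramp-hamming` / `ramp-hann`: the ramp times the cosine window
  stretched to the cutoff;
- `exact-weighting` (the WBP default): the ramp held at full weight up to
  `f_c(1 − r)` then tapered linearly to zero at `f_c`, with roll-off
  fraction `r = 0.05` by default.

FBP and WBP scale the normalized backprojection by `π/(2·n_tilts)`, the
discretization of the inverse-Radon angular integral. Defaults
`f_c = 0.5`, `r = 0.05` follow mainstream weighted-backprojection
practice; the distinction between FBP and WBP is a filter-shape
configuration, not separate code paths.

## Iterative solvers

All iterative methods start from `x⁰ = 0`, are RNG-free and bitwise
deterministic, and share the splat-weight normalization: `R` is the
inverse per-detector-pixel weight sum and `C` the inverse per-voxel
weight sum (zeros where the weights vanish). With this Cimmino-style
weighting the normalized operator `R^{1/2} A C^{1/2}` has spectral norm
at most 1, so the SIRT update `x ← x + λ C Aᵀ R (b − Ax)` is stable for
relaxation `λ ∈ (0, 2)` and converges, from zero, to the weighted
least-squares solution `C^{1/2} (R^{1/2} A C^{1/2})⁺ R^{1/2} b`. An exact
solution of a consistent system is a fixed point, and the data residual
is non-increasing for `λ ∈ (0, 1]`. SART applies the same correction
restricted to one tilt per sub-step (per-angle `R`, `C`), sweeping angles
in ascending-angle order by default (file order is available); with a
single angle one SART sweep coincides exactly with one SIRT iteration.
Any non-finite iterate aborts with the iteration index, since relaxation
factors are user-supplied.

A caveat that shaped the test design: limited-angle splat systems are
intrinsically ill-conditioned — for any volume with nz ≥ 2 the smallest
singular value of the normalized operator is of order 10⁻³–10⁻²
(missing-wedge modes are nearly invisible to the data), so no fixed
iteration budget reaches the pseudo-inverse solution on such systems.
Convergence contracts (SIRT vs pseudo-inverse, SART/SIRT fixed-point
agreement, ADMM λ→0) are therefore verified on consistent single-layer
systems (nz = 1 with a detector wide enough to catch every splat), where
the smallest singular value is ≈0.6 and a few hundred iterations converge
to machine precision; fixed-point, monotonicity and oracle-equivalence
properties are still exercised on 3D missing-wedge problems.

## ADMM

The regularized objective is `½‖Ax − b‖² + λ‖Dx‖₁` with `D` the forward
finite-difference operator along x, y and z (anisotropic total
variation, Neumann boundaries). The split `Dx = z` with penalty `ρ`
gives the classical three-step scheme: an inexact x-update (3 gradient
steps on the augmented objective per outer iteration, configurable), the
elementwise soft-threshold `z = S_{λ/ρ}(Dx + u)`, and dual ascent
`u ← u + Dx − z`. The x-steps are preconditioned by the diagonal bound
of the augmented Hessian — splat column weights plus `ρ` times the
Gershgorin row-sum bound of `DᵀD` (4 per axis of extent > 1) — which
keeps the steps contractive for any `ρ` without changing the fixed
points; on the fidelity part this reduces to the SIRT normalization.
`z` is initialized to `Dx⁰` so a λ=0 run tracks the unregularized
iteration from the first step. Defaults: `ρ = 1`, `λ = 0.1` (data scaled
as in the fixtures), 3 inner steps.

TV couples neighboring voxels in every direction, including across
y-slab boundaries, so ADMM runs whole-volume only; the slab engine
refuses it explicitly rather than producing silently inconsistent seams.

## Slab engine

`plan_slabs` partitions `[0, ny)` into near-equal cores (sizes differing
by at most one). Each slab reconstructs its core voxel rows from the
detector rows `[y₀ − halo, y₁ + halo)`; the halo is
`ceil((thickness/2 + |zshift|)·tan|pitch| + 1)` (zero at zero pitch),
the worst-case pitch-induced row displacement plus one row for the
bilinear footprint. Where the halo extends past the detector edge the
boundary row is replicated — the void-filling rule; replication adds no
invented densities and only affects a band of at most `halo` rows at the
volume's y-faces. Slabs are pure functions of their inputs, run on a
thread pool in any order, and are merged by direct row assignment into
disjoint cores, so the result is independent of worker count and
scheduling, and at zero pitch bitwise equal to the unsliced run for
BPT/WBP/FBP/SIRT/SART.

## FRC evaluation

The correlation between two volumes is computed per spherical Fourier
shell: `Re Σ F₁F₂* / sqrt(Σ|F₁|² Σ|F₂|²)`, shells one Fourier voxel wide
by default (the API keeps the historical name FRC; for 3D volumes this
is the quantity usually called FSC). The resolution estimate is the
first downward crossing of the threshold (0.143 by default, the half-map
convention), linearly interpolated between shell centers; the DC shell
always correlates and is excluded from the search. `even_odd_split`
provides the standard half-set protocol (even tilt indices vs odd);
computing the curve against a known reference volume is equally
supported.

## Synthetic data

Phantoms are unions of spheres, ellipsoids and cuboids voxelized by
center-inclusion (a voxel belongs to a body iff its center is inside;
later bodies overwrite earlier ones). No antialiasing: the rule is
deterministic and analytically checkable (a radius-6 sphere's voxel
count matches (4/3)πr³ within 5%). Simulated series are forward
projections of the phantom over ±60° at 2° steps — the common
dose-symmetric survey range, chosen so reconstructions exhibit the
missing-wedge anisotropy the algorithms must face — plus additive white
Gaussian noise from a seeded generator; the registered fixtures use
σ ≈ 10% of the peak projection value. The standard fixtures are 32³
(48³ for the "large" variant), sized so the whole suite runs in minutes
on one CPU. Real data differ in ways not modeled here — CTF modulation,
dose-dependent damage, alignment errors, non-Gaussian counting noise —
so passing tests validate operator and solver correctness, not
robustness to those effects.

## Known limitations

- The splat matrices are held in memory per angle; very large volumes
  need the slab engine (or smaller sub-problems) to stay within RAM.
- No nonnegativity constraint, CTF model, dose weighting, or Fourier
  (gridding) reconstruction.
- Per-image alignment is assumed done upstream; only a global tilt-angle
  offset is provided, with per-image angles taken from the angle file.
- HDF I/O is not implemented; MRC/ST is the interchange format.
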