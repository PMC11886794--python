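# tomoslab

CPU-based cryo-electron tomography (cryo-ET) reconstruction for aligned,
CTF-corrected tilt series, aimed at method developers and desk-scale
experiments. The package implements six classical single-axis tomographic
reconstruction algorithms — BPT, WBP, FBP, SIRT, SART and ADMM — over an
explicit tilt-geometry model (tilt-angle offset, pitch angle, z-shift,
thickness), a y-axis slab decomposition engine for parallel execution,
MRC/ST + TLT/RAWTLT file I/O, Fourier shell correlation (FSC/FRC)
evaluation, and a synthetic-data module so every algorithm can be
exercised end to end without external data.

## The model

A tilt series is a stack of projections `b_i` of an unknown density
volume `x` at stage tilt angles `θ_i` about the y-axis. With the
voxel-splatting projection operator `A` (each voxel lands on its four
nearest detector pixels with bilinear weights), the methods are:

- **BPT** — normalized backprojection, `x = diag(Aᵀ1)⁻¹ Aᵀ b`.
- **FBP / WBP** — backprojection of rows filtered in 1D Fourier space
  with a ramp `|ω|` shaped by a window (Hamming/Hann) or, for WBP, a
  linear roll-off near the cutoff.
- **SIRT** — `xᵏ⁺¹ = xᵏ + λ C Aᵀ R (b − A xᵏ)` with `R`, `C` the inverse
  row/column splat-weight sums (Cimmino-style weighting), `x⁰ = 0`.
- **SART** — the same normalized correction applied one tilt angle at a
  time within each sweep.
- **ADMM** — `min_x ½‖Ax − b‖² + λ‖Dx‖₁` with `D` the forward-difference
  operator along x, y, z (anisotropic total variation), split via
  `Dx = z` with penalty `ρ`; soft-threshold z-updates and dual ascent.

The backprojector is the exact adjoint of the forward projector by
construction, which is what makes the iterative methods' gradients
correct. At zero pitch the operator block-decouples across y-rows, so the
slab engine reconstructs y-slabs independently (bit-for-bit equal to the
unsliced result) on a worker pool; ADMM is deliberately refused in sliced
mode because the TV term couples neighboring slabs.

## Worked example

```python
import numpy as np
from tomoslab import (standard_fixture, build_transforms, FilterSpec,
                      ReconstructionParams, plan_slabs, run_sliced,
                      even_odd_split, fbp, frc)

# a 32^3 multi-sphere phantom and its noisy ±60°, 2°-step tilt series
vol, ts, geom = standard_fixture("spheres-61tilt-pm60")
shape = vol.data.shape
tr = build_transforms(ts.angles_deg, geom, shape, ts.det_shape)

# SIRT on 4 slabs — identical to the whole-volume run at zero pitch
params = ReconstructionParams(method="SIRT", n_iters=30)
rec = run_sliced(ts, tr, shape, params, plan_slabs(shape[1], 4, geom))
print("corr(SIRT, truth) =", round(np.corrcoef(
    rec.data.ravel(), vol.data.ravel())[0, 1], 3))

# half-set FRC of FBP reconstructions
even, odd = even_odd_split(ts)
spec = FilterSpec(kind="ramp")
ve = fbp(even, build_transforms(even.angles_deg, geom, shape, even.det_shape), shape, spec)
vo = fbp(odd, build_transforms(odd.angles_deg, geom, shape, odd.det_shape), shape, spec)
print("FRC_0.143 crossing =", round(frc(ve, vo).resolution_freq, 3), "cycles/voxel")
```

prints

```
corr(SIRT, truth) = 0.81
FRC_0.143 crossing = 0.354 cycles/voxel
```

i.e. 30 SIRT iterations recover the phantom up to the missing-wedge
anisotropy and noise (correlation 0.81 with the ground truth), and the
two half-set reconstructions stay correlated out to ~0.35 cycles/voxel
at the 0.143 threshold.

The same pipeline is available from the shell:

```sh
tomoslab -i ts.st -a ts.tlt -o out.mrc -m SIRT --iters 30 --thickness 100 --workers 4
tomoslab-frc even.mrc odd.mrc -o curve.tsv
```

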