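# Methods

## Model and assumptions

The reconstruction treats the eye as a body of revolution about the
anteroposterior axis (corneal apex → posterior pole). This is an
anatomical simplification — the optic nerve head, ciliary detail and any
left/right asymmetry are averaged away — but it is a serviceable first
approximation for a globe, and it lets a single artifact-free sagittal
section stand in for a full serial-section stack. The input section must
therefore be prepared so the assumption holds:

1. **Orientation** — the apex–pole segment is rotated vertical, apex up
   (`align_axes`, bilinear resampling, white fill).
2. **Cavity clearing** — the anterior chamber and vitreous are set to
   white with an explicit mask or a seeded flood fill (tolerance 10 per
   channel), since loose debris in the cavities would otherwise smear
   into rings during rotation.
3. **Symmetrization** — one half of the image (default left) is mirrored
   about the vertical center line (`symmetrize`). For odd width the
   center column belongs to the kept half and is not duplicated; for
   even width the split is at `W/2`.
4. **Down-sampling** — images taller than the 300-pixel working size are
   resampled (bilinear) with aspect ratio preserved; smaller images are
   never up-sampled. 300 px keeps the sweep's voxel count (and the
   resulting cloud) in the range external meshing tools handle well.

White (all channels ≥ 250, tunable) is the external background
convention; before rotation it is mapped to the black sentinel (0,0,0),
which is what an unwritten voxel also holds.

## Rotational voxelization

For axis column `c = floor(W/2)` (0-based; a deliberately symmetric
convention) and angle α, column `j` projects to

    x = round(cos α · (j − c)) + c,   z = round(sin α · (j − c)) + c,

with round-half-away-from-zero. Banker's rounding is rejected because it
would thin alternate shells asymmetrically. The volume is allocated
`H × D × D` with `D = W + 1`, provably sufficient since
`|round(t)| ≤ ceil(W/2)` for `|t| ≤ W/2`.

- **Angle grid**: `lo, lo+step, …, hi` with both endpoints included;
  the reference grid 0:0.2:180 has 901 angles, so a 300 × 300 section
  costs 300·300·901 = 81,090,000 projection evaluations. α = 0 and
  α = 180 write mirror-identical content for a symmetric section, which
  is harmless. Coarse steps (5–20°) are for previews; at 0.2° the arc
  spacing at the maximal radius of a 300-px section is < 1 voxel, so the
  shell closes without hole filling.
- **Collision policy**: last-writer-wins in row-major pixel order, then
  ascending angle; no blending. The vectorized implementation scatters
  each tissue pixel's color along its rotation circle in ascending
  column order, which reproduces that order exactly (within one pixel
  all angles write one color, so angle order is immaterial); a naive
  triple-loop reference implementation is kept and the two are asserted
  equal on collision-heavy random inputs.
- **Background pixels are not splatted.** Writing them would be a no-op
  into the zero-filled volume except where rounding collides a
  background pixel with already-written tissue — and there it would
  punch spurious holes in the shell, violating step-refinement
  monotonicity and the volume's rotational symmetry. Skipping them
  preserves both properties; the black sentinel simply remains wherever
  no tissue lands.

## Virtual stack and point cloud

Slices are the planes `z = k`. Only `k ≤ c` is computed; the rest is
filled by the mirror identity `slice[D−1−k] = slice[k]`, which both
halves the work and removes residual splatting asymmetry. On disk the
slices are numbered 1-based (`stack_pic1.png`, …) with a JSON manifest;
mirrored indices therefore hold byte-identical files. PNG is the default
format — JPEG blocks would leak mid-range values through the bandpass —
with JPEG available for fidelity runs. `eliminate_black` then turns
exact-zero pixels white for viewing; tissue as dark as (1,0,0) is
untouched.

The cloud keeps a voxel iff its red channel satisfies `5 < R < 230`
(both strict; channel and thresholds configurable). H&E tissue is
reliably mid-range in red, while sentinel black (0) and cleared white
(255) both fail. `rotation="half"` scans slices `z < floor(D/2)` (the
mirror-complete stack makes the rest redundant); `"full"` scans all.
Points carry `x = row, y = column, z = slice` and full RGB; each voxel
is visited once, so clouds are duplicate-free. The volume route
(`volume_to_cloud`) applies the same mirror-fill convention and is
asserted identical to the stack route. PLY (ascii or binary little
endian; float32 coordinates, uchar colors) and ascii PCD v0.7 (rgb
packed 0xRRGGBB as an unsigned field) writers are self-contained;
round trips are exact and the PLY is cross-checked against an
independent reader in the tests.

## Biometry and shrinkage

The packaged table transcribes per-species in-vivo and post-histology
means ± SD (mm for corneal diameter and axial length, μm for central
retinal thickness; mouse n = 5, rat n = 4, rabbit n = 3). The shrinkage
factor is `measured_mean / in_vivo_mean`, rounded half-away-from-zero to
3 decimals; the factors are always recomputed from the means, never
stored. One transcription note: the rabbit central-retinal entry
recomputes to 0.825 (160.39/194.30 = 0.8255), one ulp below the commonly
quoted 0.826; the recomputed value is treated as authoritative. The rat
in-vivo corneal diameter carries a literal 0.0 SD in its source and is
transcribed as-is.

Correction is **isotropic**: model scale is divided by one user-chosen
factor (`scale_to_invivo`), although measured shrinkage differs between
parameters (e.g. rat axial 0.816 vs corneal 0.873) — no anisotropic
model is attempted because the section plane confounds radial and axial
shrinkage. Retinal thickness averaging enforces the sampling protocol:
exactly six positions within 0.6 mm of the optic nerve head for mouse
and rat, 3.0 mm for rabbit; SD uses the n−1 denominator.

## Serial-stack registration

`align_serial_stack` registers conventional physical stacks to the
middle slice by closed-form moment matching: tissue-mask centroids give
the translation, principal axes (second central moments, angle taken in
(−90°, 90°] with the smaller turn chosen, since the axis is defined
modulo 180°) give the rotation, and the square root of the area ratio
gives the isotropic scale. This is intentionally global and
intensity-free: it removes mounting error but cannot repair local
distortion, which is precisely the failure mode that motivates the
rotational route.

## Phantom and what the tests show

The phantom renders a scleral annulus, retinal lining, lens disc and
corneal cap as piecewise-constant, mirror-symmetric regions with
per-layer ground-truth masks; all layer reds lie strictly inside the
default bandpass. Flat colors are deliberate — they give closed-form
expectations (per-layer pixel counts, the brute-force annulus voxel
oracle `expected_annulus_voxels`, exact color recovery in the cloud). A
seeded speckle mode perturbs colors within the band for robustness
tests without changing which voxels pass. The phantom does **not**
emulate H&E texture, stain gradients, section artifacts or asymmetric
anatomy, so green tests demonstrate geometric and numerical correctness
of the pipeline, not segmentation robustness on real stains.

Rotated tissue runs are required to match the annulus oracle within 5% —
the slack covers forward-splatting rounding at the run boundaries and is
a fixed test constant, not a tuning knob.

## Problem sizes and tolerances

The test suite exercises full resolution where the reference quantities
demand it (one 300-px reconstruction at 0.2°, ~15 s) and 41–61-px
phantoms elsewhere; the whole suite runs in well under a minute.
Determinism is byte-level: a fixed phantom seed reproduces identical
binary PLY output. Registration recovery tolerances are 0.5 px for
translation and 2% for scale; calibration must recover in-vivo lengths
within 0.5%.

## Known limitations

- Rotational symmetry erases the optic nerve head and any true
  asymmetry; the model is an individual post-mortem eye, not a species
  atlas.
- Forward splatting with nearest-voxel rounding leaves unhit voxels at
  large radii for coarse angle steps; no hole filling is performed
  (a finer step is the intended remedy).
- Shrinkage correction is isotropic and linear; differential shrinkage
  between tissues is not modeled.
- Surface meshing (normals from ~100 neighbors, screened Poisson,
  Laplacian smoothing) and VR scene assembly are delegated to external
  tools via the PLY/PCD export.
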