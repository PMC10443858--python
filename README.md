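# eye3d

Pseudorealistic, rotationally symmetric 3D reconstruction of vertebrate
eyes from a **single sagittal histological section**.

Conventional serial-section 3D reconstruction of whole eyes suffers from
per-slice artifacts (tissue folds, retinal detachments, globe
deformation) that survive even careful registration. `eye3d` takes the
complementary route: it treats the eye as a body of revolution, sweeps
one clean, symmetrized sagittal section around the apex–pole axis, and
produces

- an RGB **voxel volume** of the whole globe,
- a **virtual serial-section stack** (parallel slice images, as if the
  volume had been re-sectioned),
- a colored **point cloud** (PLY / PCD) ready for external surface
  meshing (normal estimation, screened Poisson reconstruction, Laplacian
  smoothing) and import into VR surgical-simulation platforms,
- **biometric shrinkage calibration** that rescales the model from
  post-histology to in-vivo dimensions.

It is aimed at vision researchers, ocular-implant designers and
surgical-simulation developers working with mouse, rat and rabbit eyes
(any species works if you supply its biometry).

## The model

Each pixel `(i, j)` of the prepared section keeps its row `i` (position
along the symmetry axis) and is projected, for rotation angle α, to
transverse voxel coordinates

```
x = round(cos α · (j − c)) + c
z = round(sin α · (j − c)) + c
```

where `c` is the axis column and `round` is round-half-away-from-zero.
Sweeping α over [0°, 180°] in 0.2° steps fills an `H × D × D` volume
(`D = W + 1`); a 300 × 300 section is projected
300 · 300 · 901 = 81,090,000 times. Tissue voxels are then selected by a
strict red-channel bandpass `5 < R < 230`, which rejects both the black
empty-space sentinel and cleared white regions while keeping H&E-stained
tissue.

Shrinkage calibration uses the factor
`s = mean(post-histology) / mean(in-vivo)` per species and parameter;
dividing model coordinates (or the physical voxel size) by `s` restores
in-vivo dimensions. The packaged table covers corneal diameter, ocular
axial length and central retinal thickness for mouse, rat and rabbit.

## Worked example

```sh
python examples/reconstruct_phantom.py
```

runs the full pipeline on a built-in synthetic section (a phantom with
sclera, retina, lens and cornea layers of known geometry) at the
reference settings and prints:

```
rotation angles:        901
projection operations:  81,090,000
occupied voxels:        3,883,430
virtual slices:         301
cloud points (half):    1,929,718
```

901 angles are the inclusive 0.2° sweep of [0°, 180°]; every one of the
90,000 pixels is projected at every angle (81,090,000 evaluations); the
sweep occupies ~3.9 M voxels, sliced into 301 virtual sections; the red
bandpass keeps ~1.9 M colored points for meshing. The other examples
(`shrinkage_calibration.py`, `virtual_stack_and_cloud.py`,
`serial_stack_alignment.py`) demonstrate calibration, the stage-by-stage
API and serial-section registration.

The same pipeline is available as a CLI:

```sh
eye3d phantom --size 300 --out section.png
eye3d run --input section.png --out-dir out/           # full pipeline
eye3d calibrate --species mouse --parameter ocular_axial_length
eye3d scale --ply out/cloud.ply --factor 0.923 --out out/cloud_invivo.ply
```

Real sections enter through `eye3d prep` (orientation by apex/pole
landmarks, cavity clearing by mask, symmetrization, down-sampling to the
300-pixel working size).

## Layout

- `src/eye3d/section.py` — loading, orientation, cavity clearing,
  symmetrization, serial-stack registration
- `src/eye3d/voxelize.py` — the rotational sweep
- `src/eye3d/stack.py` — virtual slice stack I/O (mirrored naming)
- `src/eye3d/cloud.py` — bandpass extraction, PLY/PCD export
- `src/eye3d/biometry.py` — shrinkage factors and rescaling
- `src/eye3d/phantom.py` — synthetic sections with ground truth
- `src/eye3d/pipeline.py`, `src/eye3d/cli.py` — end-to-end runs

Surface meshing itself is deliberately out of scope: export the PLY and
follow the recipe in `docs/methods.md` (normals from ~100 neighbors,
screened Poisson, Laplacian smoothing) in MeshLab or any equivalent
tool.
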