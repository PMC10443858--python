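"""Step through the pipeline stage by stage on a small phantom.

Rotates a 61-pixel phantom section into a voxel volume, slices it into a
mirror-complete virtual stack, extracts the bandpass-filtered point cloud
along both routes (stack and volume), and writes PLY/PCD files.
"""

import tempfile
from pathlib import Path

import numpy as np

import eye3d

section, masks = eye3d.make_phantom_section(eye3d.PhantomSpec.default(61), seed=7)
print(f"section: {section.shape[0]}x{section.shape[1]}, "
      f"{int(eye3d.tissue_mask(section).sum())} tissue pixels, "
      f"layers: {', '.join(masks)}")

volume = eye3d.rotate_section(section)  # 0.2 deg steps over [0, 180]
print(f"volume:  {volume.grid.shape[0]}x{volume.depth}x{volume.depth}, "
      f"{volume.occupied_count():,} occupied voxels")

stack = eye3d.clean_stack(eye3d.volume_to_stack(volume))
k = volume.center
mirror_ok = np.array_equal(stack.slices[k - 10], stack.slices[stack.count - 1 - (k - 10)])
print(f"stack:   {stack.count} virtual slices; mirror identity holds: {mirror_ok}")

cloud = eye3d.stack_to_cloud(stack, eye3d.BandpassFilter(), rotation="half")
via_volume = eye3d.volume_to_cloud(volume)
print(f"cloud:   {cloud.count:,} points (half rotation), "
      f"{via_volume.count:,} (full, via volume route)")

with tempfile.TemporaryDirectory() as tmp:
    ply = eye3d.write_ply(cloud, Path(tmp) / "eye.ply")
    pcd = eye3d.write_pcd(cloud, Path(tmp) / "eye.pcd")
    print(f"export:  {ply.stat().st_size:,} B binary PLY, "
          f"{pcd.stat().st_size:,} B ascii PCD")
    back = eye3d.read_ply(ply)
    print(f"round trip exact: {np.array_equal(back.points, cloud.points)}")
print()
print("The PLY feeds external meshing (normal estimation with ~100 neighbors,")
print("screened Poisson reconstruction, Laplacian smoothing) for VR platforms.")
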