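"""Reconstruct a full 3D eye model from one synthetic sagittal section.

Generates a 300x300 phantom section, runs the complete pipeline at the
reference settings (0.2 deg rotation steps over [0, 180], red bandpass
5/230) and prints the stage-by-stage counts from the run report.
"""

import json
import tempfile

import eye3d

with tempfile.TemporaryDirectory() as tmp:
    section, _ = eye3d.make_phantom_section(eye3d.PhantomSpec.default(300), seed=42)
    report = eye3d.run_pipeline(
        eye3d.RunConfig(out_dir=tmp, save_volume=False), section=section
    )

rot = report["stages"]["rotate"]
print(f"rotation angles:        {rot['angles']}")
print(f"projection operations:  {rot['projection_operations']:,}")
print(f"occupied voxels:        {report['stages']['stack']['occupied_voxels']:,}")
print(f"virtual slices:         {report['stages']['stack']['slices']}")
print(f"cloud points (half):    {report['stages']['cloud']['points']:,}")
print()
print("A 300x300 section swept in 0.2 deg steps is projected 81,090,000 times")
print("(300*300 pixels x 901 angles); the surviving in-band voxels form the")
print("colored point cloud exported as cloud.ply / cloud.pcd for meshing.")
print(json.dumps(report["parameters"], indent=1))
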