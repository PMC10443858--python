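"""End-to-end reconstruction: section → volume → virtual stack → point cloud.

One call runs every stage in order with the reference parameterization
(0.2° steps over [0°, 180°], 300-pixel standard size, red bandpass 5/230)
and writes a machine-readable run report with the quantities each stage
produced — angle count, projection evaluations, occupied voxels, cloud
points — so a run is auditable and reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .biometry import ShrinkageFactor, scale_to_invivo
from .cloud import (
    BandpassFilter,
    stack_to_cloud,
    write_pcd,
    write_ply,
)
from .errors import Eye3DError
from .section import (
    SectionImage,
    align_axes,
    clear_regions,
    load_section,
    save_section,
    standardize_size,
    symmetrize,
    white_to_black,
)
from .stack import clean_stack, volume_to_stack, write_stack
from .voxelize import (
    RotationConfig,
    angle_grid,
    count_projection_operations,
    rotate_section,
)

log = logging.getLogger("eye3d")


@dataclass
class RunConfig:
    """Parameters of one end-to-end run; defaults are the reference settings."""

    out_dir: str | Path = "eye3d_out"
    input_path: str | Path | None = None  # None → caller supplies a SectionImage
    # preparation
    apex: tuple[float, float] | None = None
    pole: tuple[float, float] | None = None
    clear_mask: np.ndarray | None = None
    keep_side: str = "left"
    target_size: int = 300
    # rotation
    step_deg: float = 0.2
    range_deg: tuple[float, float] = (0.0, 180.0)
    # cloud
    bp_low: int = 5
    bp_high: int = 230
    bp_channel: int = 0
    rotation: str = "half"
    ply_encoding: str = "binary_little_endian"
    # calibration
    shrinkage: float | None = None  # divide coordinates' scale by this factor
    # bookkeeping
    save_volume: bool = True
    stack_format: str = "png"
    seed: int = 0

    def rotation_config(self) -> RotationConfig:
        return RotationConfig(step_deg=self.step_deg, range_deg=tuple(self.range_deg))

    def bandpass(self) -> BandpassFilter:
        return BandpassFilter(low=self.bp_low, high=self.bp_high, channel=self.bp_channel)


class StageError(Eye3DError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: RunConfig,
    section: SectionImage | None = None,
) -> dict:
    """Execute prep → rotate → stack → cloud → export and write the report.

    Returns the report dict.  On failure the partially written output
    directory is retained with a ``<stage>.partial`` marker naming the
    failed stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "parameters": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "clear_mask" and not isinstance(v, np.ndarray)
        },
        "stages": {},
    }
    stage = "prep"
    try:
        t0 = time.perf_counter()
        if section is None:
            if config.input_path is None:
                raise Eye3DError("neither an input path nor a section was given")
            section = load_section(config.input_path)
        if config.clear_mask is not None:
            section = clear_regions(section, config.clear_mask)
        if config.apex is not None and config.pole is not None:
            section = align_axes(section, config.apex, config.pole)
        section = symmetrize(section, keep_side=config.keep_side)
        section = standardize_size(section, target=config.target_size)
        save_section(section, out_dir / "prepped.png")
        report["stages"]["prep"] = {
            "height": section.shape[0],
            "width": section.shape[1],
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }

        stage = "rotate"
        t0 = time.perf_counter()
        rc = config.rotation_config()
        prepped = white_to_black(section)
        vol = rotate_section(prepped, rc, assume_black_background=True)
        h, w = prepped.shape
        n_angles = len(angle_grid(rc))
        if config.save_volume:
            tifffile.imwrite(out_dir / "volume.tif", vol.grid, compression="zlib")
        report["stages"]["rotate"] = {
            "angles": n_angles,
            "projection_operations": count_projection_operations(h, w, rc),
            "occupied_voxels": vol.occupied_count(),
            "depth": vol.depth,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }

        stage = "stack"
        t0 = time.perf_counter()
        raw_stack = volume_to_stack(vol)
        stack_occupied = int(
            sum((s.sum(axis=2, dtype=np.int64) > 0).sum() for s in raw_stack.slices)
        )
        stack = clean_stack(raw_stack)
        stack_dir = out_dir / "stack"
        files = write_stack(stack, stack_dir, fmt=config.stack_format)
        report["stages"]["stack"] = {
            "slices": stack.count,
            "occupied_voxels": stack_occupied,
            "directory": str(stack_dir),
            "files": len(files),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }

        stage = "cloud"
        t0 = time.perf_counter()
        cloud = stack_to_cloud(stack, config.bandpass(), rotation=config.rotation)
        if config.shrinkage is not None and vol.voxel_size_um is not None:
            corrected = scale_to_invivo(
                vol.voxel_size_um, ShrinkageFactor(value=config.shrinkage)
            )
            cloud = cloud.scaled(corrected)
            report["stages"]["calibration"] = {
                "shrinkage_factor": config.shrinkage,
                "voxel_size_um_corrected": corrected,
            }
        ply_path = write_ply(cloud, out_dir / "cloud.ply", encoding=config.ply_encoding)
        pcd_path = write_pcd(cloud, out_dir / "cloud.pcd")
        report["stages"]["cloud"] = {
            "points": cloud.count,
            "ply": str(ply_path),
            "pcd": str(pcd_path),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        (out_dir / f"{stage}.partial").write_text(f"failed in stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    occupied = report["stages"]["stack"]["occupied_voxels"]
    points = report["stages"]["cloud"]["points"]
    h = report["stages"]["prep"]["height"]
    d = report["stages"]["rotate"]["depth"]
    if not (points <= occupied <= h * d * d):
        raise Eye3DError(
            f"inconsistent report: points={points}, occupied={occupied}, H*D*D={h * d * d}"
        )
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1))
    log.info("pipeline complete: %d points from %d occupied voxels", points, occupied)
    return report
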