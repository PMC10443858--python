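"""Virtual serial sections: slicing the voxel volume into an image stack.

A physical microtome produces parallel slices; here the same product is
computed from the rotated volume by taking planes perpendicular to the
transverse z axis.  Because the volume is rotationally symmetric only the
first half of the planes needs computing — plane ``D-1-k`` is plane ``k``
mirrored — and the on-disk naming duplicates each computed slice under
both indices, so viewers see a complete stack.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError, ValidationError
from .voxelize import VoxelVolume

DEFAULT_BASENAME = "stack_pic"


@dataclass
class VirtualStack:
    """Ordered sequence of 2D RGB slices through the reconstructed volume.

    ``slices[k]`` is the plane ``z = k`` of the source volume; all slices
    share one shape.  ``basename`` is the file-name stem used on disk.
    """

    slices: list[np.ndarray]
    basename: str = DEFAULT_BASENAME
    voxel_size_um: float | None = None
    computed_half: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValidationError("stack must contain at least one slice")
        shape = self.slices[0].shape
        for k, s in enumerate(self.slices):
            if s.shape != shape:
                raise ValidationError(
                    f"slice {k} shape {s.shape} differs from slice 0 shape {shape}"
                )

    @property
    def count(self) -> int:
        return len(self.slices)

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices[0].shape[:2]


def volume_to_stack(vol: VoxelVolume, basename: str = DEFAULT_BASENAME) -> VirtualStack:
    """Slice the volume along z, computing only the first half explicitly.

    Planes ``k <= c`` (the axis index) are read from the volume; the
    remainder is filled by the mirror identity ``slice[D-1-k] = slice[k]``.
    For a symmetric input the mirrored planes equal the volume's own
    within splatting tolerance, and forcing exact equality removes the
    residual rounding asymmetry.
    """
    d = vol.depth
    c = vol.center
    slices: list[np.ndarray | None] = [None] * d
    for k in range(c + 1):
        slices[k] = np.ascontiguousarray(vol.grid[:, :, k, :])
    for k in range(d):
        if slices[k] is None:
            slices[k] = slices[d - 1 - k]
    return VirtualStack(
        slices=[s.copy() for s in slices],  # type: ignore[union-attr]
        basename=basename,
        voxel_size_um=vol.voxel_size_um,
        computed_half=True,
    )


def eliminate_black(slice_img: np.ndarray) -> np.ndarray:
    """Turn fully black pixels white; leave every other pixel untouched.

    The voxelizer's empty-space sentinel is (0,0,0); for viewing and for
    the downstream bandpass the background must be white again.  Only
    pixels whose channel sum is exactly zero are affected, so very dark
    tissue (e.g. (1,0,0)) survives.
    """
    out = np.asarray(slice_img).copy()
    black = out.sum(axis=2, dtype=np.int64) == 0
    out[black] = 255
    return out


def clean_stack(stack: VirtualStack) -> VirtualStack:
    """Apply :func:`eliminate_black` to every slice."""
    return VirtualStack(
        slices=[eliminate_black(s) for s in stack.slices],
        basename=stack.basename,
        voxel_size_um=stack.voxel_size_um,
        computed_half=stack.computed_half,
    )


def _slice_name(basename: str, index1: int, ext: str, padded_width: int = 0) -> str:
    num = str(index1).zfill(padded_width) if padded_width else str(index1)
    return f"{basename}{num}.{ext}"


def write_stack(
    stack: VirtualStack,
    directory,
    fmt: str = "png",
    padded: bool = False,
) -> list[Path]:
    """Write all slices as numbered images plus a JSON manifest.

    File indices are 1-based with no zero padding by default (``padded``
    switches to fixed-width indices for tools that sort lexically).  PNG
    is the default because it is lossless: JPEG artifacts would leak
    through the color bandpass downstream.
    """
    if fmt not in ("png", "jpeg"):
        raise ValidationError(f"format must be 'png' or 'jpeg', got {fmt!r}")
    ext = "png" if fmt == "png" else "jpg"
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create stack directory {directory}: {exc}") from exc
    n = stack.count
    width = len(str(n)) if padded else 0
    paths: list[Path] = []
    for k, s in enumerate(stack.slices):
        name = _slice_name(stack.basename, k + 1, ext, width)
        path = directory / name
        try:
            Image.fromarray(s, mode="RGB").save(path)
        except OSError as exc:
            raise InputError(f"cannot write slice {path}: {exc}") from exc
        paths.append(path)
    manifest = {
        "basename": stack.basename,
        "count": n,
        "format": fmt,
        "voxel_size_um": stack.voxel_size_um,
        "files": [p.name for p in paths],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths


def read_stack(directory, basename: str = DEFAULT_BASENAME) -> VirtualStack:
    """Read a numbered slice sequence ``{basename}{1..N}.{ext}`` back in.

    The numeric sequence must be gapless and all slices must share one
    shape; violations raise :class:`ValidationError` naming the problem.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"stack directory not found: {directory}")
    pattern = re.compile(re.escape(basename) + r"(\d+)\.(png|jpg|jpeg|tif|tiff)$")
    found: dict[int, Path] = {}
    for p in directory.iterdir():
        m = pattern.fullmatch(p.name)
        if m:
            found[int(m.group(1))] = p
    if not found:
        raise InputError(f"no {basename}* slices in {directory}")
    n = max(found)
    missing = [i for i in range(1, n + 1) if i not in found]
    if missing:
        raise ValidationError(
            f"stack sequence has gaps: missing index {missing[0]} "
            f"(expected {basename}{missing[0]})"
        )
    slices = []
    voxel_size = None
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        voxel_size = json.loads(manifest_path.read_text()).get("voxel_size_um")
    for i in range(1, n + 1):
        arr = np.asarray(Image.open(found[i]).convert("RGB"), dtype=np.uint8)
        if slices and arr.shape != slices[0].shape:
            raise ValidationError(
                f"slice {i} shape {arr.shape[:2]} differs from slice 1 "
                f"shape {slices[0].shape[:2]}"
            )
        slices.append(arr)
    return VirtualStack(slices=slices, basename=basename, voxel_size_um=voxel_size)
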