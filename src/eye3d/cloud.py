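"""Colored point-cloud extraction and PLY/PCD export.

Tissue voxels are selected by a strict bandpass on one color channel:
H&E-stained tissue is reliably mid-range in red, while the black empty
sentinel (0) and cleared white space (255) both fall outside the band.
The surviving voxels become a list of (x, y, z) points with their full
RGB color — the input expected by external meshing tools (normal
estimation, screened Poisson reconstruction, Laplacian smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .stack import VirtualStack
from .voxelize import VoxelVolume
import warnings


@dataclass(frozen=True)
class BandpassFilter:
    """Strict per-channel intensity window selecting tissue voxels.

    A voxel passes iff ``low < value(channel) < high`` (both strict); the
    defaults (5, 230) on the red channel reject black background and
    white cleared space while keeping stained tissue.
    """

    low: int = 5
    high: int = 230
    channel: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 255):
            raise ValidationError(
                f"need 0 <= low < high <= 255, got low={self.low}, high={self.high}"
            )
        if self.channel not in (0, 1, 2):
            raise ValidationError(f"channel must be 0, 1 or 2, got {self.channel}")


@dataclass
class PointCloud:
    """Unordered colored 3D points in voxel units (or micrometers if scaled).

    ``points`` is float32 ``(N, 3)``; ``colors`` is uint8 ``(N, 3)``.
    Coordinate convention: x = volume row, y = volume column, z = slice
    index, matching the extraction loop order.
    """

    points: np.ndarray
    colors: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float32).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
        if len(self.points) != len(self.colors):
            raise ValidationError(
                f"points ({len(self.points)}) and colors ({len(self.colors)}) "
                "must have equal length"
            )

    @property
    def count(self) -> int:
        return len(self.points)

    def scaled(self, unit_um: float) -> "PointCloud":
        """Coordinates multiplied by the physical voxel edge length."""
        if unit_um <= 0:
            raise ValidationError("unit_um must be positive")
        return PointCloud(self.points * np.float32(unit_um), self.colors.copy())


def bandpass_includes(rgb, filt: BandpassFilter = BandpassFilter()) -> bool:
    """True iff the tested channel lies strictly inside the band."""
    v = int(np.asarray(rgb).reshape(3)[filt.channel])
    return filt.low < v < filt.high


def _collect_slice(
    slice_img: np.ndarray, z: int, filt: BandpassFilter
) -> tuple[np.ndarray, np.ndarray]:
    """In-band points of one slice, ordered column-major (x fastest)."""
    chan = slice_img[:, :, filt.channel]
    mask = (chan > filt.low) & (chan < filt.high)
    ys, xs = np.nonzero(mask.T)
    pts = np.empty((len(xs), 3), dtype=np.float32)
    pts[:, 0] = xs
    pts[:, 1] = ys
    pts[:, 2] = z
    return pts, slice_img[xs, ys]


def stack_to_cloud(
    stack: VirtualStack,
    filt: BandpassFilter = BandpassFilter(),
    rotation: str = "half",
) -> PointCloud:
    """Extract the colored cloud from a virtual stack.

    ``rotation='half'`` scans slices ``z in [0, floor(D/2))`` — enough for
    180° of a mirror-complete stack; ``'full'`` scans every slice.  Each
    voxel is visited once, so the cloud is duplicate-free.
    """
    if rotation not in ("half", "full"):
        raise ValidationError(f"rotation must be 'half' or 'full', got {rotation!r}")
    n = stack.count if rotation == "full" else stack.count // 2
    parts = [_collect_slice(stack.slices[z], z, filt) for z in range(n)]
    return _assemble(parts)


def volume_to_cloud(
    vol: VoxelVolume,
    filt: BandpassFilter = BandpassFilter(),
) -> PointCloud:
    """Extract the full-rotation cloud directly from a voxel volume.

    Uses the same mirror-fill convention as the stack route (plane
    ``D-1-k`` is plane ``k`` mirrored), so the result is identical to
    materializing the full stack and extracting with ``rotation='full'``.
    """
    d = vol.depth
    c = vol.center
    parts = []
    for z in range(d):
        k = z if z <= c else d - 1 - z
        parts.append(_collect_slice(vol.grid[:, :, k, :], z, filt))
    return _assemble(parts)


def _assemble(parts) -> PointCloud:
    pts = np.concatenate([p for p, _ in parts]) if parts else np.empty((0, 3), np.float32)
    cols = np.concatenate([c for _, c in parts]) if parts else np.empty((0, 3), np.uint8)
    if len(pts) == 0:
        warnings.warn("bandpass selected no voxels; cloud is empty")
    return PointCloud(pts, cols)


# ---------------------------------------------------------------------------
# PLY

_PLY_DTYPE = np.dtype(
    [
        ("x", "<f4"),
        ("y", "<f4"),
        ("z", "<f4"),
        ("red", "u1"),
        ("green", "u1"),
        ("blue", "u1"),
    ]
)


def _ply_records(cloud: PointCloud) -> np.ndarray:
    rec = np.empty(cloud.count, dtype=_PLY_DTYPE)
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    rec["red"], rec["green"], rec["blue"] = cloud.colors.T
    return rec


def write_ply(cloud: PointCloud, path, encoding: str = "binary_little_endian") -> Path:
    """Write the cloud as a PLY vertex list (float32 xyz, uchar rgb)."""
    if encoding not in ("ascii", "binary_little_endian"):
        raise ValidationError(f"unsupported PLY encoding {encoding!r}")
    path = Path(path)
    header = (
        "ply\n"
        f"format {encoding} 1.0\n"
        "comment generated by eye3d (x=row, y=column, z=slice)\n"
        f"element vertex {cloud.count}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "property uchar red\n"
        "property uchar green\n"
        "property uchar blue\n"
        "end_header\n"
    )
    rec = _ply_records(cloud)
    try:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            if encoding == "binary_little_endian":
                fh.write(rec.tobytes())
            else:
                for r in rec:
                    fh.write(
                        f"{r['x']:.6g} {r['y']:.6g} {r['z']:.6g} "
                        f"{r['red']} {r['green']} {r['blue']}\n".encode("ascii")
                    )
    except OSError as exc:
        raise InputError(f"cannot write PLY {path}: {exc}") from exc
    return path


def read_ply(path) -> PointCloud:
    """Read back a PLY vertex cloud written by :func:`write_ply`.

    Supports the two dialects this package emits (ascii and
    binary_little_endian with the x/y/z/red/green/blue layout).
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise InputError(f"cannot read PLY {path}: {exc}") from exc
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise ValidationError(f"{path} is not a PLY file")
    header = raw[:end].decode("ascii").splitlines()
    body = raw[end + len(b"end_header\n"):]
    encoding = None
    count = None
    props: list[str] = []
    for line in header:
        parts = line.split()
        if parts[:1] == ["format"]:
            encoding = parts[1]
        elif parts[:2] == ["element", "vertex"]:
            count = int(parts[2])
        elif parts[:1] == ["property"] and count is not None:
            props.append(parts[2])
    if count is None or encoding is None:
        raise ValidationError(f"{path}: malformed PLY header")
    if props != ["x", "y", "z", "red", "green", "blue"]:
        raise ValidationError(f"{path}: unsupported vertex layout {props}")
    if encoding == "binary_little_endian":
        rec = np.frombuffer(body, dtype=_PLY_DTYPE, count=count)
    elif encoding == "ascii":
        rows = body.decode("ascii").split()
        arr = np.array(rows, dtype=np.float64).reshape(count, 6) if count else np.empty((0, 6))
        rec = np.empty(count, dtype=_PLY_DTYPE)
        rec["x"], rec["y"], rec["z"] = arr[:, 0], arr[:, 1], arr[:, 2]
        rec["red"], rec["green"], rec["blue"] = arr[:, 3], arr[:, 4], arr[:, 5]
    else:
        raise ValidationError(f"{path}: unsupported encoding {encoding}")
    pts = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(np.float32)
    cols = np.stack([rec["red"], rec["green"], rec["blue"]], axis=1).astype(np.uint8)
    return PointCloud(pts, cols)


# ---------------------------------------------------------------------------
# PCD

def pack_rgb(colors: np.ndarray) -> np.ndarray:
    """Pack uint8 (N,3) colors into one unsigned integer per point (0xRRGGBB)."""
    c = np.asarray(colors, dtype=np.uint32)
    return (c[:, 0] << 16) | (c[:, 1] << 8) | c[:, 2]


def unpack_rgb(packed) -> np.ndarray:
    """Inverse of :func:`pack_rgb`."""
    p = np.asarray(packed, dtype=np.uint32)
    return np.stack([(p >> 16) & 255, (p >> 8) & 255, p & 255], axis=-1).astype(np.uint8)


def write_pcd(cloud: PointCloud, path) -> Path:
    """Write an ASCII PCD v0.7 file with FIELDS x y z rgb (rgb packed)."""
    path = Path(path)
    n = cloud.count
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        "FIELDS x y z rgb\n"
        "SIZE 4 4 4 4\n"
        "TYPE F F F U\n"
        "COUNT 1 1 1 1\n"
        f"WIDTH {n}\n"
        "HEIGHT 1\n"
        "VIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {n}\n"
        "DATA ascii\n"
    )
    packed = pack_rgb(cloud.colors)
    df = pd.DataFrame(
        {
            "x": cloud.points[:, 0],
            "y": cloud.points[:, 1],
            "z": cloud.points[:, 2],
            "rgb": packed,
        }
    )
    try:
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write(header)
            df.to_csv(fh, sep=" ", header=False, index=False, float_format="%.6g")
    except OSError as exc:
        raise InputError(f"cannot write PCD {path}: {exc}") from exc
    return path


def read_pcd(path) -> PointCloud:
    """Read back an ASCII PCD file written by :func:`write_pcd`."""
    path = Path(path)
    try:
        lines = path.read_text(encoding="ascii").splitlines()
    except OSError as exc:
        raise InputError(f"cannot read PCD {path}: {exc}") from exc
    count = None
    data_start = None
    for i, line in enumerate(lines):
        if line.startswith("POINTS"):
            count = int(line.split()[1])
        elif line.startswith("DATA"):
            if line.split()[1] != "ascii":
                raise ValidationError(f"{path}: only ascii PCD is supported")
            data_start = i + 1
            break
    if count is None or data_start is None:
        raise ValidationError(f"{path}: malformed PCD header")
    pts = np.empty((count, 3), dtype=np.float32)
    cols = np.empty((count, 3), dtype=np.uint8)
    for k, line in enumerate(lines[data_start : data_start + count]):
        x, y, z, rgb = line.split()
        pts[k] = (float(x), float(y), float(z))
        cols[k] = unpack_rgb(int(rgb))
    return PointCloud(pts, cols)
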