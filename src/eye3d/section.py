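"""Preparation of a single sagittal whole-eye section for rotational reconstruction.

A section image enters the pipeline as an 8-bit RGB raster on a white
background (white = cleared / empty space, the convention of scanned
histology on a light table).  Before it can be rotated around the ocular
symmetry axis it has to be oriented (corneal apex up, posterior pole down),
cleaned (anterior chamber and vitreous cavity cleared to white),
symmetrized about the vertical center line, and down-sampled to a standard
working size.  This module implements those steps, plus a moments-based
rigid registration for conventional serial-section stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform as sktransform

from .errors import InputError, ValidationError

#: A pixel counts as white background iff every channel is >= this value.
WHITE_THRESHOLD = 250

WHITE = (255, 255, 255)

LANDMARK_NAMES = (
    "corneal_apex",
    "posterior_pole",
    "corneoscleral_junction_left",
    "corneoscleral_junction_right",
)


@dataclass
class SectionImage:
    """One sagittal whole-eye section.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.  White (255,255,255) denotes cleared or
        empty space.
    pixel_size_um
        Physical edge length of one pixel in micrometers, if known.
    landmarks
        Optional named ``(row, col)`` pixel coordinates, e.g.
        ``corneal_apex`` and ``posterior_pole``.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    landmarks: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"pixels must be (H, W, 3), got {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValidationError(f"image too small: {px.shape[0]}x{px.shape[1]}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        h, w = px.shape[:2]
        for name, (r, c) in self.landmarks.items():
            if not (0 <= r < h and 0 <= c < w):
                raise ValidationError(
                    f"landmark {name!r} at ({r}, {c}) outside {h}x{w} image"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def copy(self) -> "SectionImage":
        return SectionImage(
            self.pixels.copy(), self.pixel_size_um, dict(self.landmarks)
        )


def load_section(path) -> SectionImage:
    """Read a PNG/JPEG/TIFF raster into a :class:`SectionImage`.

    Grayscale inputs are promoted to RGB by channel replication; images
    with an alpha channel are composited over white before the alpha is
    dropped, so transparent margins become background.
    """
    try:
        im = Image.open(path)
        im.load()
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    if im.width == 0 or im.height == 0:
        raise ValidationError(f"zero-size image: {path!r}")
    if im.mode in ("RGBA", "LA", "PA") or (im.mode == "P" and "transparency" in im.info):
        im = im.convert("RGBA")
        bg = Image.new("RGBA", im.size, (255, 255, 255, 255))
        im = Image.alpha_composite(bg, im)
    im = im.convert("RGB")
    return SectionImage(np.asarray(im, dtype=np.uint8))


def save_section(img: SectionImage, path) -> None:
    """Write the section as an 8-bit RGB raster (format from suffix)."""
    Image.fromarray(img.pixels, mode="RGB").save(path)


def standardize_size(img: SectionImage, target: int = 300) -> SectionImage:
    """Down-sample so the vertical axis has ``target`` pixels.

    Aspect ratio is preserved: the new width is ``round(target * W / H)``.
    Images already at or below ``target`` rows are returned unchanged
    (no up-sampling).  ``pixel_size_um`` is rescaled by the resampling
    factor so physical dimensions are preserved.
    """
    if target < 2:
        raise ValidationError(f"target must be >= 2, got {target}")
    h, w = img.shape
    if h <= target:
        return img
    ar = h / w
    new_w = int(round(target / ar))
    out = sktransform.resize(
        img.pixels.astype(np.float64),
        (target, new_w),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    factor = h / target
    scale = None if img.pixel_size_um is None else img.pixel_size_um * factor
    lm = {
        name: (r / factor, c * new_w / w) for name, (r, c) in img.landmarks.items()
    }
    return SectionImage(np.clip(np.rint(out), 0, 255).astype(np.uint8), scale, lm)


def _rotation_about_center(shape: tuple[int, int], angle_deg: float):
    """Similarity transform rotating (col,row) points about the image center."""
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        sktransform.SimilarityTransform(translation=-center)
        + sktransform.SimilarityTransform(rotation=np.deg2rad(angle_deg))
        + sktransform.SimilarityTransform(translation=center)
    )
    return tf


def align_axes(
    img: SectionImage,
    apex: tuple[float, float],
    pole: tuple[float, float],
) -> SectionImage:
    """Rotate the section so the apex→pole segment is vertical, apex on top.

    ``apex`` and ``pole`` are ``(row, col)`` coordinates of the corneal apex
    and the posterior pole.  Rotation uses bilinear resampling with white
    fill; landmarks (including the two given points) are transformed along.
    """
    h, w = img.shape
    for name, (r, c) in (("apex", apex), ("pole", pole)):
        if not (0 <= r < h and 0 <= c < w):
            raise ValidationError(f"{name} at ({r}, {c}) outside image bounds")
    dr = pole[0] - apex[0]
    dc = pole[1] - apex[1]
    if dr == 0 and dc == 0:
        raise ValidationError("apex and pole coincide")
    # Current axis direction in (col,row)=(x,y) coordinates; want it at
    # +90 deg (pointing down the rows, i.e. apex above pole).
    angle = 90.0 - np.degrees(np.arctan2(dr, dc))
    tf = _rotation_about_center((h, w), angle)
    warped = sktransform.warp(
        img.pixels.astype(np.float64),
        tf.inverse,
        order=1,
        cval=255.0,
        mode="constant",
        preserve_range=True,
    )
    lm = dict(img.landmarks)
    lm.setdefault("corneal_apex", apex)
    lm.setdefault("posterior_pole", pole)
    new_lm = {}
    for name, (r, c) in lm.items():
        x, y = tf([[c, r]])[0]
        if 0 <= y < h and 0 <= x < w:
            new_lm[name] = (float(y), float(x))
    return SectionImage(
        np.clip(np.rint(warped), 0, 255).astype(np.uint8),
        img.pixel_size_um,
        new_lm,
    )


def clear_regions(img: SectionImage, mask: np.ndarray) -> SectionImage:
    """Set masked pixels to white (cleared); leave everything else alone.

    Stands in for the manual eraser step that empties the anterior chamber
    and the vitreous cavity before rotation.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match image shape {img.shape}"
        )
    out = img.pixels.copy()
    out[mask] = 255
    return replace(img.copy(), pixels=out)


def flood_mask(
    img: SectionImage, seed: tuple[int, int], tolerance: int = 10
) -> np.ndarray:
    """Boolean mask of the connected region around ``seed`` with near-uniform color.

    A pixel belongs to the region if every channel differs from the seed
    pixel's channel by at most ``tolerance`` and it is 4-connected to the
    seed through such pixels.  Convenience for clearing near-uniform
    cavities without interactive editing.
    """
    r, c = int(seed[0]), int(seed[1])
    h, w = img.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValidationError(f"seed ({r}, {c}) outside image bounds")
    ref = img.pixels[r, c].astype(np.int16)
    close = np.all(np.abs(img.pixels.astype(np.int16) - ref) <= tolerance, axis=2)
    labels, _ = ndimage.label(close)
    return labels == labels[r, c]


def symmetrize(img: SectionImage, keep_side: str = "left") -> SectionImage:
    """Mirror one half of the section about the vertical center line.

    Whole-eye sections are frequently asymmetric (the optic nerve head sits
    off-axis, one side is damaged); rotation requires a symmetric profile,
    so the kept half is duplicated, mirrored and substituted for the other
    half.  For odd width the center column belongs to the kept half and is
    not duplicated; for even width the split is at ``W/2``.  The output
    equals its own horizontal mirror.
    """
    if keep_side not in ("left", "right"):
        raise ValidationError(f"keep_side must be 'left' or 'right', got {keep_side!r}")
    px = img.pixels
    w = px.shape[1]
    out = px.copy()
    half = w // 2
    if keep_side == "left":
        left = px[:, :half]
        out[:, w - half :] = left[:, ::-1]
    else:
        right = px[:, w - half :]
        out[:, :half] = right[:, ::-1]
    return replace(img.copy(), pixels=out)


def tissue_mask(img: SectionImage, white_threshold: int = WHITE_THRESHOLD) -> np.ndarray:
    """Boolean mask of non-background pixels (any channel below the threshold)."""
    return ~np.all(img.pixels >= white_threshold, axis=2)


def white_to_black(img: SectionImage, white_threshold: int = WHITE_THRESHOLD) -> SectionImage:
    """Map white background to the black sentinel (0,0,0) used by the voxelizer.

    The rotation stage stores empty voxels as zeros; converting the white
    background up front makes a background pixel indistinguishable from an
    unwritten voxel, exactly as the reference procedure assumes.
    """
    out = img.pixels.copy()
    out[~tissue_mask(img, white_threshold)] = 0
    return replace(img.copy(), pixels=out)


@dataclass(frozen=True)
class SliceTransform:
    """Rigid + isotropic-scale registration parameters for one serial slice."""

    translation: tuple[float, float]  # (drow, dcol) applied to the slice
    rotation_deg: float
    scale: float

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.translation[0]) < 1e-6
            and abs(self.translation[1]) < 1e-6
            and abs(self.rotation_deg) < 1e-6
            and abs(self.scale - 1.0) < 1e-9
        )


def _moments(mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centroid (row,col), orientation (deg, in (-90,90]) and area of a mask."""
    ys, xs = np.nonzero(mask)
    area = float(len(ys))
    cy, cx = ys.mean(), xs.mean()
    y0, x0 = ys - cy, xs - cx
    mu20 = np.mean(x0 * x0)
    mu02 = np.mean(y0 * y0)
    mu11 = np.mean(x0 * y0)
    theta = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    return np.array([cy, cx]), theta, area


def align_serial_stack(
    images: list[SectionImage],
    white_threshold: int = WHITE_THRESHOLD,
) -> tuple[list[SectionImage], list[SliceTransform]]:
    """Rigidly register a conventional serial-section stack to its middle slice.

    Each slice's tissue mask is summarized by its centroid, principal-axis
    orientation and area; the slice is translated, rotated and isotropically
    scaled so these moments match the reference (middle) slice.  This is a
    deliberately simple global registration: it removes gross positioning
    error between physical sections but cannot correct local tissue
    distortion.

    Returns the registered images and the per-slice transform parameters.
    """
    if len(images) < 2:
        raise ValidationError("need at least 2 images to align a stack")
    masks = []
    for idx, img in enumerate(images):
        m = tissue_mask(img, white_threshold)
        if not m.any():
            raise ValidationError(f"slice {idx} is blank (no non-white pixels)")
        masks.append(m)
    ref_idx = len(images) // 2
    ref_centroid, ref_theta, ref_area = _moments(masks[ref_idx])
    out_images: list[SectionImage] = []
    out_tf: list[SliceTransform] = []
    for idx, img in enumerate(images):
        centroid, theta, area = _moments(masks[idx])
        scale = float(np.sqrt(ref_area / area))
        # Principal axis is defined modulo 180 deg; take the smaller turn.
        rot = ref_theta - theta
        if rot > 90.0:
            rot -= 180.0
        elif rot <= -90.0:
            rot += 180.0
        # Map (col,row) points: scale+rotate about the slice centroid, then
        # translate the centroid onto the reference centroid.
        cxy = centroid[::-1]
        tf = (
            sktransform.SimilarityTransform(translation=-cxy)
            + sktransform.SimilarityTransform(rotation=np.deg2rad(rot), scale=scale)
            + sktransform.SimilarityTransform(translation=ref_centroid[::-1])
        )
        warped = sktransform.warp(
            img.pixels.astype(np.float64),
            tf.inverse,
            order=1,
            cval=255.0,
            mode="constant",
            preserve_range=True,
        )
        out_images.append(
            replace(img.copy(), pixels=np.clip(np.rint(warped), 0, 255).astype(np.uint8))
        )
        out_tf.append(
            SliceTransform(
                translation=(
                    float(ref_centroid[0] - centroid[0]),
                    float(ref_centroid[1] - centroid[1]),
                ),
                rotation_deg=float(rot),
                scale=scale,
            )
        )
    return out_images, out_tf
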