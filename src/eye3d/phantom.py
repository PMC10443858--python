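"""Synthetic sagittal eye sections with exact ground truth.

The phantom emulates the geometry a prepared histological section shows —
a scleral shell, a retinal lining, a lens, a corneal cap, cleared (white)
anterior chamber and vitreous — as concentric piecewise-constant discs
and annuli, mirror-symmetric about the vertical center line.  Flat colors
are deliberate: they give every downstream stage (bandpass selection,
voxel counting, cloud extraction) a closed-form expectation.  A seeded
speckle mode perturbs colors within the bandpass for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .section import SectionImage

#: Default per-layer RGB colors; red components all pass the default
#: 5 < red < 230 bandpass.
DEFAULT_COLORS = {
    "sclera": (180, 120, 150),
    "retina": (120, 60, 140),
    "lens": (200, 160, 190),
    "cornea": (150, 130, 180),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic sagittal section, all lengths in pixels.

    The globe is a circle of radius ``globe_radius`` whose wall (sclera)
    is ``wall_thickness`` thick, lined inside by a retina of
    ``retina_thickness``.  The lens disc sits ``lens_offset`` rows
    anterior (negative = up) of the globe center; the corneal cap is the
    part of a ``cornea_radius`` circle protruding beyond the globe at the
    top.  Background is white (cleared space).
    """

    height: int = 300
    width: int = 300
    globe_radius: float = 120.0
    wall_thickness: float = 12.0
    retina_thickness: float = 10.0
    lens_radius: float = 45.0
    lens_offset: float = -35.0
    cornea_radius: float = 60.0
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))

    @classmethod
    def default(cls, size: int = 300) -> "PhantomSpec":
        """Proportionally scaled spec for a square ``size`` × ``size`` image."""
        s = size / 300.0
        # Globe plus corneal cap (cap height 0.4 * cornea radius, cornea
        # radius R/2) plus margins must fit the image height.
        globe_radius = min(120.0 * s, (size - 6) / 2.2)
        wall = max(2.0, globe_radius / 10.0)
        retina = max(2.0, globe_radius / 12.0)
        inner = globe_radius - wall - retina
        if inner <= 1:
            raise ValidationError(f"size {size} too small for a default phantom")
        # At small sizes the minimum wall/retina thicknesses eat into the
        # cavity; pull the lens toward the center and shrink it to fit.
        offset = -min(35.0 * s, inner / 3.0)
        lens_radius = min(45.0 * s, inner + offset - 1.0)
        return cls(
            height=size,
            width=size,
            globe_radius=globe_radius,
            wall_thickness=wall,
            retina_thickness=retina,
            lens_radius=lens_radius,
            lens_offset=offset,
            cornea_radius=globe_radius / 2.0,
        )


def _validate(spec: PhantomSpec) -> tuple[float, float, float]:
    """Check nesting/fit; return (globe_center_row, center_col, cornea_center_row)."""
    h, w = spec.height, spec.width
    r = spec.globe_radius
    inner = r - spec.wall_thickness - spec.retina_thickness
    if spec.wall_thickness <= 0 or spec.retina_thickness < 0:
        raise ValidationError("wall_thickness must be positive, retina_thickness >= 0")
    if inner <= 0:
        raise ValidationError("wall + retina exceed the globe radius")
    if abs(spec.lens_offset) + spec.lens_radius > inner:
        raise ValidationError("lens does not fit inside the vitreous cavity")
    cornea_center_row_rel = -r + 0.6 * spec.cornea_radius  # relative to globe center
    cap_top = cornea_center_row_rel - spec.cornea_radius
    cy = -cap_top + 2.0  # 2 px white margin above the corneal apex
    if cy + r >= h - 1:
        raise ValidationError(
            f"globe (radius {r}) does not fit a {h}-row image with its corneal cap"
        )
    if (w - 1) / 2.0 - r < 1:
        raise ValidationError(f"globe (radius {r}) does not fit a {w}-column image")
    return cy, (w - 1) / 2.0, cy + cornea_center_row_rel


def make_phantom_section(
    spec: PhantomSpec | None = None,
    seed: int = 0,
    noise: int = 0,
    bandpass_bounds: tuple[int, int] = (5, 230),
) -> tuple[SectionImage, dict[str, np.ndarray]]:
    """Render the phantom and its per-layer ground-truth masks.

    ``noise`` adds seeded uniform speckle of up to ± that many intensity
    levels per channel to tissue pixels; the tested (red) channel is
    clipped to stay strictly inside ``bandpass_bounds`` so speckle never
    changes which voxels the bandpass selects.  The rendered image equals
    its own horizontal mirror by construction.
    """
    spec = spec or PhantomSpec()
    cy, cx, cornea_cy = _validate(spec)
    h, w = spec.height, spec.width
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    d_globe = np.hypot(rows - cy, cols - cx)
    d_lens = np.hypot(rows - (cy + spec.lens_offset), cols - cx)
    d_cornea = np.hypot(rows - cornea_cy, cols - cx)

    r = spec.globe_radius
    r_in_sclera = r - spec.wall_thickness
    r_in_retina = r_in_sclera - spec.retina_thickness
    masks = {
        "sclera": (d_globe <= r) & (d_globe > r_in_sclera),
        "retina": (d_globe <= r_in_sclera) & (d_globe > r_in_retina),
        "lens": d_lens <= spec.lens_radius,
        "cornea": (d_cornea <= spec.cornea_radius) & (d_globe > r),
    }
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    for layer, mask in masks.items():
        img[mask] = spec.colors[layer]

    if noise > 0:
        rng = np.random.default_rng(seed)
        tissue = np.zeros((h, w), dtype=bool)
        for m in masks.values():
            tissue |= m
        idx = np.nonzero(tissue)
        speckle = rng.integers(-noise, noise + 1, size=(len(idx[0]), 3))
        vals = img[idx].astype(np.int16) + speckle
        vals[:, 1:] = np.clip(vals[:, 1:], 0, 255)
        lo, hi = bandpass_bounds
        vals[:, 0] = np.clip(vals[:, 0], lo + 1, hi - 1)
        img[idx] = vals.astype(np.uint8)

    return SectionImage(img), masks


def expected_annulus_voxels(inner_r: float, outer_r: float, row_count: int = 1) -> int:
    """Brute-force lattice count of an annulus of revolution.

    Counts integer transverse positions ``(x, z)`` with
    ``inner_r <= sqrt(x^2 + z^2) < outer_r`` and multiplies by the number
    of rows.  Serves as the independent oracle for the voxel count a
    rotated tissue run should occupy per row plane.
    """
    if not (0 <= inner_r < outer_r):
        raise ValidationError(f"need 0 <= inner_r < outer_r, got {inner_r}, {outer_r}")
    lim = int(np.ceil(outer_r))
    ax = np.arange(-lim, lim + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    count = int(np.sum((d2 >= inner_r**2) & (d2 < outer_r**2)))
    return count * int(row_count)
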