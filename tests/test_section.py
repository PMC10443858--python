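import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from PIL import Image

import eye3d
from eye3d import (
    SectionImage,
    ValidationError,
    align_axes,
    align_serial_stack,
    clear_regions,
    flood_mask,
    load_section,
    standardize_size,
    symmetrize,
    tissue_mask,
    white_to_black,
)

rgb_images = arrays(
    np.uint8,
    st.tuples(st.integers(2, 12), st.integers(2, 12), st.just(3)),
    elements=st.integers(0, 255),
)


class TestLoadSection:
    def test_rgb_png_identity(self, tmp_path, rng):
        px = rng.integers(0, 255, (30, 20, 3)).astype(np.uint8)
        Image.fromarray(px).save(tmp_path / "a.png")
        img = load_section(tmp_path / "a.png")
        assert img.shape == (30, 20)
        assert np.array_equal(img.pixels, px)

    def test_grayscale_tiff_promoted_by_replication(self, tmp_path, rng):
        g = rng.integers(0, 255, (15, 10)).astype(np.uint8)
        Image.fromarray(g, mode="L").save(tmp_path / "g.tif")
        img = load_section(tmp_path / "g.tif")
        assert np.array_equal(img.pixels[:, :, 0], g)
        assert np.array_equal(img.pixels[:, :, 1], img.pixels[:, :, 2])

    def test_rgba_transparent_margin_becomes_white(self, tmp_path, rng):
        rgba = rng.integers(0, 255, (12, 12, 4)).astype(np.uint8)
        rgba[:3, :, 3] = 0  # fully transparent margin
        rgba[3:, :, 3] = 255
        Image.fromarray(rgba, mode="RGBA").save(tmp_path / "t.png")
        img = load_section(tmp_path / "t.png")
        # independent oracle: composite over white pixelwise
        alpha = rgba[..., 3:4].astype(np.float64) / 255.0
        expected = np.rint(rgba[..., :3] * alpha + 255.0 * (1 - alpha)).astype(np.uint8)
        assert np.array_equal(img.pixels, expected)

    def test_unreadable_file_names_path(self, tmp_path):
        (tmp_path / "junk.png").write_bytes(b"not an image")
        with pytest.raises(eye3d.InputError, match="junk.png"):
            load_section(tmp_path / "junk.png")


class TestStandardizeSize:
    @pytest.mark.parametrize(
        "shape,target,expected",
        [((600, 600), 300, (300, 300)), ((200, 200), 300, (200, 200)),
         ((600, 400), 300, (300, 200))],
    )
    def test_shapes(self, shape, target, expected, rng):
        img = SectionImage(rng.integers(0, 255, (*shape, 3)).astype(np.uint8))
        assert standardize_size(img, target).shape == expected

    def test_pixel_size_rescaled(self, rng):
        img = SectionImage(
            rng.integers(0, 255, (600, 600, 3)).astype(np.uint8), pixel_size_um=2.0
        )
        assert standardize_size(img, 300).pixel_size_um == pytest.approx(4.0)

    def test_never_upsamples_and_preserves_aspect(self, rng):
        for h, w in [(500, 333), (301, 47), (900, 900)]:
            img = SectionImage(rng.integers(0, 255, (h, w, 3)).astype(np.uint8))
            out = standardize_size(img, 300)
            assert out.shape[0] * out.shape[1] <= h * w
            assert out.shape[1] == pytest.approx(300 * w / h, abs=1)


def _two_dot_image(apex, pole, size=101):
    px = np.full((size, size, 3), 255, dtype=np.uint8)
    px[apex] = (255, 0, 0)
    px[pole] = (0, 0, 255)
    return SectionImage(px)


class TestAlignAxes:
    def test_already_vertical_is_identity(self):
        img = _two_dot_image((20, 50), (80, 50))
        out = align_axes(img, (20, 50), (80, 50))
        assert np.array_equal(out.pixels, img.pixels)

    def test_inverted_axis_rotates_180(self):
        img = _two_dot_image((80, 50), (20, 50))
        out = align_axes(img, (80, 50), (20, 50))
        assert np.array_equal(out.pixels, img.pixels[::-1, ::-1])

    def test_oblique_axis_made_vertical(self):
        # apex-pole segment at 30 deg from vertical
        apex = (50 - 30, 50 - 17)
        pole = (50 + 30, 50 + 17)
        img = _two_dot_image(apex, pole)
        out = align_axes(img, apex, pole)
        a = out.landmarks["corneal_apex"]
        p = out.landmarks["posterior_pole"]
        assert abs(a[1] - p[1]) < 0.5  # segment vertical within half a pixel
        assert a[0] < p[0]  # apex above pole

    def test_coincident_landmarks_rejected(self):
        img = _two_dot_image((10, 10), (20, 20))
        with pytest.raises(ValidationError):
            align_axes(img, (10, 10), (10, 10))


class TestClearRegions:
    def test_full_and_empty_masks(self, rng):
        img = SectionImage(rng.integers(0, 255, (8, 8, 3)).astype(np.uint8))
        assert (clear_regions(img, np.ones((8, 8), bool)).pixels == 255).all()
        assert np.array_equal(
            clear_regions(img, np.zeros((8, 8), bool)).pixels, img.pixels
        )

    def test_disc_mask_changes_exactly_disc_pixels(self, small_phantom):
        img, _ = small_phantom
        h, w = img.shape
        yy, xx = np.mgrid[:h, :w]
        disc = (yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= 10**2
        out = clear_regions(img, disc)
        changed = np.any(out.pixels != img.pixels, axis=2)
        was_white = np.all(img.pixels == 255, axis=2)
        assert not changed[~disc].any()
        assert np.array_equal(changed, disc & ~was_white)

    def test_dimension_mismatch(self, small_phantom):
        img, _ = small_phantom
        with pytest.raises(ValidationError):
            clear_regions(img, np.ones((3, 3), bool))


def test_flood_mask_selects_uniform_cavity(small_phantom):
    img, masks = small_phantom
    # seed in the lens: flat color, so the flood recovers the lens exactly
    ys, xs = np.nonzero(masks["lens"])
    seed = (int(np.mean(ys)), int(np.mean(xs)))
    assert np.array_equal(flood_mask(img, seed, tolerance=10), masks["lens"])


class TestSymmetrize:
    def test_half_black_half_white_keep_left(self):
        px = np.full((4, 6, 3), 255, dtype=np.uint8)
        px[:, :3] = 0
        out = symmetrize(SectionImage(px), keep_side="left")
        assert (out.pixels == 0).all()

    def test_odd_width_center_column_kept(self, rng):
        px = rng.integers(0, 255, (5, 7, 3)).astype(np.uint8)
        out = symmetrize(SectionImage(px), keep_side="left")
        assert np.array_equal(out.pixels[:, 3], px[:, 3])  # center column untouched
        assert np.array_equal(out.pixels[:, :4], px[:, :4])

    @given(px=rgb_images, side=st.sampled_from(["left", "right"]))
    def test_output_is_its_own_mirror_and_idempotent(self, px, side):
        img = SectionImage(px)
        out = symmetrize(img, keep_side=side)
        assert np.array_equal(out.pixels, out.pixels[:, ::-1])
        again = symmetrize(out, keep_side=side)
        assert np.array_equal(again.pixels, out.pixels)

    def test_symmetric_input_is_fixed_point(self, small_phantom):
        img, _ = small_phantom
        assert np.array_equal(symmetrize(img).pixels, img.pixels)


def test_white_to_black_maps_background_only(small_phantom):
    img, _ = small_phantom
    out = white_to_black(img)
    bg = ~tissue_mask(img)
    assert (out.pixels[bg] == 0).all()
    assert np.array_equal(out.pixels[~bg], img.pixels[~bg])


class TestAlignSerialStack:
    def test_identity_stack_gives_identity_transforms(self, small_phantom):
        img, _ = small_phantom
        aligned, tfs = align_serial_stack([img.copy(), img.copy(), img.copy()])
        for tf in tfs:
            assert abs(tf.translation[0]) < 1e-6 and abs(tf.translation[1]) < 1e-6
            assert abs(tf.rotation_deg) < 1e-6
            assert tf.scale == pytest.approx(1.0, abs=1e-9)

    def test_translation_recovered(self, small_phantom):
        img, _ = small_phantom
        shifted = np.full_like(img.pixels, 255)
        shifted[5:, :-3] = img.pixels[:-5, 3:]  # shift by (+5, -3)
        _, tfs = align_serial_stack([SectionImage(shifted), img])
        assert tfs[0].translation[0] == pytest.approx(-5, abs=0.5)
        assert tfs[0].translation[1] == pytest.approx(3, abs=0.5)
        assert tfs[1].is_identity

    def test_scale_recovered(self):
        def disc(radius, size=101):
            yy, xx = np.mgrid[:size, :size]
            m = (yy - 50) ** 2 + (xx - 50) ** 2 <= radius**2
            px = np.full((size, size, 3), 255, dtype=np.uint8)
            px[m] = (100, 60, 120)
            return SectionImage(px)

        _, tfs = align_serial_stack([disc(33), disc(30)])
        assert tfs[0].scale == pytest.approx(30 / 33, rel=0.02)

    def test_blank_slice_named_in_error(self, small_phantom):
        img, _ = small_phantom
        blank = SectionImage(np.full_like(img.pixels, 255))
        with pytest.raises(ValidationError, match="slice 1"):
            align_serial_stack([img, blank])
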