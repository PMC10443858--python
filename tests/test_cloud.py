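import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eye3d
from eye3d import (
    BandpassFilter,
    PointCloud,
    ValidationError,
    VirtualStack,
    bandpass_includes,
    clean_stack,
    read_pcd,
    read_ply,
    stack_to_cloud,
    volume_to_cloud,
    volume_to_stack,
    write_pcd,
    write_ply,
)
from eye3d.cloud import pack_rgb, unpack_rgb


class TestBandpass:
    @pytest.mark.parametrize(
        "red,included",
        [(5, False), (230, False), (6, True), (229, True), (100, True),
         (0, False), (255, False)],
    )
    def test_strict_thresholds(self, red, included):
        assert bandpass_includes((red, 128, 128)) is included

    def test_channel_selection(self):
        filt = BandpassFilter(channel=2)
        assert bandpass_includes((0, 0, 100), filt)
        assert not bandpass_includes((100, 100, 0), filt)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValidationError):
            BandpassFilter(low=200, high=100)

    @given(
        low=st.integers(0, 100),
        high=st.integers(150, 255),
        widen=st.integers(1, 20),
    )
    def test_widening_band_never_decreases_count(self, low, high, widen):
        rng = np.random.default_rng(99)
        stack = VirtualStack(
            slices=[rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
                    for _ in range(4)]
        )
        narrow = stack_to_cloud(stack, BandpassFilter(low, high), "full")
        wide = stack_to_cloud(
            stack,
            BandpassFilter(max(0, low - widen), min(255, high + widen)),
            "full",
        )
        assert wide.count >= narrow.count


class TestStackToCloud:
    def test_all_out_of_band_gives_empty_cloud(self):
        s = np.zeros((4, 4, 3), np.uint8)  # red = 0 everywhere
        stack = VirtualStack(slices=[s, s])
        with pytest.warns(UserWarning, match="empty"):
            cloud = stack_to_cloud(stack, rotation="full")
        assert cloud.count == 0

    def test_known_in_band_count(self, rng):
        slices = [np.zeros((10, 10, 3), np.uint8) for _ in range(10)]
        placed = 0
        while placed < 100:
            z, x, y = rng.integers(0, 10, 3)
            if slices[z][x, y, 0] == 0:
                slices[z][x, y] = (100, 40, 60)
                placed += 1
        cloud = stack_to_cloud(VirtualStack(slices=slices), rotation="full")
        assert cloud.count == 100
        assert (cloud.colors == (100, 40, 60)).all()

    def test_half_uses_first_half_of_slices(self, small_volume):
        stack = volume_to_stack(small_volume)
        half = stack_to_cloud(stack, rotation="half")
        full = stack_to_cloud(stack, rotation="full")
        assert half.count <= full.count <= 2 * half.count + np.prod(
            stack.slice_shape
        )  # the extra central slice(s) bound the difference
        assert (half.points[:, 2] < stack.count // 2).all()

    def test_no_duplicate_coordinates(self, small_volume):
        cloud = stack_to_cloud(volume_to_stack(small_volume), rotation="full")
        coords = np.round(cloud.points).astype(int)
        assert len(np.unique(coords, axis=0)) == cloud.count

    def test_conservation_bound(self, small_volume):
        stack = volume_to_stack(small_volume)
        nonbg = int(sum((s.sum(axis=2, dtype=int) > 0).sum() for s in stack.slices))
        cloud = stack_to_cloud(stack, rotation="full")
        assert cloud.count <= nonbg


def test_volume_and_stack_routes_agree_exactly(small_volume):
    via_volume = volume_to_cloud(small_volume)
    via_stack = stack_to_cloud(volume_to_stack(small_volume), rotation="full")
    a = np.concatenate([via_volume.points, via_volume.colors], axis=1)
    b = np.concatenate([via_stack.points, via_stack.colors], axis=1)
    assert np.array_equal(
        a[np.lexsort(a.T[::-1])], b[np.lexsort(b.T[::-1])]
    )


def test_cleaned_stack_yields_same_cloud(small_volume):
    # eliminate_black moves sentinel pixels from 0 to 255: both out of band
    raw = volume_to_stack(small_volume)
    assert stack_to_cloud(raw).count == stack_to_cloud(clean_stack(raw)).count


@pytest.fixture()
def tri_cloud():
    return PointCloud(
        points=np.array([[0, 0, 0], [1.5, 2.5, 3.5], [10, 20, 30]], np.float32),
        colors=np.array([[10, 20, 30], [255, 0, 0], [100, 150, 200]], np.uint8),
    )


class TestPly:
    @pytest.mark.parametrize("encoding", ["ascii", "binary_little_endian"])
    def test_round_trip_exact(self, tri_cloud, tmp_path, encoding):
        p = write_ply(tri_cloud, tmp_path / "c.ply", encoding=encoding)
        back = read_ply(p)
        assert np.array_equal(back.points, tri_cloud.points)
        assert np.array_equal(back.colors, tri_cloud.colors)

    def test_independent_reader_agrees(self, tri_cloud, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        p = write_ply(tri_cloud, tmp_path / "c.ply")
        mesh = trimesh.load(p)
        assert np.allclose(np.asarray(mesh.vertices), tri_cloud.points)
        assert np.array_equal(
            np.asarray(mesh.colors)[:, :3], tri_cloud.colors
        )

    def test_empty_cloud_valid_header(self, tmp_path):
        empty = PointCloud(np.empty((0, 3)), np.empty((0, 3)))
        p = write_ply(empty, tmp_path / "e.ply")
        assert b"element vertex 0" in p.read_bytes()
        assert read_ply(p).count == 0

    def test_ascii_has_one_line_per_point(self, tri_cloud, tmp_path):
        p = write_ply(tri_cloud, tmp_path / "a.ply", encoding="ascii")
        text = p.read_text()
        body = text.split("end_header\n", 1)[1]
        assert len(body.strip().splitlines()) == 3


class TestPcd:
    def test_round_trip(self, tri_cloud, tmp_path):
        p = write_pcd(tri_cloud, tmp_path / "c.pcd")
        back = read_pcd(p)
        assert np.allclose(back.points, tri_cloud.points)
        assert np.array_equal(back.colors, tri_cloud.colors)

    def test_points_field_matches_count(self, tri_cloud, tmp_path):
        p = write_pcd(tri_cloud, tmp_path / "c.pcd")
        assert "POINTS 3" in p.read_text()

    def test_single_red_point_unpacks(self, tmp_path):
        cloud = PointCloud(np.array([[1, 2, 3]], np.float32),
                           np.array([[255, 0, 0]], np.uint8))
        p = write_pcd(cloud, tmp_path / "r.pcd")
        lines = p.read_text().splitlines()
        data = lines[-1].split()
        assert tuple(unpack_rgb(int(data[3]))) == (255, 0, 0)

    def test_empty_cloud_header(self, tmp_path):
        empty = PointCloud(np.empty((0, 3)), np.empty((0, 3)))
        p = write_pcd(empty, tmp_path / "e.pcd")
        assert "POINTS 0" in p.read_text()

    @given(rgb=st.tuples(*[st.integers(0, 255)] * 3))
    def test_pack_unpack_inverse(self, rgb):
        arr = np.array([rgb], np.uint8)
        assert np.array_equal(unpack_rgb(pack_rgb(arr)), arr)


def test_scaled_cloud_multiplies_coordinates(tri_cloud):
    scaled = tri_cloud.scaled(2.5)
    assert np.allclose(scaled.points, tri_cloud.points * 2.5)
    assert np.array_equal(scaled.colors, tri_cloud.colors)
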