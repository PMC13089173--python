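import numpy as np
import pytest

from beamsel import (
    BeamOrientation,
    Ray,
    StructureMask,
    VoxelVolume,
    build_ray_bundle,
    traverse,
    wepl,
)
from beamsel.raytrace import _bev_basis


def dense_wepl(entry, direction, length, vol, step=0.01):
    """Independent oracle: midpoint-rule sampling of RSP along the ray at a fixed step."""
    n = max(1, int(np.ceil(length / step)))
    dt = length / n
    t = (np.arange(n) + 0.5) * dt
    pts = np.asarray(entry) + t[:, None] * np.asarray(direction)
    bmin = vol.origin_mm - 0.5 * vol.spacing_mm
    ijk = np.floor((pts - bmin) / vol.spacing_mm).astype(int)
    np.clip(ijk, 0, np.array(vol.shape) - 1, out=ijk)
    return float(vol.data[ijk[:, 0], ijk[:, 1], ijk[:, 2]].sum() * dt)


def random_face_to_face_rays(rng, vol, n):
    """Rays between random points on two opposite faces of the volume box."""
    bmin = vol.origin_mm - 0.5 * vol.spacing_mm
    bmax = bmin + np.array(vol.shape) * vol.spacing_mm
    rays = []
    for _ in range(n):
        axis = rng.integers(3)
        p0 = rng.uniform(bmin, bmax)
        p1 = rng.uniform(bmin, bmax)
        p0[axis] = bmin[axis]
        p1[axis] = bmax[axis]
        d = p1 - p0
        length = np.linalg.norm(d)
        rays.append(Ray(p0, d / length, p1))
    return rays


def random_rsp_volume(rng, shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0)):
    data = rng.uniform(0.0, 2.4, size=shape)
    origin = -0.5 * (np.array(shape) - 1) * np.array(spacing)
    return VoxelVolume(data, spacing, origin)


class TestTraverse:
    def test_axis_aligned_ray_chords(self):
        vol = VoxelVolume(np.zeros((10, 1, 1)), (2.0, 2.0, 2.0), (1.0, 0.0, 0.0))
        ray = Ray((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (20.0, 0.0, 0.0))
        segs = traverse(ray, vol)
        assert len(segs) == 10
        assert all(s.length_mm == pytest.approx(2.0, abs=1e-12) for s in segs)
        assert [s.index[0] for s in segs] == list(range(10))

    def test_body_diagonal_through_unit_voxel(self):
        vol = VoxelVolume(np.zeros((1, 1, 1)), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        d = np.ones(3) / np.sqrt(3)
        ray = Ray((-0.5, -0.5, -0.5), d, (0.5, 0.5, 0.5))
        segs = traverse(ray, vol)
        assert len(segs) == 1
        assert segs[0].length_mm == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_ray_missing_volume_is_empty(self):
        vol = VoxelVolume(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0))
        ray = Ray((0.0, 0.0, 100.0), (1.0, 0.0, 0.0), (50.0, 0.0, 100.0))
        assert traverse(ray, vol) == []

    def test_chord_sum_equals_path_length_on_random_rays(self):
        rng = np.random.default_rng(10)
        vol = random_rsp_volume(rng)
        for ray in random_face_to_face_rays(rng, vol, 1000):
            total = sum(s.length_mm for s in traverse(ray, vol))
            assert total == pytest.approx(ray.length_mm, abs=1e-9)

    def test_segments_ordered_from_entry(self):
        rng = np.random.default_rng(11)
        vol = random_rsp_volume(rng, shape=(8, 8, 8))
        for ray in random_face_to_face_rays(rng, vol, 20):
            segs = traverse(ray, vol)
            # consecutive segments share a voxel face: index changes by one step
            for a, b in zip(segs, segs[1:]):
                assert sum(abs(i - j) for i, j in zip(a.index, b.index)) == 1


class TestWepl:
    def test_straight_water_path(self):
        vol = VoxelVolume(np.ones((25, 3, 3)), (2.0, 2.0, 2.0), (1.0, 0.0, 0.0))
        ray = Ray((0.0, 2.0, 2.0), (1.0, 0.0, 0.0), (50.0, 2.0, 2.0))
        assert wepl(ray, vol) == pytest.approx(50.0, abs=1e-9)

    def test_layered_lung_then_water(self):
        data = np.ones((25, 3, 3))
        data[:15] = 0.25  # 30 mm of lung-like material, then 20 mm of water
        vol = VoxelVolume(data, (2.0, 2.0, 2.0), (1.0, 0.0, 0.0))
        ray = Ray((0.0, 2.0, 2.0), (1.0, 0.0, 0.0), (50.0, 2.0, 2.0))
        assert wepl(ray, vol) == pytest.approx(30 * 0.25 + 20 * 1.0, abs=1e-9)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(12)
        vol = random_rsp_volume(rng)
        for ray in random_face_to_face_rays(rng, vol, 50):
            back = Ray(ray.stop_point, -ray.direction, ray.entry_point)
            assert wepl(back, vol) == pytest.approx(wepl(ray, vol), abs=1e-9)

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(13)
        vol = random_rsp_volume(rng)
        for ray in random_face_to_face_rays(rng, vol, 50):
            ref = dense_wepl(ray.entry_point, ray.direction, ray.length_mm, vol)
            assert wepl(ray, vol) == pytest.approx(ref, rel=1e-3)

    def test_monotone_in_voxel_rsp(self):
        vol = VoxelVolume(np.ones((10, 3, 3)), (2.0, 2.0, 2.0), (1.0, 0.0, 0.0))
        ray = Ray((0.0, 2.0, 2.0), (1.0, 0.0, 0.0), (20.0, 2.0, 2.0))
        base = wepl(ray, vol)
        vol.data[5, 1, 1] += 0.5  # a voxel on the ray path
        assert wepl(ray, vol) > base


def sphere_target(radius_mm=20.0, spacing=2.0, shape=48):
    sp = np.full(3, spacing)
    origin = -0.5 * (shape - 1) * sp
    ax = origin[0] + np.arange(shape) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    data = X**2 + Y**2 + Z**2 <= radius_mm**2
    return StructureMask(data, sp, origin, role="ITV")


class TestRayBundle:
    def test_sphere_target_coverage(self):
        target = sphere_target()
        orientation = BeamOrientation(40.0, 15.0)
        bundle = build_ray_bundle(orientation, target, spacing_mm=2.0)
        d = orientation.direction
        u, v = _bev_basis(d)
        centers = target.origin_mm + np.argwhere(target.data) * target.spacing_mm
        a = centers @ u
        b = centers @ v
        seeds_a = np.array([r.entry_point @ u for r in bundle.rays])
        seeds_b = np.array([r.entry_point @ v for r in bundle.rays])
        d2 = (a[:, None] - seeds_a[None, :]) ** 2 + (b[:, None] - seeds_b[None, :]) ** 2
        max_dist = np.sqrt(d2.min(axis=1).max())
        assert max_dist <= bundle.lateral_spacing_mm / np.sqrt(2) + 1e-9

    def test_halved_pitch_quadruples_ray_count(self):
        target = sphere_target()
        orientation = BeamOrientation(90.0, 0.0)
        n2 = len(build_ray_bundle(orientation, target, spacing_mm=2.0).rays)
        n1 = len(build_ray_bundle(orientation, target, spacing_mm=1.0).rays)
        assert 0.8 * 4 <= n1 / n2 <= 1.2 * 4

    def test_single_voxel_target_stop_at_distal_face(self):
        data = np.zeros((9, 9, 9), dtype=bool)
        data[4, 4, 4] = True
        sp = np.full(3, 2.0)
        origin = -0.5 * 8 * sp
        target = StructureMask(data, sp, origin, role="ITV")
        bundle = build_ray_bundle(BeamOrientation(0.0, 0.0), target, spacing_mm=2.0)
        assert len(bundle.rays) >= 1
        center_ray = min(
            bundle.rays, key=lambda r: np.hypot(r.entry_point[0], r.entry_point[2])
        )
        # beam travels +y; the voxel's distal face is at y = center + spacing/2
        assert center_ray.stop_point[1] == pytest.approx(1.0, abs=1e-9)

    def test_stop_points_lie_inside_target_distal_extent(self):
        target = sphere_target()
        bundle = build_ray_bundle(BeamOrientation(120.0, -30.0), target, spacing_mm=2.0)
        for ray in bundle.rays:
            assert ray.length_mm > 0

    def test_empty_target_rejected(self):
        empty = StructureMask(np.zeros((5, 5, 5), bool), (1, 1, 1), (0, 0, 0), role="lungs")
        with pytest.raises(ValueError, match="empty"):
            build_ray_bundle(BeamOrientation(0.0, 0.0), empty, spacing_mm=2.0)

    def test_invalid_pitch_rejected(self):
        target = sphere_target()
        with pytest.raises(ValueError, match="pitch"):
            build_ray_bundle(BeamOrientation(0.0, 0.0), target, spacing_mm=0.0)
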