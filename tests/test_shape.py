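import math

import numpy as np
import pytest

from hippoasym.io import BinaryMask
from hippoasym.shape import (FEATURE_NAMES, TriMesh, axis_metrics,
                             compute_shape_features, diameter_metrics,
                             mask_to_mesh, mesh_area_volume)

from conftest import make_ball_mask


def single_voxel_mask(spacing=(1.0, 1.0, 1.0)):
    m = np.zeros((3, 3, 3), dtype=bool)
    m[1, 1, 1] = True
    return BinaryMask(m, spacing)


def unit_octahedron(a=0.5) -> TriMesh:
    """Regular octahedron with apexes at distance `a` along each axis —
    the exact marching-cubes surface of one isolated unit voxel."""
    v = np.array([[a, 0, 0], [-a, 0, 0], [0, a, 0],
                  [0, -a, 0], [0, 0, a], [0, 0, -a]], dtype=float)
    f = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                  [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
    return TriMesh(v, f)


class TestMaskToMesh:
    def test_single_voxel_is_octahedron(self):
        mesh = mask_to_mesh(single_voxel_mask(), smooth=False)
        assert (mesh.n_vertices, mesh.n_faces) == (6, 8)
        assert mesh.is_closed()
        area, vol = mesh_area_volume(mesh)
        # octahedron, apex distance a=0.5: V = 4a^3/3, A = 4*sqrt(3)*a^2
        assert vol == pytest.approx(1.0 / 6.0, rel=1e-12)
        assert area == pytest.approx(math.sqrt(3.0), rel=1e-12)

    def test_smoothing_preserves_topology(self):
        mesh = mask_to_mesh(single_voxel_mask())  # default: smoothed
        assert (mesh.n_vertices, mesh.n_faces) == (6, 8)
        assert mesh.is_closed()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mask_to_mesh(BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1)))

    def test_cube_euler_characteristic(self):
        m = np.zeros((24, 24, 24), bool)
        m[2:22, 2:22, 2:22] = True
        mesh = mask_to_mesh(BinaryMask(m, (1, 1, 1)), smooth=False)
        assert mesh.is_closed()
        n_edges = len(mesh.edge_counts())
        assert mesh.n_vertices - n_edges + mesh.n_faces == 2  # sphere topology


class TestMeshAreaVolume:
    def test_analytic_octahedron(self):
        area, vol = mesh_area_volume(unit_octahedron())
        assert vol == pytest.approx(4 * 0.5**3 / 3, rel=1e-12)
        assert area == pytest.approx(4 * math.sqrt(3) * 0.5**2, rel=1e-12)

    def test_translation_invariance(self):
        octa = unit_octahedron()
        shifted = TriMesh(octa.vertices + np.array([10.0, -4.0, 7.0]), octa.faces)
        assert mesh_area_volume(shifted) == pytest.approx(mesh_area_volume(octa))

    def test_open_mesh_rejected(self):
        octa = unit_octahedron()
        open_mesh = TriMesh(octa.vertices, octa.faces[:-1])
        with pytest.raises(ValueError, match="not closed"):
            mesh_area_volume(open_mesh)

    def test_sphere_r15_analytic(self, ball15):
        area, vol = mesh_area_volume(mask_to_mesh(ball15))
        r = 15.0
        assert vol == pytest.approx(4 / 3 * math.pi * r**3, rel=0.02)
        assert area == pytest.approx(4 * math.pi * r**2, rel=0.03)

    def test_spacing_scaling(self):
        """Doubling the voxel spacing scales area x4 and volume x8."""
        rng = np.random.default_rng(3)
        m = np.zeros((10, 10, 10), bool)
        m[3:7, 2:8, 4:8] = True
        m &= rng.random((10, 10, 10)) > 0.2
        m[5, 5, 5] = True
        a1, v1 = mesh_area_volume(mask_to_mesh(BinaryMask(m, (1, 1, 1)), smooth=False))
        a2, v2 = mesh_area_volume(mask_to_mesh(BinaryMask(m, (2, 2, 2)), smooth=False))
        assert a2 == pytest.approx(4 * a1, rel=1e-9)
        assert v2 == pytest.approx(8 * v1, rel=1e-9)


def make_ellipsoid_mask(a, b, c, spacing=(1.0, 1.0, 1.0)):
    g = np.arange(-max(a, b, c) - 2, max(a, b, c) + 3)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    return BinaryMask((x / a)**2 + (y / b)**2 + (z / c)**2 <= 1.0, spacing)


class TestAxisMetrics:
    def test_solid_ellipsoid(self):
        # continuum second moments of a solid ellipsoid: lambda_i = a_i^2 / 5
        major, minor, least, elong, flat = axis_metrics(make_ellipsoid_mask(20, 12, 8))
        assert elong == pytest.approx(12 / 20, abs=0.02)
        assert flat == pytest.approx(8 / 20, abs=0.02)
        assert major == pytest.approx(4 * 20 / math.sqrt(5), rel=0.02)

    def test_ball_is_isotropic(self):
        *_, elong, flat = axis_metrics(make_ball_mask(8))
        assert elong == pytest.approx(1.0, abs=0.02)
        assert flat == pytest.approx(1.0, abs=0.02)

    def test_too_few_voxels(self):
        with pytest.raises(ValueError, match="at least 2"):
            axis_metrics(single_voxel_mask())


class TestDiameterMetrics:
    def test_sphere_diameter(self):
        mesh = mask_to_mesh(make_ball_mask(10))
        max3d, *_ = diameter_metrics(mesh)
        assert max3d == pytest.approx(20.0, rel=0.02)

    def test_single_voxel(self):
        mesh = mask_to_mesh(single_voxel_mask(), smooth=False)
        max3d, d_slice, d_col, d_row = diameter_metrics(mesh)
        assert max3d == pytest.approx(1.0, rel=1e-12)  # apex to apex

    def test_3d_dominates_2d(self, ball15):
        max3d, *d2 = diameter_metrics(mask_to_mesh(ball15))
        assert max3d >= max(d2) - 1e-9


class TestComputeShapeFeatures:
    def test_exactly_14_features(self, ball15):
        feats = compute_shape_features(ball15)
        assert len(feats.as_dict()) == 14
        assert len(FEATURE_NAMES) == 14

    def test_sphere_limits(self, ball15):
        feats = compute_shape_features(ball15)
        assert feats.surface_to_volume_ratio == pytest.approx(3.0 / 15.0, rel=0.05)
        assert feats.sphericity >= 0.97
        assert feats.sphericity <= 1.0 + 1e-6

    def test_invariants(self, ball15):
        d = compute_shape_features(ball15).as_dict()
        assert all(v > 0 for v in d.values())
        assert d["flatness"] <= d["elongation"] <= 1.0 + 1e-9
        assert d["max_3d_diameter"] >= max(
            d["max_2d_diameter_slice"], d["max_2d_diameter_column"],
            d["max_2d_diameter_row"]) - 1e-9
        assert abs(d["mesh_volume"] / d["voxel_volume"] - 1) < 0.10

    def test_sv_ratio_scaling(self):
        """Uniform shrink by s multiplies the surface-to-volume ratio by 1/s."""
        m = make_ellipsoid_mask(10, 6, 4, spacing=(1, 1, 1))
        big = make_ellipsoid_mask(10, 6, 4, spacing=(2, 2, 2))  # same voxels, x2 size
        f1 = compute_shape_features(m)
        f2 = compute_shape_features(big)
        assert f2.surface_to_volume_ratio == pytest.approx(
            f1.surface_to_volume_ratio / 2, rel=1e-9)

    def test_rigid_rotation_permutes_plane_diameters(self):
        """A 90-degree in-plane rotation swaps the sagittal/coronal diameters
        and leaves every other feature unchanged (up to triangulation
        tolerance: marching-cubes cell splitting is not rotation-symmetric,
        so meshes of rotated masks are congruent only to ~0.01%)."""
        mask = make_ellipsoid_mask(9, 5, 3)
        rotated = BinaryMask(np.rot90(mask.mask, axes=(0, 1)).copy(), mask.spacing)
        f1 = compute_shape_features(mask).as_dict()
        f2 = compute_shape_features(rotated).as_dict()
        assert f2["max_2d_diameter_row"] == pytest.approx(
            f1["max_2d_diameter_column"], rel=1e-9)
        assert f2["max_2d_diameter_column"] == pytest.approx(
            f1["max_2d_diameter_row"], rel=1e-9)
        voxel_exact = ("voxel_volume", "major_axis_length", "minor_axis_length",
                       "least_axis_length", "elongation", "flatness")
        for name in FEATURE_NAMES:
            if name.startswith("max_2d"):
                continue
            tol = 1e-9 if name in voxel_exact else 1e-3
            assert f2[name] == pytest.approx(f1[name], rel=tol), name

    def test_ball_convergence(self):
        """Relative errors of mesh area and volume against the analytic ball
        decrease monotonically with radius."""
        area_err, vol_err = [], []
        for r in (5, 10, 15):
            feats = compute_shape_features(make_ball_mask(r))
            area_err.append(abs(feats.surface_area / (4 * math.pi * r**2) - 1))
            vol_err.append(abs(feats.mesh_volume / (4 / 3 * math.pi * r**3) - 1))
        assert area_err[0] > area_err[1] > area_err[2]
        assert vol_err[0] > vol_err[1] > vol_err[2]
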