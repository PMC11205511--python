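"""Basic geometric parameters: meshing, hull, axes, centroid."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cellshape3d as cs
from conftest import make_region


class TestExtractRegions:
    def test_single_block_preserves_label_and_count(self):
        grid = np.zeros((6, 6, 6), dtype=np.int32)
        grid[1:4, 1:4, 1:4] = 7
        regions = cs.extract_regions(grid)
        assert len(regions) == 1
        assert regions[0].label == 7
        assert regions[0].voxel_count == 27
        assert regions[0].mask.shape == (3, 3, 3)  # cropped tight

    def test_origin_adjusted_to_bounding_box(self):
        grid = np.zeros((6, 6, 6), dtype=np.int32)
        grid[2:4, 3:5, 1:2] = 1
        region = cs.extract_regions(grid, spacing=(0.5, 0.5, 0.5))[0]
        np.testing.assert_allclose(region.origin, [1.0, 1.5, 0.5])

    def test_two_labels_conserve_voxel_counts(self):
        grid = np.zeros((8, 8, 8), dtype=np.int32)
        grid[0:2, 0:2, 0:2] = 1
        grid[5:8, 5:8, 5:8] = 2
        regions = cs.extract_regions(grid)
        assert sorted(r.label for r in regions) == [1, 2]
        assert sum(r.voxel_count for r in regions) == int((grid > 0).sum())

    def test_all_zero_grid_raises(self):
        with pytest.raises(cs.EmptyRegionError, match="no regions"):
            cs.extract_regions(np.zeros((4, 4, 4), dtype=np.int32))

    def test_non_3d_input_raises(self):
        with pytest.raises(cs.CellShapeError, match="3D"):
            cs.extract_regions(np.ones((4, 4), dtype=np.int32))


class TestSurfaceMesh:
    def test_single_voxel_meshes_closed_with_positive_measures(self):
        region = make_region(np.ones((1, 1, 1)))
        mesh = cs.triangulate_surface(region)
        assert mesh.is_closed()
        assert cs.surface_area(mesh) > 0
        assert cs.enclosed_volume(mesh) > 0

    def test_sphere_mesh_volume_matches_closed_form(self, sphere10):
        mesh = cs.triangulate_surface(sphere10)
        vol = cs.enclosed_volume(mesh)
        assert vol == pytest.approx(4 / 3 * math.pi * 10**3, rel=0.02)

    def test_sphere_mesh_area_matches_closed_form(self, sphere20):
        mesh = cs.triangulate_surface(sphere20)
        assert cs.surface_area(mesh) == pytest.approx(4 * math.pi * 20**2, rel=0.03)

    def test_ellipsoid_mesh_volume_matches_closed_form(self, ellipsoid842):
        mesh = cs.triangulate_surface(ellipsoid842)
        vol = cs.enclosed_volume(mesh)
        assert vol == pytest.approx(4 / 3 * math.pi * 8 * 4 * 2, rel=0.02)

    @pytest.mark.parametrize("shape_spec", ["sphere", "box"])
    def test_euler_characteristic_is_two_for_genus_zero(self, shape_spec):
        spec = cs.sphere(6) if shape_spec == "sphere" else cs.box(7, 5, 4)
        mesh = cs.triangulate_surface(cs.voxelize(spec))
        assert mesh.euler_characteristic() == 2

    def test_unit_cube_area_and_volume(self, unit_cube_mesh):
        assert cs.surface_area(unit_cube_mesh) == pytest.approx(6.0)
        assert cs.enclosed_volume(unit_cube_mesh) == pytest.approx(1.0)

    def test_scaling_laws_on_cube_mesh(self, unit_cube_mesh):
        k = 2.7
        scaled = cs.SurfaceMesh(
            vertices=unit_cube_mesh.vertices * k,
            triangles=unit_cube_mesh.triangles,
        )
        assert cs.surface_area(scaled) == pytest.approx(6.0 * k**2)
        assert cs.enclosed_volume(scaled) == pytest.approx(k**3)

    def test_open_mesh_raises(self, unit_cube_mesh):
        broken = cs.SurfaceMesh(
            vertices=unit_cube_mesh.vertices,
            triangles=unit_cube_mesh.triangles[:-1],
        )
        with pytest.raises(cs.OpenMeshError):
            cs.enclosed_volume(broken)

    def test_spacing_scales_mesh_exactly(self, sphere10):
        k = 3.0
        scaled = cs.VoxelRegion(
            mask=sphere10.mask,
            spacing=sphere10.spacing * k,
            origin=sphere10.origin * k,
            label=1,
        )
        m1 = cs.triangulate_surface(sphere10)
        m2 = cs.triangulate_surface(scaled)
        assert cs.surface_area(m2) == pytest.approx(
            cs.surface_area(m1) * k**2, rel=1e-9
        )
        assert cs.enclosed_volume(m2) == pytest.approx(
            cs.enclosed_volume(m1) * k**3, rel=1e-9
        )


class TestConvexHull:
    def test_convex_region_hull_volume_close(self, sphere10):
        mesh = cs.triangulate_surface(sphere10)
        hull = cs.convex_hull_mesh(sphere10, mesh=mesh)
        ratio = cs.enclosed_volume(hull) / cs.enclosed_volume(mesh)
        assert 1.0 <= ratio * (1 + 1e-12) <= 1.02

    def test_dumbbell_hull_strictly_larger(self, dumbbell_region):
        mesh = cs.triangulate_surface(dumbbell_region)
        hull = cs.convex_hull_mesh(dumbbell_region, mesh=mesh)
        assert cs.enclosed_volume(hull) > 1.05 * cs.enclosed_volume(mesh)

    def test_coplanar_points_raise_degenerate_hull(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0]])
        with pytest.raises(cs.DegenerateHullError):
            cs.convex_hull_of_points(pts)

    def test_hull_mesh_is_closed_and_triangular(self, dumbbell_region):
        hull = cs.convex_hull_mesh(dumbbell_region)
        assert hull.is_closed()
        assert hull.triangles.shape[1] == 3


class TestPrincipalAxes:
    def test_axis_aligned_box_extents(self, box953):
        frame = cs.principal_axes(box953)
        np.testing.assert_allclose(frame.lengths, [9, 5, 3], rtol=1e-9)
        # each principal direction coincides with a grid axis
        np.testing.assert_allclose(
            np.max(np.abs(frame.directions), axis=1), 1.0, atol=1e-9
        )

    def test_rotated_box_same_sorted_lengths(self):
        mask = np.ones((9, 5, 3), dtype=bool)
        region = make_region(mask)
        rotated = make_region(np.rot90(mask, axes=(0, 1)))
        f1 = cs.principal_axes(region)
        f2 = cs.principal_axes(rotated)
        np.testing.assert_allclose(f1.lengths, f2.lengths, rtol=1e-9)

    def test_arbitrary_rotation_preserves_lengths_approximately(self):
        lengths = []
        for euler in [(0, 0, 0), (30, 45, 10)]:
            region = cs.voxelize(cs.ellipsoid(16, 12, 10, euler_deg=euler))
            lengths.append(cs.principal_axes(region).lengths)
        np.testing.assert_allclose(lengths[0], lengths[1], rtol=0.03)

    def test_sphere_degenerate_spectrum(self, sphere10):
        frame = cs.principal_axes(sphere10)
        assert frame.a / frame.c <= 1.05

    def test_single_voxel_special_case(self):
        region = make_region(np.ones((1, 1, 1)), spacing=(0.5, 0.25, 1.0))
        frame = cs.principal_axes(region)
        np.testing.assert_allclose(frame.lengths, [1.0, 0.5, 0.25])

    def test_covariance_matches_brute_force(self, ellipsoid842):
        coords = ellipsoid842.voxel_centers()
        cov = np.cov(coords.T, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        frame = cs.principal_axes(ellipsoid842)
        # projected variances along returned directions match the spectrum
        for k in range(3):
            proj = coords @ frame.directions[k]
            assert proj.var(ddof=1) == pytest.approx(eigvals[k], rel=1e-6)


class TestCentroid:
    def test_single_voxel_center_convention(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 3, 4] = True
        np.testing.assert_allclose(
            cs.centroid(make_region(mask)), [2.5, 3.5, 4.5]
        )

    def test_two_voxel_midpoint(self):
        mask = np.zeros((5, 1, 1), dtype=bool)
        mask[0] = mask[4] = True
        np.testing.assert_allclose(
            cs.centroid(make_region(mask)), [2.5, 0.5, 0.5]
        )

    def test_symmetric_region_centered(self, sphere10):
        # the digitized sphere is centrosymmetric about the lattice origin
        np.testing.assert_allclose(cs.centroid(sphere10), [0, 0, 0], atol=1e-9)


class TestBasicParams:
    def test_sphere_volume_and_hull_ratio(self, sphere15_params):
        assert sphere15_params.V == pytest.approx(14137.17, rel=0.02)
        ratio = sphere15_params.V_convex / sphere15_params.V
        assert 1.0 <= ratio * (1 + 1e-12) <= 1.02

    def test_box_volume_voxel_count_oracle(self, box953):
        params = cs.basic_params(box953)
        assert params.V == pytest.approx(135.0, rel=0.05)

    @pytest.mark.parametrize(
        "spec",
        [cs.sphere(8), cs.ellipsoid(10, 7, 5), cs.box(8, 6, 4),
         cs.dumbbell(6, 6, 9)],
        ids=["sphere", "ellipsoid", "box", "dumbbell"],
    )
    def test_invariants_hold(self, spec):
        params = cs.basic_params(cs.voxelize(spec))
        assert params.V <= params.V_convex * (1 + 1e-9)
        assert 36 * math.pi * params.V**2 <= 1.001 * params.S**3
        a, b, c = params.axes.lengths
        assert a >= b >= c > 0

    @given(
        dims=st.tuples(
            st.integers(2, 10), st.integers(2, 10), st.integers(2, 10)
        ),
        sp=st.sampled_from([0.25, 0.5, 1.0]),
    )
    def test_box_region_properties(self, dims, sp):
        region = make_region(np.ones(dims, dtype=bool), spacing=(sp,) * 3)
        params = cs.basic_params(region)
        assert params.V <= params.V_convex * (1 + 1e-9)
        assert 36 * math.pi * params.V**2 <= 1.001 * params.S**3
        a, b, c = params.axes.lengths
        np.testing.assert_allclose(
            sorted([a, b, c], reverse=True), sorted(np.array(dims) * sp, reverse=True),
            rtol=1e-9,
        )
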