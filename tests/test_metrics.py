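"""Evaluation metrics and surface morphometry."""

import numpy as np
import pytest

from cpseg.metrics import (
    angle_deficits,
    dice3d,
    extract_inner_surface,
    global_mean_curvature,
    index_agreement,
    mean_surface_distance,
    mesh_from_arrays,
    mixed_voronoi_areas,
    region_volume_cc,
    surface_area,
)
from cpseg.phantoms import PhantomSpec, generate_phantom

from conftest import brute_force_msd


class TestDice3d:
    def test_identity_is_one(self, phantom48):
        assert dice3d(phantom48.labels, phantom48.labels, "CP_L") == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((6, 6, 6), np.uint8)
        b = np.zeros((6, 6, 6), np.uint8)
        a[:2], b[4:] = 1, 1
        assert dice3d(a, b, 1) == 0.0

    def test_hand_counts(self):
        a = np.zeros((10, 10, 10), np.uint8)
        b = np.zeros((10, 10, 10), np.uint8)
        a.ravel()[:100] = 3
        b.ravel()[20:120] = 3
        assert dice3d(a, b, "CP_L") == pytest.approx(2 * 80 / 200)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4, 4), np.uint8)
        assert dice3d(z, z, "CP_R") == 1.0
        z2 = z.copy()
        z2[0, 0, 0] = 4
        assert dice3d(z, z2, "CP_R") == 0.0

    def test_invariant_to_other_region_relabeling(self, phantom48):
        scrambled = phantom48.labels.copy()
        scrambled[scrambled == 1] = 2  # merge inner volumes; CP_L untouched
        assert dice3d(phantom48.labels, scrambled, "CP_L") == 1.0


class TestMeanSurfaceDistance:
    def test_identical_regions_zero(self, phantom48):
        assert mean_surface_distance(
            phantom48.labels, phantom48.labels, "CP_L", 0.75
        ) == pytest.approx(0.0)

    def test_parallel_plates_closed_form(self):
        """1-voxel plates 3 voxels apart at 0.75 mm -> MSD = 2.25 mm."""
        a = np.zeros((10, 10, 10), np.uint8)
        b = np.zeros((10, 10, 10), np.uint8)
        a[3, :, :], b[6, :, :] = 1, 1
        assert mean_surface_distance(a, b, 1, 0.75) == pytest.approx(2.25)

    def test_symmetry(self, phantom48):
        eroded = phantom48.labels.copy()
        eroded[eroded == 3] = 0
        eroded[phantom48.labels == 1] = 3  # use inner as a deformed stand-in
        ab = mean_surface_distance(phantom48.labels, eroded, "CP_L", 0.75)
        ba = mean_surface_distance(eroded, phantom48.labels, "CP_L", 0.75)
        assert ab == pytest.approx(ba)

    def test_matches_all_pairs_brute_force(self):
        """Distance-transform MSD equals exhaustive pairwise distances."""
        rng = np.random.default_rng(0)
        a = np.zeros((12, 12, 12), np.uint8)
        b = np.zeros((12, 12, 12), np.uint8)
        a[3:7, 3:7, 3:7] = 1
        b[4:9, 4:8, 3:6] = 1
        got = mean_surface_distance(a, b, 1, 0.75)
        want = brute_force_msd(a == 1, b == 1, 0.75)
        assert got == pytest.approx(want, abs=1e-9)

    def test_empty_region_raises(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        b[1, 1, 1] = 1
        with pytest.raises(ValueError):
            mean_surface_distance(a, b, 1, 0.75)


class TestRegionVolume:
    def test_values(self):
        z = np.zeros((10, 10, 10), np.uint8)
        assert region_volume_cc(z, 1, 0.75) == 0.0
        z[:10, :10, :10] = 1
        assert region_volume_cc(z, 1, 1.0) == pytest.approx(1.0)
        z2 = np.zeros((20, 20, 20), np.uint8)
        z2.ravel()[:4741] = 3
        assert region_volume_cc(z2, "CP_L", 0.75) == pytest.approx(2.0, abs=5e-4)


class TestMixedVoronoiAreas:
    def test_unit_square_two_right_triangles(self):
        """Hand-computed planar Voronoi cells: right-angle corners get 1/4
        per triangle, 45-degree corners 1/8; totals partition the area."""
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        f = np.array([[0, 1, 2], [1, 3, 2]])
        areas = mixed_voronoi_areas(v, f)
        assert areas.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(areas, [0.25, 0.25, 0.25, 0.25], atol=1e-12)

    def test_partition_property_on_icosphere(self):
        import trimesh

        m = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        areas = mixed_voronoi_areas(m.vertices, m.faces)
        assert areas.sum() == pytest.approx(m.area, rel=1e-9)
        assert (areas > 0).all()

    def test_obtuse_triangle_half_quarter_rule(self):
        v = np.array([[0, 0, 0], [4, 0, 0], [2, 0.2, 0]], float)  # very obtuse at v2
        f = np.array([[0, 1, 2]])
        areas = mixed_voronoi_areas(v, f)
        face_area = 0.5 * 4 * 0.2
        np.testing.assert_allclose(
            areas, [face_area / 4, face_area / 4, face_area / 2], atol=1e-12
        )


class TestCurvature:
    def test_flat_grid_interior_deficit_zero(self):
        xs, ys = np.meshgrid(np.arange(3.0), np.arange(3.0))
        v = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(9)])
        f = []
        for i in range(2):
            for j in range(2):
                a = i * 3 + j
                f += [[a, a + 1, a + 3], [a + 1, a + 4, a + 3]]
        deficits = angle_deficits(v, np.array(f))
        assert deficits[4] == pytest.approx(0.0, abs=1e-12)  # interior vertex

    def test_gauss_bonnet_on_closed_meshes(self, phantom48):
        """Sum of angle deficits over a closed genus-0 surface is 4*pi."""
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        assert angle_deficits(ico.vertices, ico.faces).sum() == pytest.approx(
            4 * np.pi, abs=1e-6
        )
        mesh = extract_inner_surface(phantom48.labels, "left", phantom48.voxel_mm)
        deficits = angle_deficits(mesh.vertices, mesh.faces)
        assert deficits.sum() == pytest.approx(4 * np.pi, abs=1e-6)

    def test_gmc_decreases_with_sphere_radius(self):
        import trimesh

        gmcs = []
        for r in (10.0, 20.0):
            m = trimesh.creation.icosphere(subdivisions=3, radius=r)
            gmcs.append(global_mean_curvature(mesh_from_arrays(m.vertices, m.faces)))
        assert gmcs[0] > gmcs[1]
        # deficit theory: total |deficit| fixed at 4*pi, area grows as r^2
        assert gmcs[0] / gmcs[1] == pytest.approx(4.0, rel=0.05)


def _sphere_labels(radius_mm=10.0, voxel=0.75, grid=40):
    idx = np.indices((grid, grid, grid)) * voxel
    c = (grid - 1) * voxel / 2
    r = np.sqrt(((idx - c) ** 2).sum(axis=0))
    return (r <= radius_mm).astype(np.uint8)


class TestSurfaceExtraction:
    def test_sphere_area_within_two_percent(self):
        labels = _sphere_labels()
        mesh = extract_inner_surface(labels, "left", 0.75)
        expected = 4 * np.pi * 100.0
        assert abs(surface_area(mesh) - expected) / expected < 0.02

    def test_mesh_watertight_euler_two(self, phantom48):
        mesh = extract_inner_surface(phantom48.labels, "right", phantom48.voxel_mm)
        tm = mesh.to_trimesh()
        assert tm.is_watertight and tm.euler_number == 2

    def test_ellipsoid_area_matches_thomsen(self):
        """Smooth phantom inner surface vs the Thomsen closed-form
        approximation for ellipsoid area (exact to ~0.1%)."""
        spec = PhantomSpec.default(grid=64, fold_amplitude_mm=0.0, noise_sd=0.0)
        case = generate_phantom(spec)
        mesh = extract_inner_surface(case.labels, "left", spec.voxel_mm)
        a, b, c = (r - spec.shell_thickness_mm for r in spec.hemisphere_radii[0])
        p = 1.6075
        thomsen = 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
        assert abs(surface_area(mesh) - thomsen) / thomsen < 0.05

    def test_fold_amplitude_monotonically_increases_area_and_gmc(self):
        areas, gmcs = [], []
        for amp in (0.0, 0.6, 1.2):
            spec = PhantomSpec.default(
                grid=64, fold_amplitude_mm=amp, fold_frequency=6.0, noise_sd=0.0
            )
            case = generate_phantom(spec)
            mesh = extract_inner_surface(case.labels, "left", spec.voxel_mm)
            areas.append(surface_area(mesh))
            gmcs.append(global_mean_curvature(mesh))
        assert areas[0] < areas[1] < areas[2]
        assert gmcs[0] < gmcs[1] < gmcs[2]

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            extract_inner_surface(np.zeros((8, 8, 8), np.uint8), "left", 0.75)


class TestIndexAgreement:
    def test_perfect_agreement(self):
        import pandas as pd

        df = pd.DataFrame({"volume_cc": [1.0, 2.0, 3.0, 4.0], "gmc": [0.1, 0.2, 0.3, 0.4]})
        res = index_agreement(df, df)
        np.testing.assert_allclose(res["beta"], 1.0)
        np.testing.assert_allclose(res["r2"], 1.0)

    def test_doubled_slope(self):
        import pandas as pd

        manual = pd.DataFrame({"a": [1.0, 2.0, 3.0, 5.0]})
        auto = pd.DataFrame({"a": [2.0, 4.0, 6.0, 10.0]})
        res = index_agreement(auto, manual)
        assert res["beta"].iloc[0] == pytest.approx(2.0)

    def test_noisy_slope_recovered(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        x = rng.uniform(1, 10, 40)
        y = 1.5 * x + rng.normal(0, 0.2, 40)
        res = index_agreement(pd.DataFrame({"a": y}), pd.DataFrame({"a": x}))
        assert res["beta"].iloc[0] == pytest.approx(1.5, abs=0.1)
        assert res["r2"].iloc[0] > 0.95

    def test_too_few_pairs_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            index_agreement(df, df)
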