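"""dGEMRIC index, volume, point-sampled surface area, thickness, DSC/HD/ASD."""

import itertools

import numpy as np
import pytest

from hipcart.errors import AlignmentError, DomainError, ParameterError
from hipcart.geometry import Sphere, fit_sphere
from hipcart.metrics import (
    avg_surface_distance,
    build_section_report,
    dgemric_index,
    dice,
    generate_sphere_points,
    hausdorff,
    section_surface_area,
    section_thickness,
    section_volume,
)
from hipcart.phantom import PhantomTruth, make_shell_phantom
from hipcart.sectioning import section_label
from hipcart.volumes import ImageVolume, LabelVolume


def lab(arr, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return LabelVolume(np.asarray(arr, dtype=np.uint8), spacing=spacing, origin=origin)


class TestDgemricIndex:
    def test_constant_field(self):
        t1 = ImageVolume(np.full((4, 4, 4), 500.0), spacing=(1, 1, 1))
        m = lab(np.ones((4, 4, 4)))
        assert dgemric_index(t1, m) == 500.0

    def test_half_and_half(self):
        data = np.full((4, 4, 4), 400.0)
        data[:2] = 600.0
        t1 = ImageVolume(data, spacing=(1, 1, 1))
        assert dgemric_index(t1, lab(np.ones((4, 4, 4)))) == 500.0

    def test_empty_section_reports_missing(self):
        t1 = ImageVolume(np.full((4, 4, 4), 500.0), spacing=(1, 1, 1))
        with pytest.warns(UserWarning):
            out = dgemric_index(t1, lab(np.zeros((4, 4, 4))))
        assert np.isnan(out)

    def test_painted_quadrants_reproduced_exactly(self):
        """Sector-wise constants painted onto a phantom come back exactly as
        the per-sector means."""
        t1_map, mask, truth, labeling, sphere = _painted_quadrants()
        for k, val in enumerate(QUADRANT_T1):
            sel = labeling.sector.data == k + 1
            assert dgemric_index(t1_map, sel) == pytest.approx(val, abs=1e-12)


QUADRANT_T1 = [584.0, 481.0, 523.0, 597.0]


def _painted_quadrants():
    from hipcart.geometry import AnatomicalFrame

    truth = PhantomTruth(
        symmetry_axis=(0, 1, 0), reference_axis=(0, 0, 1),
        polar_range=(55.0, 125.0),
    )
    _, mask, truth = make_shell_phantom(truth, spacing=(1, 1, 1))
    sphere = Sphere(centre=truth.centre, radius=truth.r_mid)
    x_ax, y_ax, z_ax = truth.local_frame()
    frame = AnatomicalFrame(origin=truth.centre, X=x_ax, Y=y_ax, Z=z_ax)
    labeling = section_label(mask, frame, sphere, n_sectors=4,
                             layers=False, regions=False)
    data = np.zeros(mask.shape)
    for k, val in enumerate(QUADRANT_T1):
        data[labeling.sector.data == k + 1] = val
    t1_map = ImageVolume(data, spacing=mask.spacing, origin=mask.origin)
    return t1_map, mask, truth, labeling, sphere


class TestVolume:
    def test_arithmetic(self):
        m = lab(np.ones((10, 10, 10)), spacing=(0.24, 0.24, 1.0))
        assert section_volume(m, m.spacing) == pytest.approx(1000 * 0.0576)

    def test_empty_is_zero(self):
        assert section_volume(np.zeros((3, 3, 3)), (1, 1, 1)) == 0.0

    def test_full_shell_within_2pct(self, full_shell_phantom):
        _, mask, truth = full_shell_phantom
        v = section_volume(mask, mask.spacing)
        assert v == pytest.approx(truth.analytic_volume, rel=0.02)


class TestSpherePoints:
    def test_mean_is_origin(self):
        pts = generate_sphere_points(100_000)
        assert np.all(np.abs(pts.mean(axis=0)) < 1e-3)

    def test_octants_balanced(self):
        pts = generate_sphere_points(100_000)
        signs = pts > 0
        counts = [
            np.all(signs == np.array(o), axis=1).sum()
            for o in itertools.product([True, False], repeat=3)
        ]
        assert max(counts) <= 12500 * 1.02 and min(counts) >= 12500 * 0.98

    def test_unit_norm(self):
        pts = generate_sphere_points(1000)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_single_point_is_pole(self):
        assert np.array_equal(generate_sphere_points(1), [[0, 0, 1.0]])

    def test_invalid_count(self):
        with pytest.raises(ParameterError):
            generate_sphere_points(0)


class TestSurfaceArea:
    def test_full_shell_total_is_sphere_area(self, full_shell_phantom):
        _, mask, truth = full_shell_phantom
        sphere = fit_sphere(mask)
        areas = section_surface_area(mask, None, sphere, n_points=100_000)
        assert areas["total"] == pytest.approx(
            4 * np.pi * sphere.radius**2, rel=0.01
        )

    def test_hemisphere_total_is_half_sphere(self):
        truth = PhantomTruth(polar_range=(0.0, 90.0))
        _, mask, truth = make_shell_phantom(truth, spacing=(0.5, 0.5, 0.5))
        sphere = fit_sphere(mask)
        areas = section_surface_area(mask, None, sphere, n_points=100_000)
        assert areas["total"] == pytest.approx(
            2 * np.pi * sphere.radius**2, rel=0.02
        )

    def test_sector_areas_equal_on_uniform_band(self):
        t1_map, mask, truth, labeling, sphere = _painted_quadrants()
        areas = section_surface_area(mask, labeling, sphere, n_points=50_000)
        per_sector = [areas[(k, 0, 0)] for k in range(1, 5)]
        assert max(per_sector) - min(per_sector) < 0.02 * np.mean(per_sector) * 2
        band_area = truth.solid_angle_fraction * 4 * np.pi * sphere.radius**2
        assert sum(per_sector) == pytest.approx(band_area, rel=0.03)

    def test_doubling_points_changes_areas_below_half_pct(self, lunate_phantom):
        _, mask, truth, sphere, frame = lunate_phantom
        lab50 = section_label(mask, frame, sphere, 4, layers=False, regions=False)
        a1 = section_surface_area(mask, lab50, sphere, n_points=50_000)
        a2 = section_surface_area(mask, lab50, sphere, n_points=100_000)
        for k in range(1, 5):
            assert abs(a1[(k, 0, 0)] - a2[(k, 0, 0)]) < 0.005 * a2[(k, 0, 0)]

    def test_point_conservation_across_enabled_dims(self, lunate_phantom):
        """Enabling layers/regions never changes the sector area totals."""
        _, mask, truth, sphere, frame = lunate_phantom
        plain = section_label(mask, frame, sphere, 4, layers=False, regions=False)
        full = section_label(mask, frame, sphere, 4, layers=True, regions=True)
        a_plain = section_surface_area(mask, plain, sphere, n_points=20_000)
        a_full = section_surface_area(mask, full, sphere, n_points=20_000)
        for k in range(1, 5):
            sector_total = sum(
                v for key, v in a_full.items()
                if key != "total" and key[0] == k
            )
            assert sector_total == pytest.approx(a_plain[(k, 0, 0)], abs=1e-9)


class TestThickness:
    def test_arithmetic(self):
        assert section_thickness(57.6, 28.8) == 2.0

    def test_shell_thickness_recovered(self, full_shell_phantom):
        _, mask, truth = full_shell_phantom
        sphere = fit_sphere(mask)
        areas = section_surface_area(mask, None, sphere, n_points=100_000)
        vol = section_volume(mask, mask.spacing)
        assert section_thickness(vol, areas["total"]) == pytest.approx(
            truth.analytic_thickness, abs=0.15
        )

    def test_halving_thickness_halves_estimate(self):
        vals = []
        for t in (3.0, 1.5):
            truth = PhantomTruth(r_inner=44.0 - t / 2, r_outer=44.0 + t / 2)
            _, mask, truth = make_shell_phantom(truth, spacing=(0.5, 0.5, 0.5))
            sphere = fit_sphere(mask)
            areas = section_surface_area(mask, None, sphere, n_points=50_000)
            vals.append(section_thickness(section_volume(mask, mask.spacing),
                                          areas["total"]))
        assert vals[1] == pytest.approx(vals[0] / 2, rel=0.05)

    def test_zero_surface_is_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(section_thickness(10.0, 0.0))


class TestDice:
    def test_identical(self):
        m = lab(np.ones((4, 4, 4)))
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4)); a[:2] = 1
        b = np.zeros((4, 4, 4)); b[2:] = 1
        assert dice(lab(a), lab(b)) == 0.0

    def test_partial_overlap(self):
        a = np.zeros((10, 10, 10)); a.ravel()[:100] = 1
        b = np.zeros((10, 10, 10)); b.ravel()[20:120] = 1
        assert dice(lab(a), lab(b)) == pytest.approx(0.8)

    def test_both_empty_convention(self):
        z = lab(np.zeros((3, 3, 3)))
        assert dice(z, z) == 1.0

    def test_geometry_mismatch(self):
        a = lab(np.ones((3, 3, 3)))
        b = LabelVolume(np.ones((3, 3, 3), dtype=np.uint8), spacing=(2, 1, 1))
        with pytest.raises(AlignmentError):
            dice(a, b)


def brute_surface_distances(a, b):
    """Brute-force boundary extraction + all-pairs distances."""

    def boundary(m):
        fg = m.data > 0
        pts = []
        for idx in np.argwhere(fg):
            i, j, k = idx
            for o in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                ni, nj, nk = idx + np.array(o)
                if (
                    not (0 <= ni < fg.shape[0] and 0 <= nj < fg.shape[1]
                         and 0 <= nk < fg.shape[2])
                    or not fg[ni, nj, nk]
                ):
                    pts.append(idx)
                    break
        return m.index_to_world(np.array(pts, dtype=float))

    pa, pb = boundary(a), boundary(b)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    d_ab, d_ba = d.min(axis=1), d.min(axis=0)
    hd = max(d_ab.max(), d_ba.max())
    asd = 0.5 * (d_ab.mean() + d_ba.mean())
    return hd, asd


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        arr = np.zeros((6, 6, 6)); arr[2:4, 2:4, 2:4] = 1
        m = lab(arr)
        assert hausdorff(m, m) == 0.0
        assert avg_surface_distance(m, m) == 0.0

    def test_single_voxels_5mm_apart(self):
        a = np.zeros((8, 8, 8)); a[1, 1, 1] = 1
        b = np.zeros((8, 8, 8)); b[4, 5, 1] = 1  # displacement (3, 4, 0)
        assert hausdorff(lab(a), lab(b)) == pytest.approx(5.0)
        assert avg_surface_distance(lab(a), lab(b)) == pytest.approx(5.0)

    def test_translated_block_matches_brute_force(self):
        arr = np.zeros((12, 12, 12)); arr[2:6, 3:7, 4:8] = 1
        shifted = np.roll(arr, 3, axis=0)
        a, b = lab(arr), lab(shifted)
        hd_o, asd_o = brute_surface_distances(a, b)
        assert hausdorff(a, b) == pytest.approx(hd_o, abs=1e-9)
        assert avg_surface_distance(a, b) == pytest.approx(asd_o, abs=1e-9)
        assert hausdorff(a, b) == pytest.approx(3.0, abs=1e-9)

    def test_random_masks_match_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = lab(rng.random((8, 8, 8)) < 0.2)
            b = lab(rng.random((8, 8, 8)) < 0.2)
            if a.data.sum() == 0 or b.data.sum() == 0:
                continue
            hd_o, asd_o = brute_surface_distances(a, b)
            assert hausdorff(a, b) == pytest.approx(hd_o, abs=1e-9)
            assert avg_surface_distance(a, b) == pytest.approx(asd_o, abs=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(DomainError):
            hausdorff(lab(np.zeros((3, 3, 3))), lab(np.ones((3, 3, 3))))


class TestSectionReport:
    def test_partition_and_consistency_invariants(self, lunate_phantom):
        t1_map, mask, truth, sphere, frame = lunate_phantom
        labeling = section_label(mask, frame, sphere, n_sectors=4)
        rep = build_section_report(t1_map, mask, labeling, sphere, n_points=20_000)
        overall = rep[rep.row == "overall"].iloc[0]
        assert overall.volume_mm3 == overall.voxel_count * mask.voxel_volume
        sectors = rep[rep.row == "sector_marginal"]
        assert sectors.volume_mm3.sum() == pytest.approx(overall.volume_mm3)
        assert sectors.voxel_count.sum() == overall.voxel_count
        # thickness x surface = volume by definition
        for _, row in rep.iterrows():
            if row.surface_mm2 > 0:
                assert row.thickness_mm * row.surface_mm2 == pytest.approx(
                    row.volume_mm3
                )

    def test_sector_only_report_has_sector_rows_plus_overall(self, lunate_phantom):
        t1_map, mask, truth, sphere, frame = lunate_phantom
        labeling = section_label(mask, frame, sphere, n_sectors=4,
                                 layers=False, regions=False)
        rep = build_section_report(t1_map, mask, labeling, sphere, n_points=10_000)
        assert len(rep) == 5
        assert list(rep.row) == ["overall"] + ["section"] * 4
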