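"""Image-quantification tests: segmentation, particles, hull, density,
boundary error, and full render→measure round trips."""

import numpy as np
import pytest
from shapely.geometry import box

import frictionpad as fp
from frictionpad.imquant import (
    ContactImage,
    boundary_error,
    density_estimate,
    hull_polygon,
    particle_analysis,
    projected_area,
    quantify_image,
    segment,
)
from frictionpad.synthgen import render_patches


class TestSegment:
    def test_blank_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment(np.full((10, 10), 0.3))
        assert not mask.any()

    def test_idempotent_on_binary(self):
        rng = np.random.default_rng(0)
        img = (rng.random((20, 20)) > 0.7).astype(float)
        m1 = segment(img)
        m2 = segment(m1)
        assert np.array_equal(m1, m2)

    def test_matches_ground_truth_mask(self):
        rng = np.random.default_rng(1)
        centers = rng.uniform(2, 18, (30, 2))
        img = render_patches(centers, np.full(30, 0.3), np.ones(30),
                             np.zeros(30), pixel_scale=0.05, noise_sd=0.02,
                             seed=2, region=(0, 0, 20, 20))
        mask = segment(img)
        # analytic ground truth: pixel centres inside any disc
        yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
        px = (xx + 0.5) * 0.05
        py = (yy + 0.5) * 0.05
        r = np.sqrt(0.3 / np.pi)
        truth = np.zeros_like(mask)
        for cx, cy in centers:
            truth |= (px - cx) ** 2 + (py - cy) ** 2 <= r**2
        agreement = np.mean(mask == truth)
        assert agreement >= 0.99

    def test_fixed_threshold_method(self):
        img = np.linspace(0, 1, 100).reshape(10, 10)
        mask = segment(img, method="fixed", threshold=0.5)
        assert mask.sum() == (img > 0.5).sum()


class TestParticleAnalysis:
    def test_disc_area_matches_pi_r_squared(self):
        # r chosen so that pi r^2 = 0.235 um^2
        r = np.sqrt(0.235 / np.pi)
        scale = 0.01
        n = int(np.ceil(2 * r / scale)) + 6
        yy, xx = np.mgrid[0:n, 0:n]
        c = n / 2
        mask = ((xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2) <= (r / scale) ** 2
        table = particle_analysis(mask, scale)
        assert len(table) == 1
        # within one perimeter-pixel band of the analytic area
        band = 2 * np.pi * r * scale
        assert abs(table.area_um2[0] - 0.235) <= band

    def test_diagonal_touch_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(particle_analysis(mask, 1.0, connectivity=8)) == 1
        assert len(particle_analysis(mask, 1.0, connectivity=4)) == 2

    def test_empty_mask_gives_empty_table(self):
        table = particle_analysis(np.zeros((5, 5), dtype=bool), 0.05)
        assert len(table) == 0

    def test_tiny_spots_flagged_unreliable(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2:4] = True  # 2 px
        table = particle_analysis(mask, 0.05)
        assert bool(table.unreliable_aspect[0])

    def test_rendered_ellipse_aspect_recovered(self):
        img = render_patches([[5, 5]], [1.0], [3.0], [1.1], pixel_scale=0.05)
        table = particle_analysis(segment(img), 0.05)
        assert table.aspect_ratio[0] == pytest.approx(3.0, rel=0.05)


class TestProjectedArea:
    def test_four_corner_spots_of_a_100um_square(self):
        scale = 1.0
        mask = np.zeros((102, 102), dtype=bool)
        for r, c in [(0, 0), (0, 100), (100, 0), (100, 100)]:
            mask[r, c] = True
        assert projected_area(mask, scale) == pytest.approx(0.01)

    def test_empty_input_is_zero(self):
        assert projected_area(np.zeros((5, 5), dtype=bool), 0.05) == 0.0

    def test_adding_a_spot_never_shrinks_the_hull(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((50, 50), dtype=bool)
        prev = 0.0
        for _ in range(10):
            r, c = rng.integers(0, 50, 2)
            mask[r, c] = True
            area = projected_area(mask, 0.5)
            assert area >= prev - 1e-15
            prev = area

    def test_matches_simulator_internal_projected_area(self):
        # fully render a small pad and compare hull areas
        pad = fp.PadGeometry(dome_radius=800.0, footprint_area=900.0)
        bed = fp.make_fibril_bed(0.19, pad, tip_height_sd=1.0, seed=5)
        state = fp.solve_indentation(bed, pad, 0.05)
        img = fp.render_contact_image(state, pixel_scale=0.05,
                                      region=(-20, -20, 20, 20))
        mask = segment(img)
        measured = projected_area(mask, img.pixel_scale) * 1e6  # um^2
        assert measured == pytest.approx(state.A_A, rel=0.02)


class TestDensityEstimate:
    def test_regular_grid_recovers_packing_density(self):
        s = 2.294
        n = 20
        xy = np.array([[(i + 0.5) * s, (j + 0.5) * s]
                       for i in range(n) for j in range(n)])
        import pandas as pd

        table = pd.DataFrame({"centroid_x_um": xy[:, 0],
                              "centroid_y_um": xy[:, 1]})
        hull = box(0, 0, n * s, n * s)
        d = density_estimate(table, hull, sample_fraction=1.0)
        assert d == pytest.approx(1 / s**2, rel=1e-9)
        assert d == pytest.approx(0.190, abs=0.0005)

    def test_empty_table_is_zero(self):
        import pandas as pd

        assert density_estimate(pd.DataFrame(columns=["centroid_x_um",
                                                      "centroid_y_um"]),
                                box(0, 0, 10, 10), 1.0) == 0.0

    def test_zero_hull_area_rejected(self):
        import pandas as pd

        table = pd.DataFrame({"centroid_x_um": [1.0], "centroid_y_um": [1.0]})
        with pytest.raises(ValueError):
            density_estimate(table, box(0, 0, 0, 0), 0.5)

    def test_quarter_area_subsampling_within_ten_percent(self):
        # >=500 spots; the 25% protocol estimate stays near the exact density
        import pandas as pd

        rng = np.random.default_rng(4)
        L = 60.0
        pts = rng.uniform(0, L, (720, 2))
        table = pd.DataFrame({"centroid_x_um": pts[:, 0],
                              "centroid_y_um": pts[:, 1]})
        hull = box(0, 0, L, L)
        exact = 720 / L**2
        errors = [abs(density_estimate(table, hull, 0.25, seed=s) / exact - 1)
                  for s in range(20)]
        assert np.mean(np.array(errors) <= 0.10) >= 0.9
        assert np.median(errors) <= 0.10


class TestBoundaryError:
    def test_smallest_circular_contact_has_75_percent_error(self):
        assert boundary_error(0.12, 0.15) == pytest.approx(0.75, abs=0.03)

    def test_error_vanishes_for_large_areas(self):
        assert boundary_error(1e6, 0.15) < 1e-3
        a = np.logspace(-1, 3, 20)
        errs = [boundary_error(x, 0.15) for x in a]
        assert np.all(np.diff(errs) < 0)

    def test_elongated_spot_has_larger_error_than_equal_area_circle(self):
        area = 0.5
        b = np.sqrt(area / (np.pi * 4.0))
        a = 4.0 * b
        # Ramanujan approximation of the ellipse perimeter
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert boundary_error(area, 0.15, perimeter_um=perim) \
            > boundary_error(area, 0.15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            boundary_error(0.0, 0.15)
        with pytest.raises(ValueError):
            boundary_error(1.0, -0.1)


class TestFullRoundTrip:
    def test_scene_of_250_spots_recovers_count_area_density(self):
        """Mean per-spot area within 5%, density within 10%, count exact."""
        rng = np.random.default_rng(6)
        s = 2.4  # jittered grid, no merging
        n_side = 16
        centers = np.array([[(i + 0.5) * s, (j + 0.5) * s]
                            for i in range(n_side) for j in range(n_side)])
        centers += rng.uniform(-0.4, 0.4, centers.shape)
        n = len(centers)  # 256 spots
        areas = rng.uniform(0.15, 0.45, n)
        img = render_patches(centers, areas, np.ones(n), np.zeros(n),
                             pixel_scale=0.05, noise_sd=0.02, seed=7,
                             region=(0, 0, n_side * s, n_side * s))
        table, summary = quantify_image(img)
        assert summary["n_spots"] == n
        assert summary["A_Ac_um2"] == pytest.approx(areas.mean(), rel=0.05)
        hull = hull_polygon(segment(img), img.pixel_scale)
        exact_density = n / hull.area
        assert summary["N_A_per_um2"] == pytest.approx(exact_density, rel=0.10)


class TestContactImageIO:
    def test_tiff_save_load_round_trip(self, tmp_path):
        img = render_patches([[3, 3]], [0.5], [2.0], [0.3], pixel_scale=0.05,
                             noise_sd=0.01, seed=8)
        path = tmp_path / "img.tif"
        img.save(path)
        back = ContactImage.load(path)
        assert back.pixel_scale == img.pixel_scale
        assert np.allclose(back.pixels, img.pixels, atol=1 / 65535)

    def test_load_without_sidecar_fails(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "x.tif", np.zeros((4, 4), dtype=np.uint16))
        with pytest.raises(ValueError, match="pixel scale"):
            ContactImage.load(tmp_path / "x.tif")
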