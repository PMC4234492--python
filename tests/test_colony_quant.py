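import numpy as np
import pytest
from skimage import draw as skdraw

from colonyarray import colony_quant as cq
from colonyarray import synthetic_fixtures as sf

from conftest import ground_truth_cell_counts


class TestAutoThreshold:
    def test_two_delta_histogram_fixed_point(self):
        # exhaustive-scan oracle: the intermeans fixed point t satisfies
        # t == round((mean_below + mean_above)/2); for equal-mass deltas
        # at 50 and 200 the only fixed point is 125
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:5] = 50
        img[5:] = 200
        fixed_points = []
        for t in range(50, 200):
            below = img[img <= t]
            above = img[img > t]
            if below.size and above.size:
                if int(round((below.mean() + above.mean()) / 2)) == t:
                    fixed_points.append(t)
        assert fixed_points == [125]
        assert cq.auto_threshold(img) == 125

    def test_constant_image_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            cq.auto_threshold(np.full((8, 8), 42, dtype=np.uint8))

    def test_separates_synthetic_modes(self):
        spec = sf.PlateSpec(noise_sd=5.0, seed=3)
        img, _ = sf.render_plate(spec)
        inv = (255 - img).astype(np.uint8)
        level = cq.auto_threshold(inv)
        truth_mask = img > (spec.background_level + spec.colony_level) / 2
        recovered = (inv < level) & truth_mask
        assert recovered.sum() / truth_mask.sum() >= 0.99


class TestFindParticles:
    def test_disk_centroid_and_area_match_drawn_pixels(self):
        img = np.zeros((200, 200), dtype=bool)
        rr, cc = skdraw.disk((100, 100), 10)
        img[rr, cc] = True
        drawn_count = rr.size  # brute-force pixel count of the drawn disk
        [p] = cq.find_particles(img)
        assert p.area == drawn_count
        assert abs(p.cx - 100) < 0.5 and abs(p.cy - 100) < 0.5
        assert p.circularity > 0.8

    def test_empty_region_gives_empty_list(self):
        img = np.zeros((50, 50), dtype=bool)
        assert cq.find_particles(img) == []

    def test_min_area_filters_specks(self):
        img = np.zeros((100, 100), dtype=bool)
        rr, cc = skdraw.disk((30, 30), 8)
        img[rr, cc] = True
        img[80, 80] = img[80, 81] = True  # 2-pixel speck
        parts = cq.find_particles(img, min_area=20)
        assert len(parts) == 1
        assert parts[0].area == rr.size

    def test_region_restriction(self):
        img = np.zeros((100, 100), dtype=bool)
        rr, cc = skdraw.disk((20, 20), 5)
        img[rr, cc] = True
        rr, cc = skdraw.disk((80, 80), 5)
        img[rr, cc] = True
        parts = cq.find_particles(img, region=(0, 0, 50, 50))
        assert len(parts) == 1
        assert parts[0].cx < 50


class TestLocateGrid:
    def test_axis_aligned_recovery(self, preset_18, uniform_render):
        spec, img, _ = uniform_render
        binary = (255 - img) < 125
        fit = cq.locate_grid(binary, preset_18)
        assert abs(fit.origin_x - spec.origin[0]) < 1.0
        assert abs(fit.origin_y - spec.origin[1]) < 1.0
        assert fit.rotation == 0.0
        assert abs(fit.dx - 18.0) < 0.2 and abs(fit.dy - 18.0) < 0.2

    def test_rotated_plate_recovered_with_rotation(self, preset_18):
        spec = sf.PlateSpec(noise_sd=5.0, seed=4, rotation=2.0)
        img, _ = sf.render_plate(spec)
        binary = (255 - img) < 125
        fit = cq.locate_grid(binary, preset_18, allow_rotation=True)
        assert abs(fit.rotation - 2.0) <= 0.5

    def test_missing_corner_colonies_still_fit(self, preset_18):
        missing = frozenset({(1, 1), (1, 48), (32, 1), (32, 48)})
        spec = sf.PlateSpec(noise_sd=5.0, seed=5, missing=missing)
        img, _ = sf.render_plate(spec)
        binary = (255 - img) < 125
        fit = cq.locate_grid(binary, preset_18)
        assert abs(fit.origin_x - spec.origin[0]) < 1.0
        assert abs(fit.origin_y - spec.origin[1]) < 1.0

    def test_blank_image_raises(self, preset_18):
        with pytest.raises(cq.GridNotFoundError):
            cq.locate_grid(np.zeros((618, 906), dtype=bool), preset_18,
                           allow_rotation=False)


class TestThresholdWithRetry:
    def test_auto_level_success_keeps_auto_level(self, preset_18,
                                                 uniform_render):
        _, img, _ = uniform_render
        inv = (255 - img).astype(np.uint8)
        auto = cq.auto_threshold(inv)
        _, level, _ = cq.threshold_with_retry(inv, preset_18)
        assert level == auto

    def test_blank_agar_unthresholdable(self, preset_18):
        rng = np.random.default_rng(0)
        agar = rng.normal(215, 5, (618, 906)).clip(0, 255).astype(np.uint8)
        with pytest.raises(cq.GridNotFoundError, match="unthresholdable"):
            cq.threshold_with_retry(agar, preset_18, allow_rotation=False)


class TestAssignAndMeasure:
    GRID = cq.GridFit(origin_x=30, origin_y=30, dx=18, dy=18)
    PRESET = cq.GridPreset(4, 4, 18, 18)

    def test_particle_on_node_assigned(self):
        p = cq.Particle(cx=30.0, cy=30.0, area=100, circularity=0.95)
        pm = cq.assign_and_measure([p], self.GRID, self.PRESET)
        assert pm.areas[0, 0] == 100
        assert pm.status[0, 0] == "auto"

    def test_quarter_cell_rule_rejects_offset(self):
        p = cq.Particle(cx=30.0 + 0.3 * 18, cy=30.0, area=100,
                        circularity=0.95)
        pm = cq.assign_and_measure([p], self.GRID, self.PRESET)
        assert pm.areas[0, 0] == 0
        assert pm.status[0, 0] == "empty"

    def test_nearest_of_two_candidates_wins(self):
        near = cq.Particle(cx=31.0, cy=30.0, area=90, circularity=0.9)
        far = cq.Particle(cx=33.0, cy=30.0, area=200, circularity=0.9)
        pm = cq.assign_and_measure([far, near], self.GRID, self.PRESET)
        assert pm.areas[0, 0] == 90

    def test_circularity_floor(self):
        p = cq.Particle(cx=30.0, cy=30.0, area=100, circularity=0.5)
        pm = cq.assign_and_measure([p], self.GRID, self.PRESET)
        assert pm.status[0, 0] == "empty"


class TestRescan:
    def test_smeared_colony_recovered_low_stringency(self, preset_18):
        # ellipse with 4:1 axis ratio fails the 0.8 circularity criterion
        # on the first pass, then is recovered with min_circularity 0
        spec = sf.PlateSpec(noise_sd=0.0, seed=6, base_radius=4.0,
                            smeared={(5, 5): 4.0})
        img, truth = sf.render_plate(spec)
        pm = cq.measure_plate(img, preset_18)
        assert pm.status[4, 4] == "low_stringency"
        assert pm.areas[4, 4] > 0

    def test_truly_empty_cell_stays_empty(self, preset_18):
        spec = sf.PlateSpec(noise_sd=0.0, seed=7, missing=frozenset({(3, 3)}))
        img, _ = sf.render_plate(spec)
        pm = cq.measure_plate(img, preset_18)
        assert pm.status[2, 2] == "empty"
        assert pm.areas[2, 2] == 0

    def test_small_blemish_below_min_pixels_ignored(self, preset_18):
        spec = sf.PlateSpec(noise_sd=0.0, seed=8, missing=frozenset({(3, 3)}))
        img, _ = sf.render_plate(spec)
        # plant a 3x3 blemish (9 px < rescan_min_pixels) in the empty cell
        y = int(spec.origin[1] + 2 * spec.dy)
        x = int(spec.origin[0] + 2 * spec.dx)
        img[y - 1:y + 2, x - 1:x + 2] = spec.colony_level
        pm = cq.measure_plate(img, preset_18)
        assert pm.status[2, 2] == "empty"


@pytest.mark.parametrize("n_bad, fail_at, expected", [
    (0, 76, "ok"),
    (3, 76, "warn"),
    (100, 76, "fail"),
])
def test_classify_plate_thresholds(n_bad, fail_at, expected):
    status = np.full((32, 48), "auto", dtype="U14")
    status.flat[:n_bad] = "bad"
    pm = cq.PlateMeasurement(
        base_name="x", set_number=1, plate_number=1, rows=32, cols=48,
        areas=np.ones((32, 48), dtype=int), status=status)
    pm.areas[status == "bad"] = 0
    assert cq.classify_plate(pm, fail_threshold=fail_at) == expected


class TestRawFile:
    def test_round_trip_identity(self, tmp_path, preset_18, uniform_render):
        _, img, _ = uniform_render
        pm = cq.measure_plate(img, preset_18, base_name="scr", set_number=2,
                              plate_number=3)
        path = tmp_path / "scr_set-2_plate-3.txt"
        cq.write_raw_file(pm, path)
        back = cq.read_raw_file(path)
        assert back.base_name == "scr"
        assert back.set_number == 2 and back.plate_number == 3
        np.testing.assert_array_equal(back.areas, pm.areas)
        np.testing.assert_array_equal(back.status, pm.status)

    def test_missing_metadata_header_raises(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("row\tcol\tarea\tstatus\n1\t1\t5\tauto\n")
        with pytest.raises(ValueError, match="metadata"):
            cq.read_raw_file(path)

    def test_hand_written_fixture(self, tmp_path):
        path = tmp_path / "fix.txt"
        path.write_text(
            "# base_name\tfix\n# set\t1\n# plate\t1\n"
            "row\tcol\tarea\tstatus\n"
            "1\t1\t120\tauto\n1\t2\t0\tempty\n"
            "2\t1\t95\tlow_stringency\n2\t2\t130\tauto\n")
        pm = cq.read_raw_file(path)
        assert pm.rows == 2 and pm.cols == 2
        assert pm.areas.tolist() == [[120, 0], [95, 130]]
        assert pm.status[1, 0] == "low_stringency"


class TestMeasurementInvariants:
    def test_uniform_background_offset_invariance(self, preset_18):
        spec = sf.PlateSpec(noise_sd=0.0, seed=9)
        img, _ = sf.render_plate(spec)
        pm1 = cq.measure_plate(img, preset_18)
        shifted = np.clip(img.astype(int) - 20, 0, 255).astype(np.uint8)
        pm2 = cq.measure_plate(shifted, preset_18)
        np.testing.assert_array_equal(pm1.areas, pm2.areas)

    def test_areas_match_truth_for_radius_ge_4(self, preset_18):
        spec = sf.PlateSpec(noise_sd=5.0, seed=10, base_radius=4.0)
        img, truth = sf.render_plate(spec)
        pm = cq.measure_plate(img, preset_18)
        rel = np.abs(pm.areas - truth) / truth
        assert rel.max() <= 0.05

    def test_two_path_concordance(self, preset_18):
        # engine measurement vs naive per-cell pixel counting on the
        # ground-truth mask: independent paths, R^2 > 0.99
        spec = sf.PlateSpec(noise_sd=5.0, seed=11, base_radius=4.5,
                            corner_boost=1.3,
                            gradient=((0.9, 1.1), (0.85, 1.15)))
        img, _ = sf.render_plate(spec)
        pm = cq.measure_plate(img, preset_18)
        oracle = ground_truth_cell_counts(img, spec)
        a, b = pm.areas.ravel().astype(float), oracle.ravel().astype(float)
        r = np.corrcoef(a, b)[0, 1]
        assert r ** 2 > 0.99
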