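"""Detection-volume integration, sector extrapolation, optimization sweep."""

import numpy as np
import pytest

import batradar as br
from batradar.field import detection_height_at
from batradar.volume import write_sweep_table


def brute_force_volume(mask: br.VisibilityMask, boundary, a_px: float) -> float:
    """Independent oracle: naive per-pixel double loop over the image."""
    total = 0.0
    rows, cols = mask.mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask.mask[r, c]:
                total += a_px * detection_height_at(boundary, mask.distances_m[r, c])
    return total


@pytest.fixture(scope="module")
def boundary(calibrated, pattern, pmin):
    sigma = br.rcs_from_range(calibrated, 800.0)
    return br.extract_boundary(br.simulate_field(calibrated, pattern, sigma), pmin)


class TestIntegrateVolume:
    def test_single_pixel(self):
        flat = br.DetectionBoundary(
            distances_m=np.array([100.0]),
            intervals=(((0.0, 100.0),),),
            max_range_m=1000.0,
        )
        mask_arr = np.zeros((3, 3), dtype=bool)
        mask_arr[0, 2] = True
        mask = br.VisibilityMask(
            mask=mask_arr,
            distances_m=np.full((3, 3), 50.0),
            meters_per_pixel=3.027,
        )
        sector = br.SectorSpec(0, 0, 1000.0)
        result = br.integrate_volume(mask, flat, sector)
        assert result.total_volume_m3 == pytest.approx(3.027**2 * 100.0)
        assert result.visible_pixel_count == 1

    def test_empty_mask_zero_volume(self, boundary):
        mask = br.VisibilityMask(
            mask=np.zeros((5, 5), dtype=bool),
            distances_m=np.full((5, 5), 100.0),
            meters_per_pixel=3.027,
        )
        result = br.integrate_volume(mask, boundary, br.SectorSpec(0, 0, 1e3))
        assert result.total_volume_m3 == 0.0
        assert result.visible_pixel_count == 0

    def test_matches_brute_force_oracle(self, boundary):
        rng = np.random.default_rng(9)
        img = br.PpiImage(
            levels=rng.integers(0, 32, (48, 48)),
            meters_per_pixel=3.027,
            radar_origin=(24, 24),
        )
        sector = br.SectorSpec(25.0, 120.0, 140.0)
        mask = br.visibility_mask(img, sector, 10)
        result = br.integrate_volume(mask, boundary, sector)
        oracle = brute_force_volume(mask, boundary, img.pixel_area_m2)
        assert result.total_volume_m3 == pytest.approx(oracle, rel=1e-12)

    def test_clutter_free_annulus_constant_height(self):
        # k clutter-free pixels over a flat boundary -> V = k * A_px * h
        flat = br.DetectionBoundary(
            distances_m=np.array([50.0, 5000.0]),
            intervals=(((0.0, 120.0),), ((0.0, 120.0),)),
            max_range_m=10000.0,
        )
        img = br.PpiImage(
            levels=np.zeros((41, 41), dtype=int),
            meters_per_pixel=3.027,
            radar_origin=(20, 20),
        )
        sector = br.SectorSpec(0.0, 90.0, 60.0)
        mask = br.visibility_mask(img, sector, 0)
        result = br.integrate_volume(mask, flat, sector)
        k = mask.visible_count
        assert result.total_volume_m3 == pytest.approx(k * img.pixel_area_m2 * 120.0)

    def test_pixels_beyond_max_range_contribute_zero(self, boundary):
        img = br.PpiImage(
            levels=np.zeros((3, 3), dtype=int),
            meters_per_pixel=1000.0,  # pixels 1 km apart: all beyond max range
            radar_origin=(1, 1),
        )
        sector = br.SectorSpec(0, 0, 5e3)
        mask = br.visibility_mask(img, sector, 0)
        assert mask.visible_count == 8
        result = br.integrate_volume(mask, boundary, sector)
        assert result.total_volume_m3 == 0.0


class TestSectorExtrapolation:
    def test_abstract_arithmetic(self):
        # 0.0105 km3 over 105 deg -> 0.036 km3 full circle
        full = br.sector_extrapolate(0.0105e9, 360.0, 105.0)
        assert full / 1e9 == pytest.approx(0.036, rel=1e-9)

    def test_identity_at_own_angle(self):
        assert br.sector_extrapolate(123.0, 105.0, 105.0) == pytest.approx(123.0)

    def test_linear_in_target_angle(self):
        v1 = br.sector_extrapolate(50.0, 90.0, 45.0)
        v2 = br.sector_extrapolate(50.0, 180.0, 45.0)
        assert v2 == pytest.approx(2 * v1)

    def test_zero_sector_angle_rejected(self):
        with pytest.raises(ValueError):
            br.sector_extrapolate(1.0, 360.0, 0.0)


class TestAcousticComparison:
    def test_hemisphere_40_m(self):
        assert br.acoustic_hemisphere_volume(40.0) == pytest.approx(1.3404e5, rel=1e-4)

    def test_unit_hemisphere(self):
        assert br.acoustic_hemisphere_volume(1.0) == pytest.approx(2 * np.pi / 3, rel=1e-12)

    def test_cubic_scaling(self):
        assert br.acoustic_hemisphere_volume(2.0) == pytest.approx(
            8 * br.acoustic_hemisphere_volume(1.0), rel=1e-12
        )

    def test_study_ratio_rounds_to_270(self):
        raw, rounded = br.volume_ratio_vs_acoustic(0.0105e9, 105.0, 40.0)
        assert raw == pytest.approx(268.6, abs=0.1)
        assert rounded == 270

    def test_ratio_scales_linearly_with_volume(self):
        r1, _ = br.volume_ratio_vs_acoustic(1e7, 105.0, 40.0)
        r2, _ = br.volume_ratio_vs_acoustic(2e7, 105.0, 40.0)
        assert r2 == pytest.approx(2 * r1)

    def test_ratio_inverse_cubic_in_mic_radius(self):
        r1, _ = br.volume_ratio_vs_acoustic(1e7, 105.0, 40.0)
        r2, _ = br.volume_ratio_vs_acoustic(1e7, 105.0, 80.0)
        assert r1 == pytest.approx(8 * r2)


@pytest.fixture(scope="module")
def sweep_inputs(calibrated, pattern, pmin, csf):
    scene = br.SceneSpec(
        shape=(160, 160),
        radar_origin=(80, 80),
        blobs=(
            br.ClutterBlob(center=(50, 110), radius_px=18, base_level=14, fluctuation=0),
            br.ClutterBlob(center=(95, 120), radius_px=10, base_level=10, fluctuation=0),
        ),
        seed=21,
    )
    sector = br.SectorSpec(25.0, 120.0, 230.0)
    return calibrated, pattern, pmin, csf, scene, sector


class TestOptimizationSweep:
    def test_fence_pair_ratio_exceeds_one(self, sweep_inputs):
        calibrated, pattern, pmin, csf, scene, sector = sweep_inputs
        rows = br.optimization_sweep(
            calibrated, pattern, 12.7e-4, pmin, sector, csf,
            h_cfr_values_m=[0.2],
            thresholds=[8],
            image_pair_fn=lambda g: br.render_csf_pair(scene, g, calibrated),
        )
        assert len(rows) == 1
        assert rows[0]["ratio"] > 1.0

    def test_volume_monotone_in_threshold(self, sweep_inputs):
        calibrated, pattern, pmin, csf, scene, sector = sweep_inputs
        rows = br.optimization_sweep(
            calibrated, pattern, 12.7e-4, pmin, sector, csf,
            h_cfr_values_m=[0.16],
            thresholds=[0, 8, 16, 24],
            image_pair_fn=lambda g: br.render_csf_pair(scene, g, calibrated),
        )
        vols_no = [r["volume_no_csf_m3"] for r in rows]
        vols_csf = [r["volume_csf_m3"] for r in rows]
        assert vols_no == sorted(vols_no)
        assert vols_csf == sorted(vols_csf)

    def test_table_export(self, tmp_path, sweep_inputs):
        calibrated, pattern, pmin, csf, scene, sector = sweep_inputs
        rows = br.optimization_sweep(
            calibrated, pattern, 12.7e-4, pmin, sector, csf,
            h_cfr_values_m=[0.2],
            thresholds=[8],
            image_pair_fn=lambda g: br.render_csf_pair(scene, g, calibrated),
        )
        path = tmp_path / "sweep.tsv"
        write_sweep_table(rows, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t")[0] == "h_cfr_m"
        assert len(lines) == 2

    def test_empty_sweep_sets_rejected(self, sweep_inputs):
        calibrated, pattern, pmin, csf, scene, sector = sweep_inputs
        with pytest.raises(ValueError):
            br.optimization_sweep(
                calibrated, pattern, 12.7e-4, pmin, sector, csf,
                h_cfr_values_m=[], thresholds=[8],
                image_pair_fn=lambda g: br.render_csf_pair(scene, g, calibrated),
            )
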