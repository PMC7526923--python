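"""2D detection-field simulation and boundary extraction."""

import math

import numpy as np
import pytest

import batradar as br
from batradar.field import detection_heights


@pytest.fixture(scope="module")
def bat_sigma(calibrated):
    return br.rcs_from_range(calibrated, 800.0)


@pytest.fixture(scope="module")
def simple_field(calibrated, pattern, bat_sigma):
    return br.simulate_field(calibrated, pattern, bat_sigma)


@pytest.fixture(scope="module")
def advanced_field(calibrated, pattern, bat_sigma, csf):
    return br.simulate_field(calibrated, pattern, bat_sigma, csf)


class TestSimulateField:
    def test_boresight_cell_at_max_range_hits_pmin(self, simple_field, pmin, calibrated):
        # the cell (800 m, antenna height) sits exactly on the detection
        # threshold for the bat-model RCS
        j = int(np.argmin(np.abs(simple_field.distances_m - 800.0)))
        i = int(np.argmin(np.abs(simple_field.heights_m - calibrated.antenna_height_m)))
        p_dbm = 10 * math.log10(simple_field.power_w[i, j] / 1e-3)
        assert p_dbm == pytest.approx(pmin.dbm, abs=0.05)

    def test_advanced_ground_cells_suppressed_two_way(
        self, simple_field, advanced_field, csf, calibrated
    ):
        # ground-level (h = 0) cells lose at least twice the one-way
        # knife-edge suppression
        d_common = advanced_field.distances_m
        j_adv = int(np.argmin(np.abs(d_common - 500.0)))
        j_sim = int(np.argmin(np.abs(simple_field.distances_m - 500.0)))
        loss_db = 10 * math.log10(
            simple_field.power_w[0, j_sim] / advanced_field.power_w[0, j_adv]
        )
        assert loss_db >= 20.0

    def test_modes_agree_far_above_edge(self, simple_field, advanced_field, csf, calibrated):
        # where the ray clears the edge by many Fresnel zones the fence
        # is invisible to within the residual interference ripple, whose
        # two-way amplitude decays like 4/(pi*|v1|)
        lam = calibrated.wavelength_m
        d = advanced_field.distances_m
        h = advanced_field.heights_m
        v1 = br.edge_fresnel_v(csf, d[None, :], h[:, None], lam)
        deep_clear = v1 < -10.0
        sim = simple_field.power_w[:, np.isin(simple_field.distances_m, d)]
        ratio_db = 10 * np.log10(advanced_field.power_w[deep_clear] / sim[deep_clear])
        assert np.abs(ratio_db).max() < 0.5

    def test_fence_inside_grid_rejected(self, calibrated, pattern, bat_sigma, csf):
        with pytest.raises(ValueError, match="fence radius"):
            br.simulate_field(
                calibrated, pattern, bat_sigma, csf, distances_m=[5.0, 10.0]
            )

    def test_nonpositive_sigma_rejected(self, calibrated, pattern):
        with pytest.raises(ValueError):
            br.simulate_field(calibrated, pattern, 0.0)


class TestExtractBoundary:
    def test_bat_model_max_range_near_800(self, simple_field, pmin):
        boundary = br.extract_boundary(simple_field, pmin)
        assert boundary.max_range_m == pytest.approx(800.0, abs=5.0)

    def test_isotropic_boundary_is_circular_arc(self, calibrated, isotropic_pattern, pmin):
        # closed-form oracle: with isotropic gain, detectable iff slant
        # range <= R_max, so h(d) = h_R + sqrt(R_max^2 - d^2) (clipped at 0)
        sigma = 0.2e-4  # small target: R_max ~ 283 m, inside the height grid
        r_max = br.max_detection_range(calibrated, sigma)
        field = br.simulate_field(
            calibrated,
            isotropic_pattern,
            sigma,
            distances_m=np.arange(5.0, 400.0, 5.0),
            heights_m=np.arange(0.0, 300.0, 1.0),
        )
        boundary = br.extract_boundary(field, pmin)
        assert boundary.max_range_m == pytest.approx(r_max, abs=5.0)
        hr = calibrated.antenna_height_m
        for d in (50.0, 150.0, 250.0):
            expected = hr + math.sqrt(r_max**2 - d**2)
            got = br.detection_height_at(boundary, d)
            assert got == pytest.approx(expected, abs=2.0)

    def test_isotropic_height_decreases_toward_max_range(
        self, calibrated, isotropic_pattern, pmin
    ):
        sigma = 0.2e-4
        field = br.simulate_field(
            calibrated,
            isotropic_pattern,
            sigma,
            distances_m=np.arange(5.0, 400.0, 5.0),
            heights_m=np.arange(0.0, 300.0, 1.0),
        )
        boundary = br.extract_boundary(field, pmin)
        hs = [br.detection_height_at(boundary, d) for d in (50.0, 150.0, 250.0, 280.0)]
        assert hs == sorted(hs, reverse=True)

    def test_pmin_above_field_gives_empty_boundary(self, simple_field):
        boundary = br.extract_boundary(simple_field, br.PowerLevel.from_dbm(60.0))
        assert boundary.max_range_m == 0.0
        assert all(len(iv) == 0 for iv in boundary.intervals)

    def test_simple_mode_single_interval_from_ground(self, simple_field, pmin):
        boundary = br.extract_boundary(simple_field, pmin)
        for ivs in boundary.intervals:
            assert len(ivs) <= 1
            if ivs:
                assert ivs[0][0] == 0.0

    def test_advanced_mode_raised_lower_boundary(self, advanced_field, pmin):
        # behind the fence the ground shadow lifts the lower detection
        # boundary off the ground at large distance
        boundary = br.extract_boundary(advanced_field, pmin)
        j = int(np.argmin(np.abs(boundary.distances_m - 700.0)))
        ivs = boundary.intervals[j]
        assert ivs, "region should still be detectable at 700 m"
        assert ivs[0][0] > 0.0

    def test_advanced_ground_extent_never_exceeds_simple(
        self, simple_field, advanced_field, pmin, calibrated
    ):
        hr = calibrated.antenna_height_m
        b_sim = br.extract_boundary(simple_field, pmin)
        b_adv = br.extract_boundary(advanced_field, pmin)
        h = advanced_field.heights_m
        below = h < hr
        det_sim = simple_field.power_w >= pmin.watts
        det_adv = advanced_field.power_w >= pmin.watts
        common = np.isin(simple_field.distances_m, advanced_field.distances_m)
        assert np.all(
            det_adv[below, :].sum(axis=0) <= det_sim[np.ix_(below, common)].sum(axis=0)
        )


class TestDetectionHeight:
    def test_sum_of_interval_extents(self):
        boundary = br.DetectionBoundary(
            distances_m=np.array([100.0, 200.0]),
            intervals=((((30.0, 90.0)), ((110.0, 140.0))), ((0.0, 100.0),)),
            max_range_m=200.0,
        )
        assert br.detection_height_at(boundary, 100.0) == pytest.approx(90.0)
        assert br.detection_height_at(boundary, 200.0) == pytest.approx(100.0)

    def test_beyond_max_range_is_zero(self, simple_field, pmin):
        boundary = br.extract_boundary(simple_field, pmin)
        assert br.detection_height_at(boundary, boundary.max_range_m + 100.0) == 0.0

    def test_vectorized_matches_scalar(self, simple_field, pmin):
        boundary = br.extract_boundary(simple_field, pmin)
        qs = np.array([52.0, 313.0, 799.0, 1100.0])
        vec = detection_heights(boundary, qs)
        scalar = [br.detection_height_at(boundary, q) for q in qs]
        assert np.allclose(vec, scalar)


class TestGridRefinement:
    def test_halving_steps_stable(self, calibrated, pattern, pmin, bat_sigma):
        coarse = br.extract_boundary(
            br.simulate_field(
                calibrated, pattern, bat_sigma,
                distances_m=np.arange(10.0, 1000.0, 10.0),
                heights_m=np.arange(0.0, 300.0, 2.0),
            ),
            pmin,
        )
        fine = br.extract_boundary(
            br.simulate_field(
                calibrated, pattern, bat_sigma,
                distances_m=np.arange(5.0, 1000.0, 5.0),
                heights_m=np.arange(0.0, 300.0, 1.0),
            ),
            pmin,
        )
        assert abs(coarse.max_range_m - fine.max_range_m) <= 10.0
        for d in (100.0, 400.0, 700.0):
            assert abs(
                br.detection_height_at(coarse, d) - br.detection_height_at(fine, d)
            ) <= 4.0

    def test_boundary_export_round_trip_table(self, tmp_path, simple_field, pmin):
        boundary = br.extract_boundary(simple_field, pmin)
        path = tmp_path / "boundary.tsv"
        boundary.export(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0].split("\t") == ["distance_m", "interval_low_m", "interval_high_m"]
        assert len(rows) > 10
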