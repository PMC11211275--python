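"""AFM morphometry: dilation forward model, broadening correction, measurement."""

from __future__ import annotations

import numpy as np
import pytest

from fibriltrace import (
    DegenerateMeasurementWarning,
    TipModel,
    Topograph,
    classify_object,
    correct_tip_broadening,
    dilate_with_tip,
    extract_profile,
    measure_object,
    network_coverage,
    rms_roughness,
    segment_objects,
)
from fibriltrace.afm import ObjectMeasure, tip_broadening
from fibriltrace.synthgen import PlacedObject, TopographGenConfig, generate_topograph

TIP = TipModel(8.0)


def brute_force_dilation(heights: np.ndarray, px: float, radius: float) -> np.ndarray:
    """Independent oracle: direct max-scan of the spherical-cap tip."""
    half = int(np.ceil(radius / px))
    n, m = heights.shape
    out = np.full_like(heights, -np.inf)
    for di in range(-half, half + 1):
        for dj in range(-half, half + 1):
            d2 = (di * px) ** 2 + (dj * px) ** 2
            if d2 > radius**2:
                continue
            offset = np.sqrt(radius**2 - d2) - radius
            shifted = np.full_like(heights, -np.inf)
            i0, i1 = max(di, 0), min(n + di, n)
            j0, j1 = max(dj, 0), min(m + dj, m)
            shifted[i0 - di : i1 - di, j0 - dj : j1 - dj] = heights[i0:i1, j0:j1]
            out = np.maximum(out, shifted + offset)
    return out


def ridge_field(width_nm=8.0, height_nm=4.2, length_nm=120.0, shape=(128, 128), px=2.0,
                noise=0.0, tip_radius=8.0, seed=0):
    y = shape[0] * px / 2.0
    x0 = (shape[1] * px - length_nm) / 2.0
    obj = PlacedObject(
        object_class="fibril",
        polyline=np.array([[x0, y], [x0 + length_nm, y]]),
        width=width_nm,
        height=height_nm,
    )
    cfg = TopographGenConfig(
        shape=shape, pixel_size=px, substrate_rms=noise, tip_radius=tip_radius, objects=(obj,)
    )
    return generate_topograph(cfg, seed)


class TestDilation:
    def test_flat_surface_unchanged(self):
        t = Topograph(np.full((32, 32), 1.7), 2.0)
        np.testing.assert_allclose(dilate_with_tip(t, TIP).heights, 1.7)

    def test_single_spike_becomes_spherical_cap_mound(self):
        h, px = 4.0, 0.25
        heights = np.zeros((129, 129))
        heights[64, 64] = h
        d = dilate_with_tip(Topograph(heights, px), TIP)
        row = d.heights[64]
        base_radius_px = np.nonzero(row > 1e-12)[0]
        measured = (base_radius_px.max() - base_radius_px.min()) / 2.0 * px
        expected = np.sqrt(h * (2 * TIP.radius - h))  # sqrt(48) ~ 6.93 nm
        assert measured == pytest.approx(expected, abs=2 * px)

    def test_ridge_base_broadening_matches_closed_form(self):
        w, h, px = 8.0, 4.2, 0.5
        heights = np.zeros((64, 256))
        cols = np.abs((np.arange(256) - 128) * px) <= w / 2
        heights[:, cols] = h
        d = dilate_with_tip(Topograph(heights, px), TIP)
        base = np.nonzero(d.heights[32] > 1e-12)[0]
        measured = (base.size - 1) * px
        expected = w + 2 * np.sqrt(h * (2 * TIP.radius - h))
        assert measured == pytest.approx(expected, abs=2 * px)

    def test_matches_brute_force_oracle_on_random_surface(self, rng):
        heights = rng.uniform(0.0, 5.0, (40, 40))
        t = Topograph(heights, 1.0)
        expected = brute_force_dilation(heights, 1.0, TIP.radius)
        np.testing.assert_allclose(dilate_with_tip(t, TIP).heights, expected, atol=1e-9)

    def test_output_dominates_input(self, rng):
        heights = rng.uniform(0.0, 5.0, (64, 64))
        t = Topograph(heights, 2.0)
        assert np.all(dilate_with_tip(t, TIP).heights >= heights - 1e-12)

    def test_analytic_generator_surface_dominates_grid_dilation(self):
        truth, observed = ridge_field(noise=0.0)
        grid = dilate_with_tip(truth, TIP)
        assert np.all(observed.heights >= grid.heights - 1e-9)


class TestBroadeningCorrection:
    def test_printed_fibril_geometry_recovers_eight_nanometres(self):
        # h = 4.2 nm, R = 8 nm: broadening 2 sqrt(4.2 * 11.8) = 14.08 nm
        assert correct_tip_broadening(22.1, 4.2, TIP) == pytest.approx(8.0, abs=0.1)

    def test_zero_height_feature_unchanged(self):
        assert correct_tip_broadening(13.0, 0.0, TIP) == 13.0

    def test_overcorrection_clamps_to_zero_with_warning(self):
        with pytest.warns(DegenerateMeasurementWarning):
            assert correct_tip_broadening(5.0, 4.2, TIP) == 0.0

    def test_tall_feature_broadening_saturates_at_tip_diameter(self):
        assert tip_broadening(20.0, TIP) == pytest.approx(2 * TIP.radius)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            correct_tip_broadening(-1.0, 1.0, TIP)
        with pytest.raises(ValueError):
            correct_tip_broadening(1.0, -1.0, TIP)


class TestRoughness:
    def test_tilted_plane_is_flat_after_levelling(self):
        ii, jj = np.mgrid[0:64, 0:64]
        t = Topograph(0.01 * ii - 0.02 * jj + 3.0, 2.0)
        assert rms_roughness(t) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_substrate_noise_recovered(self, rng):
        t = Topograph(rng.normal(0.0, 0.2, (1024, 1024)), 2.0)
        assert rms_roughness(t) == pytest.approx(0.2, abs=0.01)

    def test_mask_excluding_object_matches_substrate_only(self, rng):
        noise = rng.normal(0.0, 0.2, (128, 128))
        with_ridge = noise.copy()
        with_ridge[60:68, :] += 4.2
        mask = np.ones((128, 128), dtype=bool)
        mask[55:73, :] = False
        got = rms_roughness(Topograph(with_ridge, 2.0), mask)
        want = rms_roughness(Topograph(noise, 2.0), mask)
        assert got == pytest.approx(want, abs=1e-9)

    def test_small_mask_rejected(self):
        t = Topograph(np.zeros((64, 64)), 2.0)
        mask = np.zeros((64, 64), dtype=bool)
        mask[0, :50] = True
        with pytest.raises(ValueError, match="100"):
            rms_roughness(t, mask)


class TestSegmentation:
    def test_empty_substrate_has_no_objects(self, rng):
        t = Topograph(rng.normal(0.0, 0.2, (256, 256)), 2.0)
        assert segment_objects(t).max() == 0

    def test_three_disjoint_ridges_give_three_labels(self):
        heights = np.zeros((128, 128))
        for r in (20, 60, 100):
            heights[r : r + 4, 20:100] = 4.2
        labels = segment_objects(Topograph(heights, 2.0))
        assert labels.max() == 3

    def test_crossing_fibrils_merge_into_one_label(self):
        heights = np.zeros((128, 128))
        heights[62:66, 10:118] = 4.2
        heights[10:118, 62:66] = 4.2
        labels = segment_objects(Topograph(heights, 2.0))
        assert labels.max() == 1

    def test_flat_elevated_plane_has_no_objects(self):
        # relief relative to the fitted plane is what matters, not absolute height
        assert segment_objects(Topograph(np.full((64, 64), 50.0), 2.0)).max() == 0

    def test_invalid_thresholds_rejected(self):
        t = Topograph(np.zeros((64, 64)), 2.0)
        with pytest.raises(ValueError, match="threshold_k"):
            segment_objects(t, threshold_k=0.0)
        with pytest.raises(ValueError, match="seed_k"):
            segment_objects(t, threshold_k=3.0, seed_k=2.0)

    def test_noise_blobs_not_segmented_among_real_objects(self, rng):
        truth, observed = ridge_field(noise=0.2, shape=(512, 512), seed=3)
        labels = segment_objects(observed)
        assert labels.max() == 1


class TestMeasurement:
    def test_straight_thin_ridge_length(self):
        heights = np.zeros((64, 128))
        heights[32, 14:114] = 4.2  # spans 100 px at 1 nm/px
        t = Topograph(heights, 1.0)
        labels = segment_objects(t)
        m = measure_object(t, labels == 1)
        assert 95.0 <= m.length <= 101.0

    def test_uniform_ridge_height(self):
        truth, observed = ridge_field(height_nm=4.2, noise=0.0)
        labels = segment_objects(observed)
        m = measure_object(observed, labels == 1, tip=TIP, exclude_mask=labels > 0)
        assert m.height == pytest.approx(4.2, abs=0.05)

    def test_dilation_correction_round_trip_recovers_true_width(self):
        """Measured FWHM minus tip broadening returns the rendered width within 2 px."""
        for h in (0.5, 2.0, 4.2, 4.7):
            truth, observed = ridge_field(width_nm=8.0, height_nm=h, noise=0.0)
            labels = segment_objects(observed)
            m = measure_object(observed, labels == 1, tip=TIP, exclude_mask=labels > 0)
            assert m.width_corrected == pytest.approx(8.0, abs=2 * 2.0), f"h={h}"

    def test_too_small_component_rejected(self):
        t = Topograph(np.zeros((32, 32)), 2.0)
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 5:7] = True
        with pytest.raises(ValueError, match="4 px"):
            measure_object(t, mask)

    def test_classification_invariant_to_rotation(self):
        truth, observed = ridge_field(height_nm=0.5, noise=0.2, seed=4)
        rotated = Topograph(np.rot90(observed.heights).copy(), observed.pixel_size)
        results = []
        for t in (observed, rotated):
            labels = segment_objects(t)
            m = measure_object(t, labels == 1, tip=TIP, exclude_mask=labels > 0)
            results.append(m)
        assert results[0].object_class == results[1].object_class
        assert results[0].length == pytest.approx(results[1].length, rel=0.05)


class TestClassification:
    def make(self, length, width, height):
        return ObjectMeasure(
            label=1, length=length, height=height,
            width_measured=width + 4.0, width_corrected=width,
            object_class="unclassified",
        )

    def test_short_protofibril_dimensions(self):
        assert classify_object(self.make(85.0, 8.0, 0.5)) == "protofibril"

    def test_long_tall_fibril_dimensions(self):
        assert classify_object(self.make(1500.0, 8.0, 4.7)) == "fibril"

    def test_globular_oligomer(self):
        assert classify_object(self.make(10.0, 9.0, 1.0)) == "oligomer"


class TestNetworkCoverage:
    def test_empty_field(self):
        t = Topograph(np.zeros((64, 64)), 2.0)
        assert network_coverage(t, np.zeros((64, 64), dtype=int)) == 0.0

    def test_fully_covered_field(self):
        t = Topograph(np.ones((64, 64)), 2.0)
        labels = np.ones((64, 64), dtype=int)
        assert network_coverage(t, labels, classes={1: "protofibril"}) == 1.0

    def test_only_protofibril_class_counts(self):
        t = Topograph(np.ones((64, 64)), 2.0)
        labels = np.ones((64, 64), dtype=int)
        assert network_coverage(t, labels, classes={1: "fibril"}) == 0.0


class TestProfiles:
    def test_flat_plane_profile_is_constant(self):
        t = Topograph(np.full((64, 64), 3.0), 2.0)
        p = extract_profile(t, (10.0, 10.0), (100.0, 80.0))
        np.testing.assert_allclose(p.height, 3.0)

    def test_profile_length_matches_euclidean_distance(self):
        t = Topograph(np.zeros((64, 64)), 2.0)
        p = extract_profile(t, (10.0, 10.0), (70.0, 90.0))
        assert p.length == pytest.approx(np.hypot(60.0, 80.0), abs=1.0)

    def test_profile_across_ridge_reaches_crest_height(self):
        truth, observed = ridge_field(height_nm=4.2, noise=0.0)
        mid_y = observed.shape[0] * observed.pixel_size / 2.0
        p = extract_profile(observed, (128.0, mid_y - 30.0), (128.0, mid_y + 30.0))
        assert p.height.max() == pytest.approx(4.2, abs=0.05)

    def test_out_of_bounds_endpoint_rejected(self):
        t = Topograph(np.zeros((64, 64)), 2.0)
        with pytest.raises(ValueError, match="outside"):
            extract_profile(t, (0.0, 0.0), (10_000.0, 0.0))
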