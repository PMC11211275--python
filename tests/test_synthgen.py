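"""Synthetic forward models: spectra, topographs, plate reads, presets."""

from __future__ import annotations

import numpy as np
import pytest

from fibriltrace import TipModel, boltzmann, dilate_with_tip, make_timeline_preset
from fibriltrace.amide import BandComponent, pseudo_voigt
from fibriltrace.presets import LABELS, TimelinePreset
from fibriltrace.synthgen import (
    PlacedObject,
    SpectrumGenConfig,
    ThTGenConfig,
    TopographGenConfig,
    clean_spectrum,
    empty_field_config,
    field_config_for,
    generate_spectrum_set,
    generate_tht,
    generate_topograph,
    spectrum_config_for,
    tht_config_for,
)


class TestSpectrumModel:
    def test_noise_free_spectrum_is_bands_plus_baseline(self):
        band = BandComponent(center=1670.0, fwhm=18.0, eta=0.5, area=1000.0)
        cfg = SpectrumGenConfig(bands=(band,), baseline_coeffs=(200.0, -50.0))
        s = clean_spectrum(cfg)
        u = (s.shift - s.shift.mean()) / ((s.shift[-1] - s.shift[0]) / 2.0)
        expected = 200.0 - 50.0 * u + pseudo_voigt(s.shift, band)
        np.testing.assert_allclose(s.intensity, expected, rtol=1e-12)

    def test_replicates_reproducible_for_fixed_seed(self):
        cfg = spectrum_config_for(make_timeline_preset("240min"), n_replicates=3)
        a = generate_spectrum_set(cfg, seed=11)
        b = generate_spectrum_set(cfg, seed=11)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_different_seeds_differ(self):
        cfg = spectrum_config_for(make_timeline_preset("240min"), n_replicates=1)
        a = generate_spectrum_set(cfg, seed=1)[0]
        b = generate_spectrum_set(cfg, seed=2)[0]
        assert not np.array_equal(a.intensity, b.intensity)

    def test_band_outside_axis_rejected(self):
        band = BandComponent(center=2500.0, fwhm=18.0, eta=0.5, area=100.0)
        with pytest.raises(ValueError, match="outside axis"):
            clean_spectrum(SpectrumGenConfig(bands=(band,)))

    def test_preset_amide_areas_follow_structure_fractions(self):
        preset = make_timeline_preset("48h")
        cfg = spectrum_config_for(preset)
        amide = sorted(
            (b for b in cfg.bands if 1640.0 <= b.center <= 1690.0),
            key=lambda b: b.center,
        )
        assert len(amide) == 3
        total = sum(b.area for b in amide)
        got = tuple(b.area / total for b in amide)
        np.testing.assert_allclose(got, preset.structure_fractions, rtol=1e-12)


class TestTopographModel:
    def test_observed_surface_dominates_grid_dilated_truth(self):
        preset = make_timeline_preset("240min")
        cfg = field_config_for(preset, seed=5, shape=(256, 256))
        truth, observed = generate_topograph(cfg, seed=6)
        grid = dilate_with_tip(truth, TipModel(cfg.tip_radius))
        noise_free = TopographGenConfig(
            shape=cfg.shape, pixel_size=cfg.pixel_size, substrate_rms=0.0,
            tip_radius=cfg.tip_radius, objects=cfg.objects,
        )
        _, clean_obs = generate_topograph(noise_free, seed=6)
        assert np.all(clean_obs.heights >= grid.heights - 1e-9)

    def test_reproducible_for_fixed_seed(self):
        cfg = empty_field_config(shape=(128, 128))
        _, a = generate_topograph(cfg, seed=3)
        _, b = generate_topograph(cfg, seed=3)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_empty_field_truth_is_flat(self):
        truth, _ = generate_topograph(empty_field_config(shape=(128, 128)), seed=0)
        np.testing.assert_allclose(truth.heights, 0.0)

    def test_out_of_field_object_rejected(self):
        obj = PlacedObject(
            object_class="fibril",
            polyline=np.array([[-50.0, 10.0], [100.0, 10.0]]),
            width=8.0,
            height=4.2,
        )
        with pytest.raises(ValueError, match="field"):
            TopographGenConfig(shape=(64, 64), pixel_size=2.0, objects=(obj,))

    def test_truth_crest_matches_requested_height(self):
        obj = PlacedObject(
            object_class="fibril",
            polyline=np.array([[30.0, 64.0], [220.0, 64.0]]),
            width=8.0,
            height=4.2,
        )
        cfg = TopographGenConfig(shape=(64, 128), pixel_size=2.0, substrate_rms=0.0,
                                 objects=(obj,))
        truth, _ = generate_topograph(cfg, seed=0)
        assert truth.heights.max() == pytest.approx(4.2, abs=1e-9)

    def test_field_composition_matches_preset_counts(self):
        preset = make_timeline_preset("480min")
        cfg = field_config_for(preset, seed=9)
        by_class = {}
        for obj in cfg.objects:
            by_class[obj.object_class] = by_class.get(obj.object_class, 0) + 1
        assert by_class.get("protofibril", 0) == preset.protofibril_params[3]
        assert by_class.get("fibril", 0) == preset.fibril_params[2]


class TestThTModel:
    def test_noise_free_wells_follow_the_sigmoid_exactly(self):
        cfg = ThTGenConfig(noise_sd=0.0)
        traces = generate_tht(cfg, seed=0)
        sample = traces[0]
        expected = boltzmann(sample.time_hours, *cfg.sigmoid)
        np.testing.assert_allclose(sample.intensity, expected, rtol=1e-12)

    def test_control_wells_are_flat_at_baseline(self):
        cfg = ThTGenConfig(noise_sd=0.0)
        controls = [t for t in generate_tht(cfg, seed=0) if t.is_control]
        assert len(controls) == cfg.n_controls
        for c in controls:
            np.testing.assert_allclose(c.intensity, cfg.sigmoid[0])

    def test_default_noise_is_two_percent_of_amplitude(self):
        cfg = ThTGenConfig()
        assert cfg.effective_noise_sd == pytest.approx(0.02 * 1000.0)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            ThTGenConfig(sigmoid=(100.0, 50.0, 0.5, 11.5))  # Fmax < F0
        with pytest.raises(ValueError):
            ThTGenConfig(sigmoid=(100.0, 1100.0, -0.5, 11.5))  # k < 0


class TestPresets:
    def test_all_seven_timepoints_constructible(self):
        for label in LABELS:
            preset = make_timeline_preset(label)
            assert sum(preset.structure_fractions) == pytest.approx(1.0)

    def test_beta_fraction_rises_monotonically_after_two_hours(self):
        betas = [make_timeline_preset(l).structure_fractions[1]
                 for l in ("120min", "240min", "480min", "24h", "48h")]
        assert all(b2 > b1 for b1, b2 in zip(betas, betas[1:]))

    def test_coil_dominates_early_beta_dominates_late(self):
        a0, b0, c0 = make_timeline_preset("0min").structure_fractions
        a1, b1, c1 = make_timeline_preset("48h").structure_fractions
        assert c0 > b0 > a0
        assert b1 > c1 > a1

    def test_fibrils_absent_before_four_hours(self):
        for label in ("0min", "60min", "120min"):
            assert make_timeline_preset(label).fibril_params[2] == 0
        assert make_timeline_preset("240min").fibril_params[2] > 0

    def test_mature_fibrils_taller_than_early_fibrils(self):
        assert make_timeline_preset("24h").fibril_params[1] > \
            make_timeline_preset("240min").fibril_params[1]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown timepoint"):
            make_timeline_preset("90min")

    def test_inconsistent_preset_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TimelinePreset(
                label="0min",
                structure_fractions=(0.5, 0.5, 0.5),
                protofibril_params=(85.0, 8.0, 0.5, 24),
                fibril_params=((0.0, 0.0), 0.0, 0),
                network_flag=False,
                tht_params=(100.0, 1100.0, 4.0 / 7.0, 11.5),
            )
        with pytest.raises(ValueError, match="absent before"):
            TimelinePreset(
                label="60min",
                structure_fractions=(0.24, 0.32, 0.44),
                protofibril_params=(85.0, 8.0, 0.5, 40),
                fibril_params=((200.0, 600.0), 4.2, 8),
                network_flag=True,
                tht_params=(100.0, 1100.0, 4.0 / 7.0, 11.5),
            )
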