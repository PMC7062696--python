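"""Phantom population statistics, rendering contracts and reproducibility."""

import dataclasses

import numpy as np
import pytest

from radiocell import qpm
from radiocell import synthetic_data as sd
from radiocell.config import AcquisitionConfig, OpticsConfig, SegmentationConfig

from conftest import single_phantom


class TestPopulation:
    def test_reproducible_for_fixed_seed(self):
        a = sd.make_phantom_population(10, seed=5)
        b = sd.make_phantom_population(10, seed=5)
        for pa, pb in zip(a, b):
            assert pa == pb

    def test_default_26_cell_mass_median_in_reference_iqr(self):
        """Default population median dry mass falls inside 494-669 pg."""
        for seed in (0, 1, 2):
            ph = sd.make_phantom_population(26, seed=seed)
            med = np.median([p.dry_mass_pg for p in ph])
            assert 494 <= med <= 669

    def test_zero_variance_single_phantom_is_exact(self):
        """All variances 0 => the phantom carries exactly the configured medians."""
        g1 = dataclasses.replace(
            sd.DEFAULT_PHASE_STATS["G1"],
            proportion=1.0, mass_log_sd=0.0, cpm_log_sd=0.0,
        )
        params = sd.PopulationParams(
            phase_stats={**sd.DEFAULT_PHASE_STATS, "G1": g1,
                         "G1_S": dataclasses.replace(sd.DEFAULT_PHASE_STATS["G1_S"], proportion=0.0),
                         "S_G2_M": dataclasses.replace(sd.DEFAULT_PHASE_STATS["S_G2_M"], proportion=0.0)},
            fluor_log_sd=0.0,
        )
        (p,) = sd.make_phantom_population(1, seed=3, params=params)
        assert p.dry_mass_pg == pytest.approx(g1.mass_median_pg)
        assert p.expected_cpm == pytest.approx(g1.cpm_median)
        assert p.rfp_level == pytest.approx(g1.rfp_median)

    def test_large_sample_medians_match_configuration(self):
        """n=1000: per-phase sample medians within 5% of the configured medians."""
        ph = sd.make_phantom_population(1000, seed=11, place=False)
        for name, st in sd.DEFAULT_PHASE_STATS.items():
            if st.proportion == 0:
                continue
            masses = [p.dry_mass_pg for p in ph if p.cycle_phase == name]
            assert np.median(masses) == pytest.approx(st.mass_median_pg, rel=0.05)
            cpms = [p.expected_cpm for p in ph if p.cycle_phase == name]
            assert np.median(cpms) == pytest.approx(st.cpm_median, rel=0.05)

    def test_phase_fluorescence_consistency(self):
        """Reporter levels strictly follow the FUCCI truth table per phase."""
        ph = sd.make_phantom_population(40, seed=2, place=False)
        for p in ph:
            want = {"G1": (False, True), "S_G2_M": (True, False),
                    "G1_S": (True, True), "M_G1": (False, False)}[p.cycle_phase]
            assert (p.gfp_level > 0, p.rfp_level > 0) == want

    def test_uptake_structure_targets_reference(self):
        """Configured S/G2/M counts median is ~2x G1 (the published structure)."""
        stats = sd.DEFAULT_PHASE_STATS
        ratio = stats["S_G2_M"].cpm_median / stats["G1"].cpm_median
        assert ratio == pytest.approx(87 / 44)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sd.make_phantom_population(0, seed=0)
        with pytest.raises(ValueError):
            sd.CellPhantom(center_um=(0, 0), radius_um=5, dry_mass_pg=-1,
                           cycle_phase="G1", activity_bq=0, gfp_level=0, rfp_level=1)
        with pytest.raises(ValueError):  # G1 must be red-only
            sd.CellPhantom(center_um=(0, 0), radius_um=5, dry_mass_pg=100,
                           cycle_phase="G1", activity_bq=0, gfp_level=1, rfp_level=1)


class TestInterferogram:
    OPTICS = OpticsConfig(sensor_px=(256, 256))

    def test_empty_fov_sample_equals_background(self):
        sample, bg = sd.render_interferogram([], self.OPTICS, noise_sigma=0.0)
        np.testing.assert_array_equal(sample, bg)

    def test_round_trip_mass_within_2_percent(self):
        """Demodulating the rendered interferogram recovers the dry mass."""
        ph = single_phantom(mass_pg=500.0, radius_um=14.0, optics=self.OPTICS)
        sample, bg = sd.render_interferogram([ph], self.OPTICS, noise_sigma=0.0)
        phase = qpm.retrieve_phase(sample, bg, self.OPTICS.pixel_pitch_um)
        mask = phase.values > 0.15
        mass = qpm.dry_mass(phase, mask)
        assert mass == pytest.approx(500.0, rel=0.02)

    def test_steep_phase_warns(self):
        ph = single_phantom(mass_pg=5000.0, radius_um=10.0, optics=self.OPTICS)
        with pytest.warns(UserWarning, match="gradient"):
            sd.render_phase_map([ph], self.OPTICS)


class TestFluorescenceRendering:
    OPTICS = OpticsConfig(sensor_px=(256, 256))

    def test_g1_phantom_dark_in_gfp(self):
        """A G1 (red-only) cell leaves the GFP channel at pure background."""
        ph = single_phantom(phase="G1", optics=self.OPTICS)
        img, bg = sd.render_fluorescence([ph], "GFP", self.OPTICS, noise_sigma=0.0)
        np.testing.assert_array_equal(img, bg)

    def test_g1s_phantom_bright_in_both(self):
        ph = single_phantom(phase="G1_S", optics=self.OPTICS)
        for channel in ("GFP", "RFP"):
            img, bg = sd.render_fluorescence([ph], channel, self.OPTICS, noise_sigma=0.0)
            assert (img - bg).max() > 100

    def test_uniform_excitation_no_cells_is_constant_offset(self):
        field = np.ones((256, 256))
        img, bg = sd.render_fluorescence(
            [], "GFP", self.OPTICS, excitation_field=field, noise_sigma=0.0, offset=7.0
        )
        np.testing.assert_allclose(img, 7.0)
        np.testing.assert_array_equal(img, bg)

    def test_nonpositive_excitation_rejected(self):
        with pytest.raises(ValueError):
            sd.render_fluorescence([], "GFP", self.OPTICS,
                                   excitation_field=np.zeros((256, 256)))


class TestRLMStack:
    OPTICS = OpticsConfig(sensor_px=(256, 256))

    def test_zero_activity_matches_dark_statistics(self):
        ph = single_phantom(optics=self.OPTICS, activity_bq=0.0)
        acq = AcquisitionConfig(n_frames=50, seed=1)
        stack = sd.simulate_rlm_stack([ph], self.OPTICS, acq, n_dark_frames=50)
        assert len(stack.events) <= 2  # only rare sensor hits possible
        s, d = stack.frames.mean(), stack.dark_frames.mean()
        assert s == pytest.approx(d, rel=0.01)

    def test_event_budget_matches_decay_integral(self):
        """Short-only, no noise: total events ~ activity * live * mean decay."""
        tracks = sd.TrackClassParams(proportions=(1.0, 0.0, 0.0),
                                     sensor_hit_rate_per_frame=0.0)
        acq = AcquisitionConfig(n_frames=2000, seed=9, start_offset_min=0.0)
        ph = single_phantom(optics=self.OPTICS, activity_bq=2.0)
        stack = sd.simulate_rlm_stack(
            [ph], self.OPTICS, acq, track_classes=tracks,
            noise=sd.RLMNoiseParams(baseline=0.0, read_sigma=0.0), n_dark_frames=10,
        )
        # independent oracle: integrate the decay curve analytically
        lam = np.log(2) / (acq.half_life_min * 60.0)
        wall = acq.n_frames * acq.frame_period_s
        mean_decay = (1 - np.exp(-lam * wall)) / (lam * wall)
        expected = ph.activity_bq * acq.live_time_s * mean_decay
        assert len(stack.events) == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_long_only_stack_yields_zero_accepted_events(self):
        """Every track exceeds the 10-px length filter by construction."""
        from radiocell.config import OrbitParams
        from radiocell.rlm import accumulate, dark_correct, detect_stack

        tracks = sd.TrackClassParams(proportions=(0.0, 1.0, 0.0),
                                     long_length_px_range=(12.0, 13.0),
                                     sensor_hit_rate_per_frame=0.0)
        acq = AcquisitionConfig(n_frames=300, seed=4)
        ph = single_phantom(optics=self.OPTICS, activity_bq=3.0)
        stack = sd.simulate_rlm_stack([ph], self.OPTICS, acq, track_classes=tracks,
                                      n_dark_frames=50)
        corrected = dark_correct(stack.frames, stack.dark_frames)
        events = detect_stack(corrected, OrbitParams())
        counts = accumulate(events, self.OPTICS.binned_px, acq)
        assert counts.total_counts == 0

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            acq = AcquisitionConfig(n_frames=0)
            sd.simulate_rlm_stack([], self.OPTICS, acq)


def test_dataset_determinism(small_optics):
    """Fixed seed => bit-identical images and event ledgers."""
    acq = AcquisitionConfig(n_frames=50, seed=8)
    a = sd.simulate_dataset(n_cells=2, seed=8, optics=small_optics, acq=acq, n_dark_frames=20)
    b = sd.simulate_dataset(n_cells=2, seed=8, optics=small_optics, acq=acq, n_dark_frames=20)
    np.testing.assert_array_equal(a.interferogram, b.interferogram)
    np.testing.assert_array_equal(a.gfp, b.gfp)
    np.testing.assert_array_equal(a.rlm.frames, b.rlm.frames)
    assert a.rlm.events.equals(b.rlm.events)
    assert a.truth_table().equals(b.truth_table())


def test_write_dataset_round_trip(tmp_path, small_optics):
    import tifffile

    acq = AcquisitionConfig(n_frames=20, seed=3)
    ds = sd.simulate_dataset(n_cells=1, seed=3, optics=small_optics, acq=acq, n_dark_frames=10)
    sd.write_dataset(ds, tmp_path)
    stack = tifffile.imread(tmp_path / "rlm_stack.tif")
    np.testing.assert_array_equal(stack, ds.rlm.frames)
    ifg = tifffile.imread(tmp_path / "interferogram.tif")
    np.testing.assert_allclose(ifg, ds.interferogram.astype(np.float32))
    assert (tmp_path / "ground_truth.csv").exists()
    assert (tmp_path / "manifest.json").exists()
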