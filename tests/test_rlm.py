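"""Scintillation-event detection, filtering, counting, decay correction."""

import numpy as np
import pytest

from radiocell import rlm
from radiocell import synthetic_data as sd
from radiocell.config import AcquisitionConfig, OpticsConfig, OrbitParams

OPTICS = OpticsConfig(sensor_px=(256, 256))


class TestDecayCorrection:
    @pytest.mark.parametrize(
        "elapsed,expected",
        [(0.0, 1.0), (110.0, 2.0), (55.0, 1.4142135623730951), (220.0, 4.0)],
    )
    def test_reference_values(self, elapsed, expected):
        assert rlm.decay_correction_factor(elapsed) == pytest.approx(expected, rel=1e-12)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            rlm.decay_correction_factor(-1.0)


class TestDarkCorrect:
    def test_stack_equal_to_dark_mean_is_zero(self):
        dark = np.full((10, 8, 8), 100, dtype=np.uint16)
        stack = np.full((5, 8, 8), 100, dtype=np.uint16)
        np.testing.assert_array_equal(rlm.dark_correct(stack, dark), 0)

    def test_constant_offset_survives(self):
        dark = np.full((10, 8, 8), 100, dtype=np.uint16)
        stack = np.full((5, 8, 8), 130, dtype=np.uint16)
        np.testing.assert_allclose(rlm.dark_correct(stack, dark), 30)

    def test_snr_improves_on_simulated_stack(self):
        """Removing the baseline raises event-region SNR vs the raw frames."""
        from conftest import single_phantom

        tracks = sd.TrackClassParams(proportions=(1.0, 0.0, 0.0),
                                     sensor_hit_rate_per_frame=0.0)
        acq = AcquisitionConfig(n_frames=100, seed=2)
        ph = single_phantom(optics=OPTICS, activity_bq=5.0)
        stack = sd.simulate_rlm_stack([ph], OPTICS, acq, track_classes=tracks,
                                      n_dark_frames=50)
        corrected = rlm.dark_correct(stack.frames, stack.dark_frames)
        raw = stack.frames.astype(float)
        sig_mask = corrected.max(axis=0) > 700
        assert sig_mask.any()
        bg_mask = ~sig_mask

        def snr(a):
            return a[:, sig_mask].max() / max(a[:, bg_mask].mean(), 1e-9)

        assert snr(corrected) > snr(raw)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rlm.dark_correct(np.zeros((2, 8, 8)), np.zeros((2, 9, 9)))


def _blob(shape, y, x, sigma, peak):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return peak * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))


class TestDetectEvents:
    def test_empty_frame_yields_nothing(self):
        assert rlm.detect_events(np.zeros((32, 32))) == []

    def test_single_blob_centroid_matches_brute_force(self):
        """Centroid equals the exhaustively computed intensity-weighted mean
        of suprathreshold pixels (independent oracle), within 0.5 px of truth."""
        frame = _blob((64, 64), 20.3, 41.7, 0.9, 1500.0)
        params = OrbitParams()
        events = rlm.detect_events(frame, params)
        assert len(events) == 1
        ev = events[0]
        assert ev.klass == "short"
        mask = frame > params.binary_threshold
        yy, xx = np.nonzero(mask)
        w = frame[yy, xx]
        oracle = ((yy * w).sum() / w.sum(), (xx * w).sum() / w.sum())
        assert ev.centroid_px == pytest.approx(oracle, abs=1e-9)
        assert np.hypot(ev.centroid_px[0] - 20.3, ev.centroid_px[1] - 41.7) < 0.5

    def test_streak_spanning_12_px_is_long(self):
        frame = np.zeros((64, 64))
        for t in np.linspace(-6, 6, 40):
            frame += _blob((64, 64), 30 + 0.2 * t, 30 + t, 1.0, 120.0)
        assert frame.max() > 700
        events = rlm.detect_events(frame)
        assert len(events) == 1
        assert events[0].klass == "long"
        assert events[0].length_px > 10

    def test_broad_glow_is_diffuse(self):
        frame = _blob((64, 64), 30, 30, 3.5, 900.0)
        events = rlm.detect_events(frame)
        assert len(events) == 1
        assert events[0].klass == "diffuse"

    def test_single_pixel_impulse_is_sensor_hit(self):
        frame = np.zeros((64, 64))
        frame[10, 50] = 50_000.0
        events = rlm.detect_events(frame)
        assert len(events) == 1
        assert events[0].klass == "sensor_hit"

    def test_shallow_peak_suppressed_by_h_value(self):
        """A plateau just over threshold but with < h prominence is dropped."""
        frame = np.full((64, 64), 650.0)
        frame[20:24, 20:24] = 720.0  # prominence 70 < h = 100
        assert rlm.detect_events(frame, OrbitParams()) == []

    def test_intensity_scale_covariance(self):
        """Scaling frame and both intensity thresholds by c yields identical events."""
        rng = np.random.default_rng(3)
        frame = _blob((64, 64), 12.2, 15.8, 0.9, 2000.0)
        frame += _blob((64, 64), 40.0, 45.0, 3.5, 900.0)
        frame += rng.normal(0, 20, frame.shape).clip(0)
        p1 = OrbitParams()
        c = 2.5
        p2 = OrbitParams(binary_threshold=p1.binary_threshold * c,
                         h_value=p1.h_value * c)
        ev1 = rlm.detect_events(frame, p1)
        ev2 = rlm.detect_events(frame * c, p2)
        assert len(ev1) == len(ev2) == 2
        for a, b in zip(ev1, ev2):
            assert a.klass == b.klass
            assert a.centroid_px == pytest.approx(b.centroid_px, abs=1e-9)
            assert b.peak_intensity == pytest.approx(a.peak_intensity * c)


class TestAccumulate:
    ACQ = AcquisitionConfig(n_frames=100, exposure_s=0.020)

    def _event(self, y, x, klass="short", frame=0):
        return rlm.RLMEvent(frame_index=frame, centroid_px=(y, x), length_px=2,
                            peak_intensity=1000.0, klass=klass)

    def test_no_events_zero_grid(self):
        counts = rlm.accumulate([], (16, 16), self.ACQ)
        assert counts.total_counts == 0

    def test_k_events_sum_to_k(self):
        events = [self._event(5.2, 5.4, frame=i) for i in range(7)]
        counts = rlm.accumulate(events, (16, 16), self.ACQ)
        assert counts.total_counts == 7
        assert counts.grid[5, 5] == 7

    def test_rejected_classes_are_discarded(self):
        events = [self._event(4, 4), self._event(5, 5, "long"),
                  self._event(6, 6, "diffuse"), self._event(7, 7, "sensor_hit")]
        counts = rlm.accumulate(events, (16, 16), self.ACQ)
        assert counts.total_counts == 1

    def test_conservation_on_simulated_stack(self):
        """Accepted-count conservation: grid total == number of accepted events."""
        from conftest import single_phantom

        acq = AcquisitionConfig(n_frames=300, seed=5)
        ph = single_phantom(optics=OPTICS, activity_bq=4.0)
        stack = sd.simulate_rlm_stack([ph], OPTICS, acq, n_dark_frames=50)
        corrected = rlm.dark_correct(stack.frames, stack.dark_frames)
        events = rlm.detect_stack(corrected)
        counts = rlm.accumulate(events, OPTICS.binned_px, acq)
        n_short = sum(1 for e in events if e.klass == "short")
        # border-exiting centroids are the only permitted discrepancy
        assert abs(counts.total_counts - n_short) <= 1

    def test_localization_improves_with_event_count(self):
        """Counts-centroid error shrinks roughly as sigma_psf/sqrt(N)."""
        rng = np.random.default_rng(8)
        sigma = 2.5  # binned px
        errs = []
        for n in (20, 2000):
            events = [self._event(32 + rng.normal(0, sigma), 32 + rng.normal(0, sigma), frame=i)
                      for i in range(n)]
            counts = rlm.accumulate(events, (64, 64), self.ACQ)
            yy, xx = np.nonzero(counts.grid)
            w = counts.grid[yy, xx]
            cy, cx = (yy * w).sum() / w.sum(), (xx * w).sum() / w.sum()
            errs.append(np.hypot(cy - 32, cx - 32))
        assert errs[1] < errs[0]
        assert errs[1] < 4 * sigma / np.sqrt(2000)


def test_detection_precision_recall_on_synthetic_stack():
    """Short-track precision and recall >= 0.95 at default parameters."""
    full_optics = OpticsConfig()
    acq = AcquisitionConfig(n_frames=800, seed=13)
    phantoms = sd.make_phantom_population(10, seed=13, optics=full_optics)
    stack = sd.simulate_rlm_stack(phantoms, full_optics, acq, n_dark_frames=100)
    corrected = rlm.dark_correct(stack.frames, stack.dark_frames)
    detected = rlm.detect_stack(corrected)
    det_short = [e for e in detected if e.klass == "short"]
    true_short = stack.events[stack.events.klass == "short"]
    by_frame: dict[int, list] = {}
    for e in det_short:
        by_frame.setdefault(e.frame_index, []).append(e)
    tp, used = 0, set()
    for row in true_short.itertuples():
        for e in by_frame.get(row.frame, []):
            if id(e) in used:
                continue
            if np.hypot(e.centroid_px[0] - row.y_px, e.centroid_px[1] - row.x_px) < 2:
                tp += 1
                used.add(id(e))
                break
    precision = tp / len(det_short)
    recall = tp / len(true_short)
    assert precision >= 0.95
    assert recall >= 0.95
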