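"""Shared configuration dataclasses for the multimodal radiography pipeline.

All internal lengths are micrometres, masses picograms, times seconds unless a
field name says otherwise.  The specific refraction increment 0.18 mL/g is the
same number as 0.18 um^3/pg, which keeps the dry-mass integral dimensionally
closed at image scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging geometry shared by all modalities.

    Defaults mirror a 40x/0.8-NA chain on a 1024x1024 EMCCD: 0.625 um/px full
    resolution (640 um field of view), 8x8 binning for radioluminescence
    acquisition (5 um/px) and a ~30 um FWHM scintillation point-spread
    function.
    """

    pixel_pitch_um: float = 0.625
    sensor_px: tuple[int, int] = (1024, 1024)
    wavelength_um: float = 0.633
    carrier_freq_cyc_per_um: tuple[float, float] = (0.25, 0.15)
    rlm_binning: int = 8
    psf_fwhm_um: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        ny, nx = self.sensor_px
        if ny != nx:
            raise ValueError("sensor must be square")
        if ny % self.rlm_binning != 0:
            raise ValueError("sensor size must be divisible by rlm_binning")
        nyq = 1.0 / (2.0 * self.pixel_pitch_um)
        if any(abs(f) >= nyq for f in self.carrier_freq_cyc_per_um):
            raise ValueError("carrier frequency at or above Nyquist")

    @property
    def fov_um(self) -> float:
        return self.sensor_px[0] * self.pixel_pitch_um

    @property
    def binned_pitch_um(self) -> float:
        return self.pixel_pitch_um * self.rlm_binning

    @property
    def binned_px(self) -> tuple[int, int]:
        b = self.rlm_binning
        return (self.sensor_px[0] // b, self.sensor_px[1] // b)

    @property
    def psf_sigma_um(self) -> float:
        return self.psf_fwhm_um * FWHM_TO_SIGMA

    # Grid convention (shared by all modules): 0-based, pixel-centre, physical
    # origin at the centre of the full-resolution top-left pixel.  Binned pixel
    # (I, J) covers full-resolution rows [bI, bI+b) (half-open).
    def um_to_binned(self, coord_um):
        """Physical um coordinate -> fractional binned-pixel coordinate."""
        b = self.rlm_binning
        return coord_um / self.binned_pitch_um - (b - 1) / (2.0 * b)

    def binned_to_um(self, coord_px):
        """Fractional binned-pixel coordinate -> physical um coordinate."""
        b = self.rlm_binning
        return (coord_px + (b - 1) / (2.0 * b)) * self.binned_pitch_um


@dataclass(frozen=True)
class AcquisitionConfig:
    """Radioluminescence acquisition timing.

    ``n_frames`` frames of ``exposure_s`` each; readout gaps make the wall
    clock longer than the live time by 1/(1 - dead_time_fraction).
    ``start_offset_min`` is the delay between tracer calibration and the first
    frame, used for decay correction (fluorine-18 half-life 110 min).
    """

    n_frames: int = 20_000
    exposure_s: float = 0.020
    dead_time_fraction: float = 0.32
    start_offset_min: float = 60.0
    half_life_min: float = 110.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 0:
            raise ValueError("n_frames must be nonnegative")
        if not (0.0 <= self.dead_time_fraction < 1.0):
            raise ValueError("dead_time_fraction must be in [0, 1)")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be positive")
        if self.start_offset_min < 0:
            raise ValueError("start_offset_min must be nonnegative")

    @property
    def live_time_s(self) -> float:
        return self.n_frames * self.exposure_s

    @property
    def live_time_min(self) -> float:
        return self.live_time_s / 60.0

    @property
    def wall_time_s(self) -> float:
        return self.live_time_s / (1.0 - self.dead_time_fraction)

    @property
    def frame_period_s(self) -> float:
        """Wall-clock spacing between frame starts (exposure plus readout gap)."""
        return self.exposure_s / (1.0 - self.dead_time_fraction)


@dataclass(frozen=True)
class OrbitParams:
    """Track-detection settings for the scintillation-event reconstruction.

    ``binary_threshold`` and ``h_value`` are camera intensities; ``sharpness``
    is a k-space radius (FFT bins on a 128-px window) separating focused tracks
    from diffuse deep-crystal glows; ``max_length_px`` is in binned (5 um)
    pixels.
    """

    binary_threshold: float = 700.0
    h_value: float = 100.0
    sharpness: float = 20.0
    max_length_px: float = 10.0
    sharpness_cutoff: float = 0.05

    def __post_init__(self) -> None:
        for name in ("binary_threshold", "h_value", "sharpness", "max_length_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DryMassParams:
    """Constants of the phase-to-mass conversion m = lambda/(2 pi alpha) * integral(Phi)."""

    wavelength_um: float = 0.633
    alpha_um3_per_pg: float = 0.18

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0 or self.alpha_um3_per_pg <= 0:
            raise ValueError("wavelength and alpha must be positive")

    @property
    def mass_prefactor_pg_per_um2(self) -> float:
        """pg of dry matter per (rad * um^2) of integrated phase."""
        return self.wavelength_um / (2.0 * math.pi * self.alpha_um3_per_pg)


@dataclass(frozen=True)
class SegmentationConfig:
    """Cell segmentation from the leveled phase image."""

    phase_thresh_rad: float = 0.15
    min_area_um2: float = 50.0
    dilation_sigma_um: float = 12.5
    exclude_border: bool = True


@dataclass
class RunConfig:
    """Everything a `process` run needs, serialisable to/from JSON/YAML."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    orbit: OrbitParams = field(default_factory=OrbitParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    dry_mass: DryMassParams = field(default_factory=DryMassParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acquisition.start_offset_min < 0:
            raise ValueError("acquisition must not start before tracer calibration")
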