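"""Quantitative phase microscopy: off-axis interferogram demodulation and dry mass.

The sample arm interferes with a tilted reference beam, so the detector sees
``I = A + B cos(2 pi f . r + Phi)``.  In the spatial-frequency domain the
cosine contributes two sidebands at +/- f around the zero order; selecting one
sideband, shifting it to baseband and inverse transforming yields the complex
field, whose argument (relative to an empty-field background) is the
sample-induced phase Phi(x, y).

Dry mass follows from the phase integral over the cell area,

    m = lambda / (2 pi alpha) * integral Phi(x, y) dx dy,

with alpha = 0.18 um^3/pg the specific refraction increment: at 633 nm one
radian of phase over 100 um^2 corresponds to 55.97 pg of non-aqueous content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase

from .config import DryMassParams


@dataclass
class PhaseImage:
    """Unwrapped, background-leveled optical phase map in radians."""

    values: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("phase map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map contains non-finite values")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch_um ** 2


class CarrierNotFoundError(RuntimeError):
    """Raised when no off-axis carrier sideband is separable from the zero order."""


def _find_carrier_peak(spectrum: np.ndarray, dc_guard: int) -> tuple[int, int]:
    """Locate the strongest spectral peak outside a guard zone around DC.

    Works on the fftshifted magnitude spectrum; returns (row, col) offsets
    relative to the spectrum centre.  Only the upper half-plane is searched
    (the two sidebands are conjugate mirrors).
    """
    ny, nx = spectrum.shape
    cy, cx = ny // 2, nx // 2
    mag = np.abs(spectrum)
    yy, xx = np.ogrid[:ny, :nx]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    search = mag.copy()
    search[r2 <= dc_guard**2] = 0.0
    search[cy + 1 :, :] = 0.0  # keep one half-plane
    peak = np.unravel_index(np.argmax(search), search.shape)
    dc_level = mag[cy, cx]
    if search[peak] <= 1e-3 * dc_level or search[peak] == 0.0:
        raise CarrierNotFoundError(
            "carrier sideband indistinguishable from the zero order "
            "(fringe contrast too low?)"
        )
    return peak[0] - cy, peak[1] - cx


def _demodulate(image: np.ndarray, peak: tuple[int, int], radius: float) -> np.ndarray:
    """Extract the complex field: window the sideband at `peak`, shift to baseband."""
    ny, nx = image.shape
    spec = np.fft.fftshift(np.fft.fft2(image))
    cy, cx = ny // 2, nx // 2
    py, px = cy + peak[0], cx + peak[1]
    yy, xx = np.ogrid[:ny, :nx]
    window = ((yy - py) ** 2 + (xx - px) ** 2) <= radius**2
    sideband = np.where(window, spec, 0.0)
    # roll the carrier peak onto the spectrum centre == baseband shift
    sideband = np.roll(sideband, (-peak[0], -peak[1]), axis=(0, 1))
    return np.fft.ifft2(np.fft.ifftshift(sideband))


def _fit_background_surface(
    phase: np.ndarray, cell_free: np.ndarray, order: int = 2
) -> np.ndarray:
    """Least-squares 2D polynomial surface (default 2nd order) on cell-free pixels."""
    ny, nx = phase.shape
    y, x = np.mgrid[:ny, :nx]
    y = (y - ny / 2) / ny
    x = (x - nx / 2) / nx
    cols = [
        (x**i) * (y**j)
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    design = np.stack([c.ravel() for c in cols], axis=1)
    sel = cell_free.ravel()
    if sel.sum() < design.shape[1]:
        raise ValueError("too few cell-free pixels to fit background surface")
    # subsample for speed; the surface is low order
    idx = np.flatnonzero(sel)
    if idx.size > 20_000:
        idx = idx[:: idx.size // 20_000]
    coef, *_ = np.linalg.lstsq(design[idx], phase.ravel()[idx], rcond=None)
    return (design @ coef).reshape(ny, nx)


def retrieve_phase(
    interferogram: np.ndarray,
    background: np.ndarray,
    pixel_pitch_um: float,
    carrier_hint: tuple[float, float] | None = None,
) -> PhaseImage:
    """Recover the sample-induced phase from an off-axis interferogram.

    Parameters
    ----------
    interferogram, background
        Raw fringe images with and without the sample, same shape.
    pixel_pitch_um
        Physical pixel pitch of the images.
    carrier_hint
        Optional carrier spatial frequency (cyc/um, (fy, fx)).  When omitted
        the carrier is auto-located as the strongest off-centre spectral peak.

    Returns
    -------
    PhaseImage
        Unwrapped phase with a 2nd-order background surface (fitted on
        cell-free pixels) subtracted, so the empty region sits at zero.
    """
    interferogram = np.asarray(interferogram, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if interferogram.shape != background.shape:
        raise ValueError("interferogram and background shapes differ")
    ny, nx = interferogram.shape

    if carrier_hint is not None:
        fy, fx = carrier_hint
        peak = (round(fy * ny * pixel_pitch_um), round(fx * nx * pixel_pitch_um))
    else:
        bg_spec = np.fft.fftshift(np.fft.fft2(background))
        peak = _find_carrier_peak(bg_spec, dc_guard=min(ny, nx) // 16)

    carrier_mag = float(np.hypot(*peak))
    if carrier_mag < 2:
        raise CarrierNotFoundError("carrier magnitude too small to window")
    radius = carrier_mag / 2.0  # half the carrier magnitude: standard trade-off

    field_s = _demodulate(interferogram, peak, radius)
    field_b = _demodulate(background, peak, radius)
    eps = 1e-12 * np.abs(field_b).max()
    ratio = field_s * np.conj(field_b) / (np.abs(field_b) ** 2 + eps)
    wrapped = np.angle(ratio)
    unwrapped = np.asarray(unwrap_phase(wrapped), dtype=np.float64)

    # level: coarse offset, then a low-order surface on apparent cell-free pixels
    unwrapped -= np.median(unwrapped)
    cell_free = np.abs(unwrapped) < 0.3
    if cell_free.sum() < unwrapped.size // 20:
        cell_free = np.abs(unwrapped) < np.percentile(np.abs(unwrapped), 50)
    surface = _fit_background_surface(unwrapped, cell_free)
    leveled = unwrapped - surface
    # Which of the two conjugate sidebands was windowed is arbitrary, so the
    # recovered phase is defined up to a global sign.  Cells raise the optical
    # path (positive refraction increment), so resolve toward positive bulk.
    if leveled.sum() < 0:
        leveled = -leveled
    return PhaseImage(values=leveled, pixel_pitch_um=pixel_pitch_um)


def dry_mass(
    phase: PhaseImage, mask: np.ndarray, params: DryMassParams | None = None
) -> float:
    """Dry mass (pg) of the region `mask` by Riemann sum of the phase integral."""
    params = params or DryMassParams()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != phase.values.shape:
        raise ValueError("mask and phase shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    vals = phase.values[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("NaN phase under mask")
    integral = float(vals.sum()) * phase.pixel_area_um2
    return params.mass_prefactor_pg_per_um2 * integral
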