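"""FUCCI two-channel fluorescence normalization and cell-cycle classification.

The FUCCI reporter pair marks the cycle: Cdt1-RFP accumulates in G1,
geminin-GFP in S/G2/M, both are present around the G1/S transition and
neither just after mitosis (M/G1).  Per cell, the classification uses the
green and red intensities summed over the cell area after flat-field
normalization, background subtraction and noise thresholding:

    red only  -> G1        green only -> S_G2_M
    both      -> G1_S      neither    -> M_G1

"Expressing" means the summed intensity exceeds a channel threshold.
Automatic assignments can be overridden explicitly per cell (mirroring the
manual visual verification step of the original protocol); overrides are
always recorded, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

PHASES = ("G1", "G1_S", "S_G2_M", "M_G1")


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """Summed per-cell channel intensities after normalization and thresholding."""

    green_sum: float
    red_sum: float

    def __post_init__(self) -> None:
        if self.green_sum < 0 or self.red_sum < 0:
            raise ValueError("summed intensities must be nonnegative")


@dataclass(frozen=True)
class CyclePhase:
    value: str
    manual_override: bool = False
    override_reason: str = ""

    def __post_init__(self) -> None:
        if self.value not in PHASES:
            raise ValueError(f"unknown phase {self.value!r}")


def normalize_channel(
    image: np.ndarray,
    background_image: np.ndarray,
    empty_mask: np.ndarray | None = None,
    smooth_sigma_px: float = 8.0,
    noise_nsigma: float = 3.0,
) -> np.ndarray:
    """Flat-field a fluorescence channel against its own empty-field background.

    The background image is smoothed (it should carry only the excitation
    profile) and divided out, compensating the nonuniform excitation light.
    The mean of an empty region is then subtracted and pixels below
    ``noise_nsigma`` empty-region standard deviations are zeroed.

    Parameters
    ----------
    empty_mask
        Pixels known to contain no cells, used for the offset and the noise
        threshold.  Defaults to the image's 16-px-wide border frame.
    """
    image = np.asarray(image, dtype=np.float64)
    background_image = np.asarray(background_image, dtype=np.float64)
    if image.shape != background_image.shape:
        raise ValueError("image and background shapes differ")
    smooth_bg = ndimage.gaussian_filter(background_image, smooth_sigma_px)
    if smooth_bg.min() <= 0:
        raise ValueError("background contains nonpositive values after smoothing")
    flat = image / smooth_bg

    if empty_mask is None:
        empty_mask = np.zeros(image.shape, dtype=bool)
        b = max(4, min(16, min(image.shape) // 8))
        empty_mask[:b, :] = empty_mask[-b:, :] = True
        empty_mask[:, :b] = empty_mask[:, -b:] = True
    empty_vals = flat[np.asarray(empty_mask, dtype=bool)]
    if empty_vals.size == 0:
        raise ValueError("empty region is empty")
    offset = float(empty_vals.mean())
    sigma = float(empty_vals.std())
    out = flat - offset
    out[out < noise_nsigma * sigma] = 0.0
    return out


def measure_cell(
    green: np.ndarray, red: np.ndarray, mask: np.ndarray
) -> FluorescenceMeasurement:
    """Sum both normalized channels over one cell mask."""
    mask = np.asarray(mask, dtype=bool)
    return FluorescenceMeasurement(
        green_sum=float(green[mask].sum()), red_sum=float(red[mask].sum())
    )


def classify_phase(
    m: FluorescenceMeasurement,
    green_thresh: float = 0.0,
    red_thresh: float = 0.0,
) -> CyclePhase:
    """Assign a cycle phase from the two summed intensities.

    Thresholds must be nonnegative; a sum strictly greater than its threshold
    counts as "expressing".  The four rules partition the plane, so the
    function is total.
    """
    if green_thresh < 0 or red_thresh < 0:
        raise ValueError("thresholds must be nonnegative")
    green = m.green_sum > green_thresh
    red = m.red_sum > red_thresh
    if green and red:
        return CyclePhase("G1_S")
    if green:
        return CyclePhase("S_G2_M")
    if red:
        return CyclePhase("G1")
    return CyclePhase("M_G1")


def classify_cells(
    green: np.ndarray,
    red: np.ndarray,
    label_image: np.ndarray,
    green_thresh: float = 0.0,
    red_thresh: float = 0.0,
    overrides: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Classify every labelled cell; returns a per-cell table.

    ``overrides`` maps cell label -> phase name for explicit manual
    corrections; the table records which rows were overridden.
    """
    overrides = overrides or {}
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    rows = []
    for lab in labels:
        meas = measure_cell(green, red, label_image == lab)
        phase = classify_phase(meas, green_thresh, red_thresh)
        overridden = int(lab) in overrides
        if overridden:
            phase = CyclePhase(overrides[int(lab)], manual_override=True,
                               override_reason="manual override file")
        rows.append(
            {
                "label": int(lab),
                "green_sum": meas.green_sum,
                "red_sum": meas.red_sum,
                "cycle_phase": phase.value,
                "overridden": overridden,
            }
        )
    return pd.DataFrame(rows, columns=["label", "green_sum", "red_sum", "cycle_phase", "overridden"])
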