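"""Cell segmentation from the phase image and per-cell measurement assembly.

The leveled phase image gives the clearest cell outline: a binary mask at a
phase threshold, connected components above a minimum area, and a Sobel
contour of the mask define each cell boundary.  For radioluminescence
integration the boundary is dilated by one PSF sigma (12.5 um) so that
events scattered outside the physical cell are still attributed to it; when
dilation merges two boundaries the counts would cross-contaminate, so both
cells are flagged and discarded.  Cells touching the field-of-view border
are excluded (their event capture is truncated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from .config import OpticsConfig, SegmentationConfig
from .qpm import PhaseImage, dry_mass
from .config import DryMassParams
from .rlm import CountsImage


@dataclass
class CellBoundary:
    """One segmented cell: mask, Sobel contour and PSF-dilated mask."""

    label: int
    mask: np.ndarray
    boundary: np.ndarray
    dilated_mask: np.ndarray | None = None
    merged: bool = False
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class CellRecord:
    """One measured cell; discarded (merged) cells never become records."""

    label: int
    dry_mass_pg: float
    counts_per_min: float
    cycle_phase: str
    green_sum: float = 0.0
    red_sum: float = 0.0
    merged_discarded: bool = False
    manual_phase_override: bool = False


def segment_cells(
    phase: PhaseImage,
    config: SegmentationConfig | None = None,
) -> list[CellBoundary]:
    """Segment cells from a background-leveled phase image.

    Binary mask = phase > threshold; connected components smaller than the
    minimum area are dropped; each kept component gets a Sobel contour of its
    binary mask.  Labels are assigned in top-left-to-bottom-right centroid
    order, so they are deterministic across reruns.
    """
    config = config or SegmentationConfig()
    binary = phase.values > config.phase_thresh_rad
    labels, n = ndimage.label(binary)
    if n == 0:
        return []
    min_area_px = config.min_area_um2 / phase.pixel_area_um2
    cells: list[CellBoundary] = []
    ny, nx = binary.shape
    comps = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < min_area_px:
            continue
        cy, cx = ndimage.center_of_mass(mask)
        comps.append((cy, cx, mask))
    comps.sort(key=lambda t: (round(t[0]), round(t[1])))
    for i, (cy, cx, mask) in enumerate(comps):
        edge = filters.sobel(mask.astype(float)) > 0
        boundary = edge & ~ndimage.binary_erosion(mask)
        touches = bool(
            mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
        )
        cells.append(
            CellBoundary(
                label=i + 1, mask=mask, boundary=boundary, touches_border=touches
            )
        )
    return cells


def dilate_and_flag(
    cells: list[CellBoundary],
    pixel_pitch_um: float,
    sigma_um: float = 12.5,
) -> list[CellBoundary]:
    """Dilate each mask by a disc of one PSF sigma and flag merged pairs.

    Dilation uses the Euclidean distance transform (exact disc radius in um).
    Any two cells whose dilated masks intersect are both flagged ``merged``
    (the flag is symmetric by construction) and are excluded downstream.
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    r_px = sigma_um / pixel_pitch_um
    for cell in cells:
        dist = ndimage.distance_transform_edt(~cell.mask)
        cell.dilated_mask = dist <= r_px
        cell.merged = False
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if (cells[i].dilated_mask & cells[j].dilated_mask).any():
                cells[i].merged = True
                cells[j].merged = True
    return cells


def downsample_mask_to_binned(mask: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    """Binned-resolution mask: True where the binned pixel centre lies in `mask`.

    The binned pixel (I, J) covers full-resolution rows [bI, bI+b); its centre
    sits between full-resolution pixels, so the nearest full-resolution sample
    (index bI + b//2 - 1 for even b) represents it — a half-pixel (0.3 um)
    convention well below the 12.5 um dilation scale.
    """
    b = optics.rlm_binning
    c = max(0, b // 2 - 1) if b % 2 == 0 else b // 2
    return np.asarray(mask, dtype=bool)[c::b, c::b].copy()


def integrate_counts(
    cell: CellBoundary,
    counts: CountsImage,
    optics: OpticsConfig,
    decay_factor: float | None = None,
) -> float:
    """Decay-corrected counts/min inside a cell's dilated boundary.

    Sums the counts grid over the dilated mask downsampled to binned
    resolution, divides by live time (minutes) and multiplies by the decay
    factor.  Refuses merged cells: their counts are cross-contaminated.
    """
    if cell.merged:
        raise ValueError(f"cell {cell.label} is merged; counts are contaminated")
    if cell.dilated_mask is None:
        raise ValueError("cell has no dilated mask; run dilate_and_flag first")
    binned_mask = downsample_mask_to_binned(cell.dilated_mask, optics)
    if binned_mask.shape != counts.grid.shape:
        raise ValueError("phase grid and counts grid are not registered")
    if decay_factor is None:
        decay_factor = counts.decay_factor
    total = float(counts.grid[binned_mask].sum())
    return total / counts.live_time_min * decay_factor


def build_cell_table(
    phase: PhaseImage,
    fluorescence: pd.DataFrame,
    counts: CountsImage,
    optics: OpticsConfig,
    segmentation: SegmentationConfig | None = None,
    dry_mass_params: DryMassParams | None = None,
    cells: list[CellBoundary] | None = None,
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Join the three modality outputs into per-cell records.

    ``fluorescence`` is the per-label classification table from
    :func:`radiocell.fucci.classify_cells`.  Returns the records for
    non-merged, non-border cells plus a QC table covering every segmented
    cell (including discarded ones, with their flags).
    """
    segmentation = segmentation or SegmentationConfig()
    if cells is None:
        cells = segment_cells(phase, segmentation)
        cells = dilate_and_flag(cells, phase.pixel_pitch_um, segmentation.dilation_sigma_um)
    fl = fluorescence.set_index("label") if len(fluorescence) else pd.DataFrame()

    records: list[CellRecord] = []
    qc_rows = []
    for cell in cells:
        discard = cell.merged or (segmentation.exclude_border and cell.touches_border)
        qc_rows.append(
            {
                "label": cell.label,
                "merged": cell.merged,
                "touches_border": cell.touches_border,
                "discarded": discard,
            }
        )
        if discard:
            continue
        mass = dry_mass(phase, cell.mask, dry_mass_params)
        cpm = integrate_counts(cell, counts, optics)
        if cell.label in getattr(fl, "index", []):
            row = fl.loc[cell.label]
            phase_name = str(row["cycle_phase"])
            green_sum = float(row["green_sum"])
            red_sum = float(row["red_sum"])
            overridden = bool(row["overridden"])
        else:
            phase_name, green_sum, red_sum, overridden = "M_G1", 0.0, 0.0, False
        records.append(
            CellRecord(
                label=cell.label,
                dry_mass_pg=mass,
                counts_per_min=cpm,
                cycle_phase=phase_name,
                green_sum=green_sum,
                red_sum=red_sum,
                manual_phase_override=overridden,
            )
        )
    return records, pd.DataFrame(qc_rows)


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Serialize records to the canonical CSV column layout."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "dry_mass_pg": r.dry_mass_pg,
                "counts_per_min": r.counts_per_min,
                "cycle_phase": r.cycle_phase,
                "green_sum": r.green_sum,
                "red_sum": r.red_sum,
                "merged": r.merged_discarded,
                "overridden": r.manual_phase_override,
            }
            for r in records
        ],
        columns=[
            "label", "dry_mass_pg", "counts_per_min", "cycle_phase",
            "green_sum", "red_sum", "merged", "overridden",
        ],
    )
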