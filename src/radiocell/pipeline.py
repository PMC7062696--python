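"""Orchestration: simulate -> process -> report, with manifests and determinism.

`process` runs the full measurement chain on one field of view:

    interferogram -> phase -> segmentation (+ one-sigma dilation, merge QC)
    fluorescence  -> normalization -> FUCCI phase per cell
    frame stack   -> dark correction -> event detection -> short-track counts
                  -> decay correction to the tracer calibration time

and joins everything into a per-cell table (dry mass in pg, decay-corrected
counts/min, cycle phase, QC flags), then reproduces the statistical analyses
(median/IQR by phase group, Mann-Whitney and ANOVA across groups, Huber-IRLS
regression of counts on mass, raw and mass-normalized).  Identical config and
inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .cells import build_cell_table, dilate_and_flag, records_to_frame, segment_cells
from .config import OpticsConfig, RunConfig
from .fucci import classify_cells, normalize_channel
from .qpm import retrieve_phase
from .rlm import accumulate, dark_correct, decay_correction_factor, detect_stack
from .synthetic_data import DATASET_FILES, SimulatedDataset, simulate_dataset, write_dataset

#: summed-intensity expression threshold per channel, in normalized units:
#: far above the residual noise sum after 3-sigma pixel thresholding, far
#: below any genuine reporter expression summed over a cell.
DEFAULT_SUM_THRESHOLD = 10.0


def _label_image(cells, shape) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.uint16)
    for c in cells:
        lab[c.mask] = c.label
    return lab


def process_arrays(
    ds: SimulatedDataset | dict,
    config: RunConfig | None = None,
    overrides: dict[int, str] | None = None,
) -> dict:
    """Run the full measurement chain on in-memory images.

    Accepts a :class:`SimulatedDataset` or a dict with the same attribute
    names.  Returns a dict with the per-cell table, QC table, stats report,
    counts image, phase image and stage counters.
    """
    config = config or RunConfig()
    get = (lambda k: getattr(ds, k)) if not isinstance(ds, dict) else ds.__getitem__
    optics: OpticsConfig = config.optics

    # --- QPM: phase and segmentation -------------------------------------
    phase = retrieve_phase(
        get("interferogram"),
        get("interferogram_background"),
        optics.pixel_pitch_um,
        carrier_hint=optics.carrier_freq_cyc_per_um,
    )
    cells = segment_cells(phase, config.segmentation)
    cells = dilate_and_flag(
        cells, phase.pixel_pitch_um, config.segmentation.dilation_sigma_um
    )
    label_img = _label_image(cells, phase.values.shape)

    # --- FUCCI: cycle phase per cell --------------------------------------
    empty = label_img == 0
    green = normalize_channel(get("gfp"), get("gfp_background"), empty_mask=empty)
    red = normalize_channel(get("rfp"), get("rfp_background"), empty_mask=empty)
    fluor = classify_cells(
        green, red, label_img,
        green_thresh=DEFAULT_SUM_THRESHOLD, red_thresh=DEFAULT_SUM_THRESHOLD,
        overrides=overrides,
    )

    # --- RLM: events -> counts image --------------------------------------
    rlm_obj = get("rlm")
    stack, dark = rlm_obj.frames, rlm_obj.dark_frames
    corrected = dark_correct(stack, dark)
    events = detect_stack(corrected, config.orbit)
    decay = decay_correction_factor(
        config.acquisition.start_offset_min, config.acquisition.half_life_min
    )
    counts = accumulate(
        events, optics.binned_px, config.acquisition, decay_factor=decay
    )

    # --- join + statistics -------------------------------------------------
    records, qc = build_cell_table(
        phase, fluor, counts, optics,
        segmentation=config.segmentation,
        dry_mass_params=config.dry_mass,
        cells=cells,
    )
    table = records_to_frame(records)
    report = analyze_table(table)
    by_class: dict[str, int] = {}
    for ev in events:
        by_class[ev.klass] = by_class.get(ev.klass, 0) + 1
    report["stage_counts"] = {
        "cells_segmented": len(cells),
        "cells_kept": len(records),
        "cells_discarded": int(qc["discarded"].sum()) if len(qc) else 0,
        "events_detected": len(events),
        "events_by_class": dict(sorted(by_class.items())),
        "events_accepted": counts.total_counts,
    }
    return {
        "table": table,
        "qc": qc,
        "report": report,
        "counts": counts,
        "phase": phase,
        "cells": cells,
        "events": events,
        "decay_factor": decay,
    }


def analyze_table(table: pd.DataFrame) -> dict:
    """Statistical report for a per-cell table (JSON-serializable)."""
    from . import stats as st

    report: dict = {"n_cells": int(len(table))}
    if len(table) == 0:
        return report
    mass = table["dry_mass_pg"].to_numpy(float)
    cpm = table["counts_per_min"].to_numpy(float)

    groups = {"all": mass}
    cpm_groups = {"all": cpm}
    for phase_name, sub in table.groupby("cycle_phase"):
        groups[phase_name] = sub["dry_mass_pg"].to_numpy(float)
        cpm_groups[phase_name] = sub["counts_per_min"].to_numpy(float)
    report["dry_mass_pg"] = st.summarize(groups)
    report["counts_per_min"] = st.summarize(cpm_groups)

    if len(table) >= 3 and np.ptp(mass) > 0:
        reg = st.huber_irls(mass, cpm)
        report["regression_counts_vs_mass"] = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "adjusted_r_squared": reg.adjusted_r_squared,
            "ols_adjusted_r_squared": reg.ols_adjusted_r_squared,
            "p_value_slope": reg.p_value_slope,
            "converged": reg.converged,
            "n_irls_iterations": reg.n_irls_iterations,
        }
        regn = st.huber_irls(mass, cpm / mass)
        report["regression_normalized_counts_vs_mass"] = {
            "slope": regn.slope,
            "intercept": regn.intercept,
            "adjusted_r_squared": regn.adjusted_r_squared,
            "p_value_slope": regn.p_value_slope,
        }

    g1 = cpm_groups.get("G1")
    sgm = cpm_groups.get("S_G2_M")
    if g1 is not None and sgm is not None and len(g1) >= 2 and len(sgm) >= 2:
        p_mw, u = st.mann_whitney_two_tailed(sgm, g1)
        phase_cpm = {k: v for k, v in cpm_groups.items() if k != "all" and len(v) >= 2}
        f = p_anova = float("nan")
        if len(phase_cpm) >= 2:
            f, p_anova = st.anova_oneway(list(phase_cpm.values()))
        med_g1 = float(np.median(g1))
        report["uptake_by_phase"] = {
            "mw_p_two_tailed_sgm_vs_g1": p_mw,
            "mw_u": u,
            "anova_f": f,
            "anova_p": p_anova,
            "sgm_over_g1_median_ratio": float(np.median(sgm)) / med_g1 if med_g1 else float("nan"),
        }
        p_mw_m, _ = st.mann_whitney_two_tailed(groups["S_G2_M"], groups["G1"])
        report["mass_by_phase"] = {"mw_p_two_tailed_sgm_vs_g1": p_mw_m}
    return report


# ---------------------------------------------------------------------------
# file-based runs
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _round_floats(obj, ndigits: int = 8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_simulate(outdir, n_cells: int = 26, seed: int = 0, **kwargs) -> SimulatedDataset:
    """Simulate a dataset and write it to `outdir`."""
    ds = simulate_dataset(n_cells=n_cells, seed=seed, **kwargs)
    write_dataset(ds, outdir)
    return ds


def load_dataset(indir) -> dict:
    """Load a written dataset directory back into the process_arrays input form."""
    from types import SimpleNamespace

    from .config import AcquisitionConfig

    indir = Path(indir)
    manifest = json.loads((indir / DATASET_FILES["manifest"]).read_text())
    acq = AcquisitionConfig(**manifest["acquisition"])
    opt_kwargs = dict(manifest["optics"])
    opt_kwargs["sensor_px"] = tuple(opt_kwargs["sensor_px"])
    opt_kwargs["carrier_freq_cyc_per_um"] = tuple(opt_kwargs["carrier_freq_cyc_per_um"])
    optics = OpticsConfig(**opt_kwargs)
    rd = lambda key: tifffile.imread(indir / DATASET_FILES[key])
    rlm = SimpleNamespace(frames=rd("rlm_stack"), dark_frames=rd("dark_stack"))
    return {
        "interferogram": rd("interferogram"),
        "interferogram_background": rd("interferogram_background"),
        "gfp": rd("gfp"),
        "gfp_background": rd("gfp_background"),
        "rfp": rd("rfp"),
        "rfp_background": rd("rfp_background"),
        "rlm": rlm,
        "optics": optics,
        "acquisition": acq,
    }


def run_process(
    indir,
    outdir,
    config: RunConfig | None = None,
    overrides: dict[int, str] | None = None,
) -> dict:
    """Process a dataset directory; write cell table, stats report and manifest."""
    from dataclasses import replace

    indir, outdir = Path(indir), Path(outdir)
    data = load_dataset(indir)
    if config is None:
        config = RunConfig(optics=data["optics"], acquisition=data["acquisition"])
    else:
        config = replace(config, optics=data["optics"], acquisition=data["acquisition"])
    result = process_arrays(data, config, overrides=overrides)

    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / "cell_table.csv"
    qc_path = outdir / "cell_qc.csv"
    report_path = outdir / "stats_report.json"
    counts_path = outdir / "counts_image.tif"
    result["table"].to_csv(table_path, index=False, float_format="%.10g")
    result["qc"].to_csv(qc_path, index=False)
    label_path = outdir / "cell_labels.tif"
    tifffile.imwrite(
        label_path, _label_image(result["cells"], result["phase"].values.shape)
    )
    report_path.write_text(
        json.dumps(_round_floats(result["report"]), indent=2, sort_keys=True) + "\n"
    )
    tifffile.imwrite(counts_path, result["counts"].grid.astype(np.uint32))
    sidecar = {
        "live_time_min": result["counts"].live_time_min,
        "decay_factor": result["counts"].decay_factor,
        "orbit": asdict(config.orbit),
    }
    (outdir / "counts_image.json").write_text(
        json.dumps(_round_floats(sidecar), indent=2, sort_keys=True) + "\n"
    )
    manifest = {
        "software_version": __version__,
        "seed": config.seed,
        "config": _round_floats(
            {
                "optics": asdict(config.optics),
                "acquisition": asdict(config.acquisition),
                "orbit": asdict(config.orbit),
                "segmentation": asdict(config.segmentation),
                "dry_mass": asdict(config.dry_mass),
            }
        ),
        "stage_counts": result["report"].get("stage_counts", {}),
        "outputs": {
            p.name: _sha256(p)
            for p in [table_path, qc_path, report_path, counts_path,
                      label_path, outdir / "counts_image.json"]
        },
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return result


def run_report(cell_table: pd.DataFrame, outdir) -> dict:
    """Figures + JSON for a cell table: scatter with robust fit and 95% CI band,
    mass-normalized scatter, and per-phase box plots (median/IQR/range)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from . import stats as st

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = analyze_table(cell_table)

    mass = cell_table["dry_mass_pg"].to_numpy(float)
    cpm = cell_table["counts_per_min"].to_numpy(float)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(mass, cpm, color="k", s=20)
    axes[0].set_xlabel("dry mass (pg)")
    axes[0].set_ylabel("counts / min")
    if len(cell_table) >= 3 and np.ptp(mass) > 0:
        reg = st.huber_irls(mass, cpm)
        xs = np.linspace(mass.min(), mass.max(), 100)
        ys = reg.predict(xs)
        band = reg.prediction_band(xs)
        axes[0].plot(xs, ys, color="C0")
        axes[0].fill_between(xs, ys - band, ys + band, color="0.8", alpha=0.7)
        regn = st.huber_irls(mass, cpm / mass)
        ysn = regn.predict(xs)
        bandn = regn.prediction_band(xs)
        axes[1].plot(xs, ysn, color="C0")
        axes[1].fill_between(xs, ysn - bandn, ysn + bandn, color="0.8", alpha=0.7)
    axes[1].scatter(mass, cpm / mass, color="k", s=20)
    axes[1].set_xlabel("dry mass (pg)")
    axes[1].set_ylabel("counts / min / pg")
    fig.tight_layout()
    fig.savefig(outdir / "counts_vs_mass.png", dpi=150)
    plt.close(fig)

    order = [p for p in ("G1", "G1_S", "S_G2_M", "M_G1") if (cell_table["cycle_phase"] == p).any()]
    if order:
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (col, label) in zip(
            axes,
            [("dry_mass_pg", "dry mass (pg)"), ("counts_per_min", "counts/min"),
             (None, "counts/min/pg")],
        ):
            data = [
                (cell_table.loc[cell_table["cycle_phase"] == p, col].to_numpy(float)
                 if col else
                 (cell_table.loc[cell_table["cycle_phase"] == p, "counts_per_min"]
                  / cell_table.loc[cell_table["cycle_phase"] == p, "dry_mass_pg"]).to_numpy(float))
                for p in order
            ]
            ax.boxplot(data, tick_labels=order, whis=(0, 100))
            ax.set_ylabel(label)
        fig.tight_layout()
        fig.savefig(outdir / "by_cycle_phase.png", dpi=150)
        plt.close(fig)

    (outdir / "report.json").write_text(
        json.dumps(_round_floats(report), indent=2, sort_keys=True) + "\n"
    )
    return report
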