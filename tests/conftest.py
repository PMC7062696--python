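"""Shared fixtures: small-geometry optics and a reusable simulated dataset."""

from __future__ import annotations

import numpy as np
import pytest

from radiocell.config import AcquisitionConfig, OpticsConfig, RunConfig
from radiocell import synthetic_data as sd


@pytest.fixture(scope="session")
def small_optics() -> OpticsConfig:
    """A 512-px (320 um) field of view: full pipeline behaviour at 1/4 area."""
    return OpticsConfig(sensor_px=(512, 512))


@pytest.fixture(scope="session")
def tiny_dataset(small_optics):
    """Three isolated cells (one per expressed cycle phase), 400 RLM frames."""
    import dataclasses

    stats = sd.DEFAULT_PHASE_STATS
    params = sd.PopulationParams(
        phase_stats={
            name: dataclasses.replace(
                st, proportion=(1 / 3 if name != "M_G1" else 0.0)
            )
            for name, st in stats.items()
        }
    )
    acq = AcquisitionConfig(n_frames=400, seed=42)
    return sd.simulate_dataset(
        n_cells=3,
        seed=42,
        optics=small_optics,
        acq=acq,
        population=params,
        n_dark_frames=100,
    )


@pytest.fixture(scope="session")
def tiny_config(small_optics, tiny_dataset) -> RunConfig:
    return RunConfig(optics=small_optics, acquisition=tiny_dataset.acquisition)


def single_phantom(
    mass_pg: float = 300.0,
    radius_um: float = 15.0,
    center_um: tuple[float, float] | None = None,
    optics: OpticsConfig | None = None,
    phase: str = "G1",
    activity_bq: float = 0.0,
) -> sd.CellPhantom:
    """One phantom centred in the field of view (gentle phase slope by default)."""
    optics = optics or OpticsConfig()
    if center_um is None:
        c = optics.fov_um / 2
        center_um = (c, c)
    gfp, rfp = {
        "G1": (0.0, 1000.0),
        "S_G2_M": (1000.0, 0.0),
        "G1_S": (800.0, 800.0),
        "M_G1": (0.0, 0.0),
    }[phase]
    return sd.CellPhantom(
        center_um=center_um,
        radius_um=radius_um,
        dry_mass_pg=mass_pg,
        cycle_phase=phase,
        activity_bq=activity_bq,
        gfp_level=gfp,
        rfp_level=rfp,
    )
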