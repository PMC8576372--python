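"""Shared fixtures: small simulated acquisitions reused across test modules.

Everything is generated at test time; grids are kept small so the full
suite stays well inside the CI budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from holoscan.field_optics import GridSpec
from holoscan.reconstruct import (
    ReconSettings,
    WavelengthPlan,
    build_wavelength_plan,
    reconstruct_channel,
)
from holoscan.synthetic_scene import (
    AcquisitionSpec,
    BarTargetSpec,
    TargetPlacement,
    AcquisitionSpec,
    disk_phantom_spec,
    make_ladder_scene,
    make_stain_phantom,
    paint_bar_target,
    simulate_stack,
)
from holoscan.field_optics import ComplexField

SENSOR_PITCH_UM = 1.85
SUPER_PITCH_UM = SENSOR_PITCH_UM / 4


@pytest.fixture(scope="session")
def g_band_plan() -> WavelengthPlan:
    return build_wavelength_plan({"G": (512.0, 548.0)}, 6.0)


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionSpec:
    return AcquisitionSpec(
        sensor_grid=GridSpec(64, 64, SENSOR_PITCH_UM), upsample_factor_L=4, z2_um=1000.0
    )


@pytest.fixture(scope="session")
def small_bar_scene(small_acq):
    """A coarse bar target (width >= 3x super pitch) in a 256^2 super grid."""
    sg = small_acq.super_grid
    amplitude = np.ones(sg.shape)
    spec = BarTargetSpec(line_width_um=2.775, orientation="vertical")  # 6 super px
    center = (31.5 * SENSOR_PITCH_UM, 31.5 * SENSOR_PITCH_UM)
    paint_bar_target(amplitude, sg, spec, center)
    field = ComplexField.from_amplitude_phase(sg, amplitude)
    placement = TargetPlacement(spec=spec, center_um=center)
    return field, placement


@pytest.fixture(scope="session")
def small_g_stack(small_bar_scene, g_band_plan, small_acq):
    field, _ = small_bar_scene
    return simulate_stack({"G": field}, g_band_plan, small_acq)


@pytest.fixture(scope="session")
def small_g_recon(small_g_stack):
    settings = ReconSettings(z2_um=1000.0, n_iterations=15)
    return reconstruct_channel(small_g_stack, "G", settings), settings


@pytest.fixture(scope="session")
def stain_disk_setup():
    """3-band stain-disk acquisition: object fields, plan, acq, stack."""
    acq = AcquisitionSpec(
        sensor_grid=GridSpec(64, 64, SENSOR_PITCH_UM), upsample_factor_L=4, z2_um=1000.0
    )
    sg = acq.super_grid
    plan = build_wavelength_plan(
        {"R": (606.0, 642.0), "G": (512.0, 548.0), "B": (452.0, 488.0)}, 6.0
    )
    spec = disk_phantom_spec(
        sg, radius_um=18.0, per_band_transmittance={"R": 0.9, "G": 0.2, "B": 0.7}
    )
    objects = {band: make_stain_phantom(spec, band) for band in ("R", "G", "B")}
    stack = simulate_stack(objects, plan, acq)
    return objects, plan, acq, stack


@pytest.fixture(scope="session")
def stain_disk_recon(stain_disk_setup):
    _, _, _, stack = stain_disk_setup
    settings = ReconSettings(z2_um=1000.0, n_iterations=15)
    return {
        band: reconstruct_channel(stack, band, settings) for band in ("R", "G", "B")
    }, settings
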