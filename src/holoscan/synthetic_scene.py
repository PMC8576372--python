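"""Synthetic acquisition: phantoms and the multi-wavelength forward model.

Builds three-bar resolution targets and stained-tissue-like phantoms, then
simulates the full hologram acquisition — per-wavelength angular-spectrum
propagation to the sensor, full-fill-factor pixel-aperture integration
(block mean) and optional Poisson shot noise.  The simulated stacks are the
fixtures the whole pipeline is tested against.

Raw holograms are background-normalized: a blank object yields intensity
1.0 at every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Mapping

import numpy as np

from .errors import (
    ConfigError,
    GeometryError,
    InvalidParameterError,
    StructuralError,
)
from .field_optics import ComplexField, GridSpec, propagate
from .reconstruct import HologramStack, WavelengthPlan

__all__ = [
    "BAR_LENGTH_TO_WIDTH",
    "BarTargetSpec",
    "TargetPlacement",
    "PhantomSpec",
    "AcquisitionSpec",
    "make_bar_target",
    "paint_bar_target",
    "make_ladder_scene",
    "make_stain_phantom",
    "disk_phantom_spec",
    "bin_to_sensor",
    "simulate_stack",
]

#: Three-bar targets use the USAF 5:1 bar length-to-width ratio.
BAR_LENGTH_TO_WIDTH = 5.0


@dataclass(frozen=True)
class BarTargetSpec:
    """A three-bar resolution element: dark bars on a bright background."""

    line_width_um: float
    orientation: str  # "vertical": long axis along y, modulation along x
    n_bars: int = 3
    duty_cycle: float = 0.5

    def __post_init__(self) -> None:
        if not self.line_width_um > 0:
            raise InvalidParameterError("line_width_um must be > 0")
        if self.orientation not in ("horizontal", "vertical"):
            raise InvalidParameterError(
                f"orientation must be horizontal|vertical, got {self.orientation!r}"
            )
        if self.n_bars < 1:
            raise InvalidParameterError("n_bars must be >= 1")
        if not 0.0 < self.duty_cycle < 1.0:
            raise InvalidParameterError("duty_cycle must lie in (0, 1)")

    @property
    def period_um(self) -> float:
        """Bar-to-bar spacing along the modulation axis."""
        return self.line_width_um / self.duty_cycle

    @property
    def bar_length_um(self) -> float:
        return BAR_LENGTH_TO_WIDTH * self.line_width_um

    @property
    def extent_mod_um(self) -> float:
        """Pattern extent along the modulation axis (outer bar edges)."""
        return (self.n_bars - 1) * self.period_um + self.line_width_um

    def bar_offsets_um(self) -> np.ndarray:
        """Bar-centre offsets from the pattern centre, along the modulation axis."""
        return (np.arange(self.n_bars) - (self.n_bars - 1) / 2.0) * self.period_um


@dataclass(frozen=True)
class TargetPlacement:
    """A bar target located in a scene: spec plus centre in um (x, y)."""

    spec: BarTargetSpec
    center_um: tuple[float, float]


def _bar_mask(
    spec: BarTargetSpec, grid: GridSpec, center_um: tuple[float, float]
) -> np.ndarray:
    xc, yc = center_um
    x = grid.x_coords_um()[None, :]
    y = grid.y_coords_um()[:, None]
    if spec.orientation == "vertical":
        u, v = x - xc, y - yc  # modulation along x
    else:
        u, v = y - yc, x - xc
    half_w = spec.line_width_um / 2.0
    half_len = spec.bar_length_um / 2.0
    in_length = (v >= -half_len) & (v < half_len)
    mask = np.zeros(grid.shape, dtype=bool)
    for off in spec.bar_offsets_um():
        mask |= in_length & (u - off >= -half_w) & (u - off < half_w)
    return mask


def _check_fits(
    spec: BarTargetSpec, grid: GridSpec, center_um: tuple[float, float]
) -> None:
    xc, yc = center_um
    if spec.orientation == "vertical":
        half_x, half_y = spec.extent_mod_um / 2.0, spec.bar_length_um / 2.0
    else:
        half_x, half_y = spec.bar_length_um / 2.0, spec.extent_mod_um / 2.0
    x_max = (grid.width_px - 1) * grid.pitch_um
    y_max = (grid.height_px - 1) * grid.pitch_um
    if xc - half_x < 0 or xc + half_x > x_max or yc - half_y < 0 or yc + half_y > y_max:
        raise GeometryError(
            f"target (width {spec.line_width_um} um at {center_um}) does not fit "
            f"the {grid.height_px}x{grid.width_px} grid"
        )


def make_bar_target(
    spec: BarTargetSpec,
    grid: GridSpec,
    center_um: tuple[float, float] | None = None,
) -> ComplexField:
    """Amplitude-only field: bars of amplitude 0 on a background of 1, phase 0."""
    if center_um is None:
        center_um = (
            (grid.width_px - 1) / 2.0 * grid.pitch_um,
            (grid.height_px - 1) / 2.0 * grid.pitch_um,
        )
    _check_fits(spec, grid, center_um)
    amplitude = np.ones(grid.shape, dtype=np.float64)
    amplitude[_bar_mask(spec, grid, center_um)] = 0.0
    return ComplexField.from_amplitude_phase(grid, amplitude)


def paint_bar_target(
    amplitude: np.ndarray,
    grid: GridSpec,
    spec: BarTargetSpec,
    center_um: tuple[float, float],
) -> None:
    """Stamp a bar target (amplitude 0) into an existing amplitude map, in place."""
    _check_fits(spec, grid, center_um)
    amplitude[_bar_mask(spec, grid, center_um)] = 0.0


def make_ladder_scene(
    widths_um: list[float] | tuple[float, ...],
    grid: GridSpec,
    snap_to_um: float | None = None,
    snap_offset_um: float = 0.0,
) -> tuple[ComplexField, list[TargetPlacement]]:
    """One scene holding both orientations of a descending bar-width ladder.

    Targets are laid out on a rows (widths) x columns (orientations) raster
    spanning the grid.  If ``snap_to_um`` is given, target centres are
    snapped to ``snap_offset_um + k * snap_to_um`` — used to grid-align bar
    centres with sensor pixel centres for best-case contrast measurement.
    """
    if len(widths_um) == 0:
        raise ConfigError("widths_um must be non-empty")
    orientations = ("vertical", "horizontal")
    width_um_total = (grid.width_px - 1) * grid.pitch_um
    height_um_total = (grid.height_px - 1) * grid.pitch_um
    amplitude = np.ones(grid.shape, dtype=np.float64)
    placements: list[TargetPlacement] = []
    n_rows = len(widths_um)
    for row, lw in enumerate(widths_um):
        yc = height_um_total * (row + 1) / (n_rows + 1)
        for col, orient in enumerate(orientations):
            xc = width_um_total * (col + 1) / (len(orientations) + 1)
            if snap_to_um is not None:
                xc = round((xc - snap_offset_um) / snap_to_um) * snap_to_um + snap_offset_um
                yc_s = round((yc - snap_offset_um) / snap_to_um) * snap_to_um + snap_offset_um
            else:
                yc_s = yc
            spec = BarTargetSpec(line_width_um=float(lw), orientation=orient)
            paint_bar_target(amplitude, grid, spec, (xc, yc_s))
            placements.append(TargetPlacement(spec=spec, center_um=(xc, yc_s)))
    return ComplexField.from_amplitude_phase(grid, amplitude), placements


@dataclass
class PhantomSpec:
    """A thin transmissive object with wavelength-band-dependent absorption.

    ``amplitude_map`` is the transmission amplitude of the fully absorbing
    stain; ``per_band_transmittance[band]`` blends it toward a blank field
    (transmittance 1 = stain invisible in that band, 0 = full contrast).
    """

    amplitude_map: np.ndarray
    per_band_transmittance: Mapping[str, float]
    phase_map: np.ndarray | None = None
    pitch_um: float = 1.85 / 4

    def __post_init__(self) -> None:
        self.amplitude_map = np.asarray(self.amplitude_map, dtype=np.float64)
        if self.amplitude_map.ndim != 2:
            raise StructuralError("amplitude_map must be 2D")
        if np.any(self.amplitude_map < 0) or np.any(self.amplitude_map > 1):
            raise InvalidParameterError("amplitude_map entries must lie in [0, 1]")
        for band, t in self.per_band_transmittance.items():
            if not 0.0 <= t <= 1.0:
                raise InvalidParameterError(
                    f"transmittance for band {band!r} must lie in [0, 1], got {t}"
                )
        if self.phase_map is not None:
            self.phase_map = np.asarray(self.phase_map, dtype=np.float64)
            if self.phase_map.shape != self.amplitude_map.shape:
                raise StructuralError("phase_map shape != amplitude_map shape")


def make_stain_phantom(spec: PhantomSpec, band: str) -> ComplexField:
    """Band-specific object field of a stained phantom.

    Amplitude is ``amplitude_map`` blended toward 1 by the band's
    transmittance ``t``: ``a + (1 - a) * t`` — so ``t = 1`` gives a blank
    (all-ones) field and ``t = 0`` reproduces ``amplitude_map`` exactly.
    """
    try:
        t = float(spec.per_band_transmittance[band])
    except KeyError:
        raise ConfigError(f"no transmittance defined for band {band!r}") from None
    a = spec.amplitude_map
    amplitude = a + (1.0 - a) * t
    phase = spec.phase_map if spec.phase_map is not None else 0.0
    h, w = a.shape
    grid = GridSpec(h, w, spec.pitch_um)
    return ComplexField.from_amplitude_phase(grid, amplitude, phase)


def disk_phantom_spec(
    grid: GridSpec,
    radius_um: float,
    per_band_transmittance: Mapping[str, float],
    amplitude_inside: float = 0.0,
) -> PhantomSpec:
    """Centred disk stain, the stock band-selective test object."""
    x = grid.x_coords_um()[None, :] - (grid.width_px - 1) / 2.0 * grid.pitch_um
    y = grid.y_coords_um()[:, None] - (grid.height_px - 1) / 2.0 * grid.pitch_um
    amplitude = np.ones(grid.shape, dtype=np.float64)
    amplitude[x**2 + y**2 <= radius_um**2] = amplitude_inside
    return PhantomSpec(
        amplitude_map=amplitude,
        per_band_transmittance=dict(per_band_transmittance),
        pitch_um=grid.pitch_um,
    )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sensor geometry and acquisition options of the simulated microscope."""

    sensor_grid: GridSpec
    upsample_factor_L: int = 4
    z2_um: float = 1000.0
    noise_model: str = "none"
    photon_budget: float = 10000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.upsample_factor_L < 1:
            raise InvalidParameterError("upsample_factor_L must be >= 1")
        if not self.z2_um > 0:
            raise InvalidParameterError("z2_um must be > 0")
        if self.noise_model not in ("none", "shot"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if not self.photon_budget > 0:
            raise InvalidParameterError("photon_budget must be > 0")

    @property
    def super_grid(self) -> GridSpec:
        """The simulation grid: sensor grid at L x finer pitch."""
        return self.sensor_grid.upsampled(self.upsample_factor_L)


def bin_to_sensor(intensity: np.ndarray, L: int) -> np.ndarray:
    """Pixel-aperture integration: mean over each L x L block.

    The mean (not the sum) preserves the intensity scale, so a blank unit
    field bins to 1.0.
    """
    if L < 1:
        raise InvalidParameterError(f"L must be >= 1, got {L}")
    intensity = np.asarray(intensity, dtype=np.float64)
    if np.any(intensity < 0):
        raise StructuralError("intensity must be nonnegative")
    h, w = intensity.shape
    if h % L or w % L:
        raise StructuralError(
            f"intensity shape {intensity.shape} not divisible by L={L}; "
            "pad the simulation grid"
        )
    return intensity.reshape(h // L, L, w // L, L).mean(axis=(1, 3))


def _shot_noise(
    intensity: np.ndarray, photon_budget: float, seed_key: tuple[int, ...]
) -> np.ndarray:
    rng = np.random.default_rng(seed_key)
    return rng.poisson(photon_budget * intensity).astype(np.float64) / photon_budget


def simulate_stack(
    object_per_band: Mapping[str, ComplexField],
    plan: WavelengthPlan,
    acq: AcquisitionSpec,
) -> HologramStack:
    """Forward-model a full multi-wavelength acquisition.

    For every wavelength of every band: propagate the band's object field
    to the sensor plane, record the intensity, integrate it over the pixel
    aperture, then (optionally) apply Poisson shot noise with a seed offset
    deterministically per (band, wavelength).
    """
    super_grid = acq.super_grid
    images: dict[tuple[str, float], np.ndarray] = {}
    for band_idx, (band, wavelengths) in enumerate(plan.bands.items()):
        try:
            obj = object_per_band[band]
        except KeyError:
            raise ConfigError(f"no object field supplied for band {band!r}") from None
        if obj.grid != super_grid:
            raise ConfigError(
                f"band {band!r}: object grid {obj.grid} != acquisition super grid "
                f"{super_grid} (sensor grid x L)"
            )
        for k, wl in enumerate(wavelengths):
            sensor = propagate(obj, wl, acq.z2_um)
            hologram = bin_to_sensor(np.abs(sensor.values) ** 2, acq.upsample_factor_L)
            if acq.noise_model == "shot":
                hologram = _shot_noise(
                    hologram, acq.photon_budget, (acq.rng_seed, band_idx, k)
                )
            images[(band, wl)] = hologram
    return HologramStack(grid=acq.sensor_grid, images=images)
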