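"""Scalar free-space wave optics on sampled complex fields.

Angular-spectrum propagation with a hard evanescent cutoff, plane-wave
tilt carriers, and the inter-wavelength phase rescaling used by the
wavelength-scanning reconstruction.

Conventions
-----------
* Time convention ``exp(+j 2 pi f t)``; forward propagation
  (object -> sensor) uses positive ``distance_um``.
* The frequency lattice follows the FFT layout (zero frequency first);
  spatial frequencies are in cycles/um.
* Coordinates are pixel-centred, origin at the top-left pixel, row-major:
  pixel ``(i, j)`` sits at ``(y, x) = (i, j) * pitch_um``.
* Wavelengths are given in nm, distances and pitches in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .errors import InvalidParameterError, StructuralError

__all__ = [
    "GridSpec",
    "ComplexField",
    "IlluminationGeometry",
    "angular_spectrum_kernel",
    "propagate",
    "tilt_carrier",
    "phase_rescale",
]


@dataclass(frozen=True)
class GridSpec:
    """Sampling lattice of a 2D field: pixel counts and physical pitch."""

    height_px: int
    width_px: int
    pitch_um: float

    def __post_init__(self) -> None:
        if self.height_px < 2 or self.width_px < 2:
            raise InvalidParameterError(
                f"grid must be at least 2x2, got {self.height_px}x{self.width_px}"
            )
        if not self.pitch_um > 0:
            raise InvalidParameterError(f"pitch_um must be > 0, got {self.pitch_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def x_coords_um(self) -> np.ndarray:
        """Pixel-centre x coordinates (1D, length ``width_px``)."""
        return np.arange(self.width_px) * self.pitch_um

    def y_coords_um(self) -> np.ndarray:
        """Pixel-centre y coordinates (1D, length ``height_px``)."""
        return np.arange(self.height_px) * self.pitch_um

    def freq_x(self) -> np.ndarray:
        """FFT-ordered spatial frequencies along x, cycles/um."""
        return np.fft.fftfreq(self.width_px, d=self.pitch_um)

    def freq_y(self) -> np.ndarray:
        """FFT-ordered spatial frequencies along y, cycles/um."""
        return np.fft.fftfreq(self.height_px, d=self.pitch_um)

    def upsampled(self, factor: int) -> "GridSpec":
        """Grid covering the same physical extent at ``factor`` x finer pitch."""
        return GridSpec(
            self.height_px * factor, self.width_px * factor, self.pitch_um / factor
        )


@dataclass
class ComplexField:
    """A 2D complex optical amplitude sampled on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.complex128)
        if values.shape != self.grid.shape:
            raise StructuralError(
                f"field values shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise StructuralError("field values contain non-finite entries")
        self.values = values

    @classmethod
    def from_amplitude_phase(
        cls,
        grid: GridSpec,
        amplitude: np.ndarray,
        phase: np.ndarray | float = 0.0,
    ) -> "ComplexField":
        amplitude = np.asarray(amplitude, dtype=np.float64)
        return cls(grid, amplitude * np.exp(1j * np.asarray(phase, dtype=np.float64)))

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def phase(self) -> np.ndarray:
        """Per-pixel wrapped phase in (-pi, pi]."""
        return np.angle(self.values)

    def copy(self) -> "ComplexField":
        return ComplexField(self.grid, self.values.copy())


@dataclass(frozen=True)
class IlluminationGeometry:
    """Plane-wave illumination direction and the propagation medium index."""

    theta_rad: float = 0.0
    phi_rad: float = 0.0
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_rad < np.pi / 2):
            raise InvalidParameterError(
                f"theta_rad must lie in [0, pi/2), got {self.theta_rad}"
            )
        if self.medium_index < 1.0:
            raise InvalidParameterError(
                f"medium_index must be >= 1, got {self.medium_index}"
            )

    def carrier_freqs(self, wavelength_nm: float) -> tuple[float, float]:
        """Transverse carrier frequencies (f_x, f_y) in cycles/um."""
        lam_um = _wavelength_um(wavelength_nm)
        s = self.medium_index * np.sin(self.theta_rad) / lam_um
        return (s * np.cos(self.phi_rad), s * np.sin(self.phi_rad))


def _wavelength_um(wavelength_nm: float) -> float:
    if not wavelength_nm > 0:
        raise InvalidParameterError(f"wavelength_nm must be > 0, got {wavelength_nm}")
    return wavelength_nm * 1e-3


def angular_spectrum_kernel(
    grid: GridSpec,
    wavelength_nm: float,
    distance_um: float,
    medium_index: float = 1.0,
) -> np.ndarray:
    """Frequency-domain free-space transfer function on the FFT lattice.

    Propagating frequencies (``f_x^2 + f_y^2 <= (n/lambda)^2``) get the
    unit-magnitude phase factor
    ``exp(j 2 pi z sqrt((n/lambda)^2 - f_x^2 - f_y^2))``;
    evanescent frequencies are zeroed outright (hard cutoff).  The sign of
    ``distance_um`` selects forward (+z) versus backward (-z) propagation.
    """
    lam_um = _wavelength_um(wavelength_nm)
    if not medium_index > 0:
        raise InvalidParameterError(f"medium_index must be > 0, got {medium_index}")
    fx = grid.freq_x()[None, :]
    fy = grid.freq_y()[:, None]
    kz_sq = (medium_index / lam_um) ** 2 - fx**2 - fy**2
    propagating = kz_sq >= 0.0
    kz = np.sqrt(np.where(propagating, kz_sq, 0.0))
    kernel = np.exp(1j * (2.0 * np.pi * distance_um) * kz)
    kernel[~propagating] = 0.0
    return kernel


def propagate(
    field: ComplexField,
    wavelength_nm: float,
    distance_um: float,
    medium_index: float = 1.0,
) -> ComplexField:
    """Angular-spectrum propagation of ``field`` by ``distance_um``.

    Returns ``ifft2(kernel * fft2(field))`` on the same grid.  Energy in the
    propagating band is conserved exactly (the kernel has unit magnitude
    there); evanescent content is discarded.
    """
    kernel = angular_spectrum_kernel(field.grid, wavelength_nm, distance_um, medium_index)
    spectrum = scipy.fft.fft2(field.values)
    out = scipy.fft.ifft2(kernel * spectrum)
    return ComplexField(field.grid, out)


def tilt_carrier(
    geometry: IlluminationGeometry, wavelength_nm: float, grid: GridSpec
) -> ComplexField:
    """Unit-magnitude phase ramp ``exp(j 2 pi (f_x x + f_y y))`` on ``grid``.

    The carrier frequencies follow
    ``f_x = n sin(theta) cos(phi) / lambda`` and
    ``f_y = n sin(theta) sin(phi) / lambda``.
    """
    f_x, f_y = geometry.carrier_freqs(wavelength_nm)
    x = grid.x_coords_um()[None, :]
    y = grid.y_coords_um()[:, None]
    return ComplexField(grid, np.exp(2j * np.pi * (f_x * x + f_y * y)))


def phase_rescale(
    field: ComplexField, lambda_from_nm: float, lambda_to_nm: float
) -> ComplexField:
    """Re-reference a retrieved field from one wavelength to another.

    For a thin object the optical path length, not the phase, is
    wavelength-invariant, so the wrapped per-pixel phase ``phi`` (taken in
    ``(-pi, pi]``) is replaced by ``phi * lambda_from / lambda_to`` while the
    amplitude is left untouched.  No unwrapping is attempted.
    """
    ratio = _wavelength_um(lambda_from_nm) / _wavelength_um(lambda_to_nm)
    if ratio == 1.0:
        return field.copy()
    magnitude = np.abs(field.values)
    phase = np.angle(field.values)
    return ComplexField(field.grid, magnitude * np.exp(1j * (phase * ratio)))
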