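"""Quantitative evaluation: bar-target contrast, recovery fidelity and
background chroma artifacts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .colour import ColourPlanes, rgb_to_yuv
from .errors import ConfigError, GeometryError, UndefinedCorrelationError
from .field_optics import ComplexField, GridSpec
from .reconstruct import ObjectEstimate
from .synthetic_scene import TargetPlacement

__all__ = [
    "ResolutionReport",
    "michelson_contrast",
    "smallest_resolved_width",
    "recovery_error",
    "chroma_artifact_score",
]

#: Fraction of the bar length averaged over when extracting the profile.
_PROFILE_LENGTH_FRACTION = 0.6

#: Default contrast threshold for calling a bar element "resolved".
DEFAULT_CONTRAST_THRESHOLD = 0.15


@dataclass
class ResolutionReport:
    """Per-width Michelson contrasts and the finest fully resolved width."""

    contrasts: dict[float, dict[str, float]]
    smallest_resolved_um: float | None
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "smallest_resolved_um": self.smallest_resolved_um,
            "contrasts": {
                str(w): dict(per_orient) for w, per_orient in self.contrasts.items()
            },
        }


def _profile_and_positions(
    image: np.ndarray,
    grid: GridSpec,
    placement: TargetPlacement,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean profile across the bars plus trough/peak sampling positions (um)."""
    spec = placement.spec
    xc, yc = placement.center_um
    if spec.orientation == "vertical":
        prof_axis_c, avg_axis_c = xc, yc
        axis_coords = grid.x_coords_um()
        avg_coords = grid.y_coords_um()
        img = image
    else:
        prof_axis_c, avg_axis_c = yc, xc
        axis_coords = grid.y_coords_um()
        avg_coords = grid.x_coords_um()
        img = image.T
    half_avg = _PROFILE_LENGTH_FRACTION * spec.bar_length_um / 2.0
    rows = np.flatnonzero(np.abs(avg_coords - avg_axis_c) <= half_avg)
    if rows.size == 0:
        raise GeometryError("bar length window contains no pixels")
    profile = img[rows, :].mean(axis=0)

    troughs = prof_axis_c + spec.bar_offsets_um()
    p = spec.period_um
    n = spec.n_bars
    gap_centres = prof_axis_c + (np.arange(n - 1) - (n - 2) / 2.0) * p
    flank = (n - 1) / 2.0 * p + p / 2.0
    flanks = np.array([prof_axis_c - flank, prof_axis_c + flank])
    peaks = np.concatenate([gap_centres, flanks])
    lo, hi = axis_coords[0], axis_coords[-1]
    for pos in np.concatenate([troughs, peaks]):
        if pos < lo or pos > hi:
            raise GeometryError(f"sampling position {pos} um outside the image")
    return profile, axis_coords, troughs, peaks


def michelson_contrast(
    image: np.ndarray,
    grid: GridSpec,
    placement: TargetPlacement,
) -> float:
    """(I_max - I_min) / (I_max + I_min) of a three-bar element, in [0, 1].

    The profile perpendicular to the bars is averaged along the central
    portion of the bar length; I_min is the mean of the profile at the bar
    centres, I_max the mean at the gap and flank centres (linear
    interpolation between pixel centres).
    """
    image = np.asarray(image, dtype=np.float64)
    profile, coords, troughs, peaks = _profile_and_positions(image, grid, placement)
    i_min = float(np.mean(np.interp(troughs, coords, profile)))
    i_max = float(np.mean(np.interp(peaks, coords, profile)))
    denom = i_max + i_min
    if denom <= 0:
        return 0.0
    return float(np.clip((i_max - i_min) / denom, 0.0, 1.0))


def smallest_resolved_width(
    recon_amplitude: np.ndarray,
    grid: GridSpec,
    ladder: Sequence[TargetPlacement],
    threshold: float = DEFAULT_CONTRAST_THRESHOLD,
) -> ResolutionReport:
    """Finest bar width whose contrast passes ``threshold`` in BOTH orientations.

    Widths are scanned from coarse to fine and, following the USAF reading
    convention, the scan stops at the first width that fails — finer widths
    that might pass incidentally are not credited.
    """
    if len(ladder) == 0:
        raise ConfigError("ladder must contain at least one placement")
    by_width: dict[float, list[TargetPlacement]] = {}
    for placement in ladder:
        by_width.setdefault(placement.spec.line_width_um, []).append(placement)
    contrasts: dict[float, dict[str, float]] = {}
    smallest: float | None = None
    stopped = False
    for width in sorted(by_width, reverse=True):
        per_orient = {
            p.spec.orientation: michelson_contrast(recon_amplitude, grid, p)
            for p in by_width[width]
        }
        contrasts[width] = per_orient
        if stopped:
            continue
        if all(c >= threshold for c in per_orient.values()):
            smallest = width
        else:
            stopped = True
    return ResolutionReport(
        contrasts=contrasts, smallest_resolved_um=smallest, threshold=threshold
    )


def recovery_error(
    estimate: ObjectEstimate | ComplexField,
    truth: ComplexField,
    region: np.ndarray | None = None,
) -> dict[str, float]:
    """Pearson r and normalized RMS error between |estimate| and |truth|.

    ``nrmse`` is the RMS difference divided by the standard deviation of
    |truth| over the region, so additive noise of known sigma yields
    ``nrmse ~= sigma / std(|truth|)``.
    """
    est_field = estimate.field if isinstance(estimate, ObjectEstimate) else estimate
    if est_field.grid != truth.grid:
        raise ConfigError("estimate and truth are on different grids")
    a = np.abs(est_field.values)
    b = np.abs(truth.values)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        a, b = a[region], b[region]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for zero-variance input"
        )
    r = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
    nrmse = float(np.sqrt(np.mean((a - b) ** 2)) / np.std(b))
    return {"pearson_r": r, "nrmse": nrmse}


def chroma_artifact_score(
    planes: ColourPlanes, background_mask: np.ndarray
) -> float:
    """sqrt(var(U) + var(V)) over a blank background region.

    Zero for achromatic or constant-chroma images; chroma mean filtering
    strictly reduces it whenever the background chroma is non-constant.
    """
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != planes.shape:
        raise ConfigError("background_mask shape != planes shape")
    if not background_mask.any():
        raise ConfigError("background_mask is empty")
    if planes.U is None or planes.V is None:
        planes = rgb_to_yuv(planes)
    u = planes.U[background_mask]
    v = planes.V[background_mask]
    return float(np.sqrt(np.var(u) + np.var(v)))
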