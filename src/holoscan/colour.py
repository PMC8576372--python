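"""RGB composition and YUV-space chroma smoothing.

Per-band reconstructions are composed into an RGB image; converting to YUV,
mean-filtering only the chroma planes (U, V) and converting back removes
the rainbow artifacts of coherent colour holography while leaving the
luminance (and hence all brightness detail) bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage

from .errors import ConfigError, StructuralError
from .reconstruct import ObjectEstimate

__all__ = [
    "ColourPlanes",
    "RGB_TO_YUV",
    "YUV_TO_RGB",
    "compose_rgb",
    "rgb_to_yuv",
    "yuv_to_rgb",
    "enhance_colour",
    "ablation_replace_y",
]

# BT.601 full-range luma/chroma coefficients.
RGB_TO_YUV = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.492 * -0.299, 0.492 * -0.587, 0.492 * (1 - 0.114)],
        [0.877 * (1 - 0.299), 0.877 * -0.587, 0.877 * -0.114],
    ]
)
YUV_TO_RGB = np.linalg.inv(RGB_TO_YUV)


@dataclass
class ColourPlanes:
    """Registered R/G/B (and optionally Y/U/V) real-valued image planes."""

    R: np.ndarray
    G: np.ndarray
    B: np.ndarray
    Y: np.ndarray | None = None
    U: np.ndarray | None = None
    V: np.ndarray | None = None

    def __post_init__(self) -> None:
        planes = {"R": self.R, "G": self.G, "B": self.B}
        shape = None
        for name, p in planes.items():
            p = np.asarray(p, dtype=np.float64)
            if shape is None:
                shape = p.shape
            elif p.shape != shape:
                raise StructuralError(f"plane {name} shape {p.shape} != {shape}")
            setattr(self, name, p)
        for name in ("Y", "U", "V"):
            p = getattr(self, name)
            if p is not None:
                p = np.asarray(p, dtype=np.float64)
                if p.shape != shape:
                    raise StructuralError(f"plane {name} shape {p.shape} != {shape}")
                setattr(self, name, p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.R.shape

    def rgb_stack(self) -> np.ndarray:
        """(H, W, 3) array of the R, G, B planes."""
        return np.stack([self.R, self.G, self.B], axis=-1)


def _normalize(intensity: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "background":
        # modal intensity ~= blank background level; refine the modal bin
        # by the median of its members so a constant background maps to
        # exactly 1.0
        hist, edges = np.histogram(intensity, bins=512)
        i = int(np.argmax(hist))
        members = intensity[(intensity >= edges[i]) & (intensity <= edges[i + 1])]
        mode = float(np.median(members)) if members.size else 0.0
        ref = mode if mode > 0 else float(np.max(intensity))
    elif normalization == "percentile":
        ref = np.percentile(intensity, 99)
    else:
        raise ConfigError(f"unknown normalization {normalization!r}")
    if ref <= 0:
        return np.zeros_like(intensity)
    return np.clip(intensity / ref, 0.0, 1.0)


def compose_rgb(
    O_R: ObjectEstimate,
    O_G: ObjectEstimate,
    O_B: ObjectEstimate,
    normalization: str = "background",
) -> ColourPlanes:
    """Per-channel intensity images (squared magnitudes), normalized to [0, 1].

    ``background`` normalization divides by the modal (background)
    intensity so a blank field maps to 1.0; ``percentile`` divides by the
    99th percentile.  Both clip to [0, 1].
    """
    grids = {e.field.grid for e in (O_R, O_G, O_B)}
    if len(grids) != 1:
        raise StructuralError(f"band estimates on mismatched grids: {grids}")
    planes = [
        _normalize(np.abs(e.field.values) ** 2, normalization)
        for e in (O_R, O_G, O_B)
    ]
    return ColourPlanes(R=planes[0], G=planes[1], B=planes[2])


def rgb_to_yuv(planes: ColourPlanes) -> ColourPlanes:
    """Fill the Y/U/V planes from R/G/B (BT.601 full range)."""
    rgb = planes.rgb_stack()
    yuv = rgb @ RGB_TO_YUV.T
    return replace(planes, Y=yuv[..., 0], U=yuv[..., 1], V=yuv[..., 2])


def yuv_to_rgb(planes: ColourPlanes) -> ColourPlanes:
    """Fill R/G/B from Y/U/V (exact matrix inverse), clipped to [0, 1]."""
    if planes.Y is None or planes.U is None or planes.V is None:
        raise ConfigError("yuv_to_rgb requires Y, U and V planes")
    yuv = np.stack([planes.Y, planes.U, planes.V], axis=-1)
    rgb = np.clip(yuv @ YUV_TO_RGB.T, 0.0, 1.0)
    return replace(planes, R=rgb[..., 0], G=rgb[..., 1], B=rgb[..., 2])


def _filter_chroma(plane: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return plane.copy()
    return scipy.ndimage.uniform_filter(plane, size=k, mode="reflect")


def enhance_colour(planes: ColourPlanes, chroma_filter_px: int = 9) -> ColourPlanes:
    """Chroma-only smoothing: Y untouched, U/V mean-filtered, RGB rebuilt.

    The returned planes carry the filtered U/V and the RGB image recomputed
    from (Y, U_ave, V_ave); the Y plane is bit-identical to the input's.
    """
    if chroma_filter_px < 1 or chroma_filter_px % 2 == 0:
        raise ConfigError(f"chroma_filter_px must be odd >= 1, got {chroma_filter_px}")
    if planes.Y is None:
        planes = rgb_to_yuv(planes)
    u_ave = _filter_chroma(planes.U, chroma_filter_px)
    v_ave = _filter_chroma(planes.V, chroma_filter_px)
    return yuv_to_rgb(replace(planes, U=u_ave, V=v_ave))


def ablation_replace_y(
    lowres_planes: ColourPlanes,
    hr_single_channel: np.ndarray,
    chroma_filter_px: int = 9,
) -> ColourPlanes:
    """Comparison baseline: chroma from a low-resolution colour image,
    luminance replaced wholesale by one high-resolution single-band image.

    Loses any brightness detail that is visible only in the other bands;
    kept to quantify that loss against the full three-band pipeline.
    """
    hr = np.asarray(hr_single_channel, dtype=np.float64)
    if hr.shape != lowres_planes.shape:
        raise StructuralError(
            f"hr_single_channel shape {hr.shape} != planes shape {lowres_planes.shape}"
        )
    if chroma_filter_px < 1 or chroma_filter_px % 2 == 0:
        raise ConfigError(f"chroma_filter_px must be odd >= 1, got {chroma_filter_px}")
    yuv = rgb_to_yuv(lowres_planes) if lowres_planes.Y is None else lowres_planes
    u_ave = _filter_chroma(yuv.U, chroma_filter_px)
    v_ave = _filter_chroma(yuv.V, chroma_filter_px)
    return yuv_to_rgb(replace(yuv, Y=hr, U=u_ave, V=v_ave))
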