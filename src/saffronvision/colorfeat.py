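"""Color features and hue-window composition analysis.

A graded saffron sample is mostly red stigma tissue; yellow style and white
debris count as lower-value "foreign matter". This module converts the
cropped image into 18 color-channel maps, segments foreign matter with a hue
window (plus a low-saturation/high-intensity rule for achromatic white),
and reports the three composition percentages. The per-sample color feature
block is the 18 foreground channel means followed by the 3 percentages —
21 values.

Channel glossary (all maps share the image's shape):

====  =====================================================================
R G B raw 8-bit sensor channels
H S   hue and saturation of the HSV conversion, in [0, 1]
r     chromaticity R/(R+G+B), in [0, 1]
L* a* b*  CIELAB under D65
C     chroma sqrt(a*^2 + b*^2)
I     intensity (R+G+B)/3
E     Euclidean RGB norm sqrt(R^2+G^2+B^2)/sqrt(3)
Y Cb Cr   ITU-R BT.601 studio-range digital video components
Y' I' Q   NTSC YIQ components (unit scale)
====  =====================================================================

Y/Y' and I/I' are distinct definitions that happen to share a letter; both
positions are kept so the block totals 18 channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

__all__ = [
    "CHANNEL_NAMES",
    "ColorParams",
    "CompositionFractions",
    "to_channels",
    "hue_saturation_intensity",
    "yellow_white_mask",
    "composition",
    "color_feature_block",
    "color_feature_names",
]

CHANNEL_NAMES = (
    "R", "G", "B", "H", "S", "r", "L*", "a*", "b*",
    "C", "I", "E", "Y", "Cb", "Cr", "Y'", "I'", "Q",
)


@dataclass(frozen=True)
class ColorParams:
    """Hue window for foreign matter (style yellow) plus the white rule.

    ``hue_min``/``hue_max`` bound the closed hue interval, on the [0, 1]
    hue circle, that selects yellow pixels. Achromatic white has no stable
    hue, so pixels with saturation below ``white_saturation_max`` and
    intensity above ``white_intensity_min`` (fraction of 255) are selected
    as well.
    """

    hue_min: float = 0.045
    hue_max: float = 0.279
    white_saturation_max: float = 0.1
    white_intensity_min: float = 0.8
    channel_list: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_min < self.hue_max <= 1.0):
            raise ValueError("require 0 <= hue_min < hue_max <= 1")
        if len(self.channel_list) != 18:
            raise ValueError("channel_list must have exactly 18 entries")


@dataclass(frozen=True)
class CompositionFractions:
    """Composition of the foreground, in percent of foreground pixels."""

    foreign_pct: float
    stigma_pct: float
    foreign_to_stigma_pct: float


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB, got {image.shape}")
    return image.astype(np.float64)


def hue_saturation_intensity(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(H, S, I) maps: HSV hue and saturation in [0, 1], intensity (R+G+B)/3.

    This is the single hue definition used both for the H feature channel
    and for the foreign-matter segmentation.
    """
    rgb = _as_float_rgb(image) / 255.0
    hsv = skcolor.rgb2hsv(rgb)
    intensity = rgb.mean(axis=2) * 255.0
    return hsv[..., 0], hsv[..., 1], intensity


def to_channels(image: np.ndarray) -> dict[str, np.ndarray]:
    """Decompose an 8-bit RGB image into the 18 named channel maps."""
    rgbf = _as_float_rgb(image)
    rgb01 = rgbf / 255.0
    R, G, B = rgbf[..., 0], rgbf[..., 1], rgbf[..., 2]
    H, S, I = hue_saturation_intensity(image)
    total = R + G + B
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, R / np.where(total > 0, total, 1.0), 1.0 / 3.0)
    lab = skcolor.rgb2lab(rgb01)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    C = np.hypot(a, b)
    E = np.sqrt(R**2 + G**2 + B**2) / np.sqrt(3.0)
    ycbcr = skcolor.rgb2ycbcr(rgb01)
    yiq = skcolor.rgb2yiq(rgb01)
    maps = {
        "R": R, "G": G, "B": B, "H": H, "S": S, "r": r,
        "L*": L, "a*": a, "b*": b, "C": C, "I": I, "E": E,
        "Y": ycbcr[..., 0], "Cb": ycbcr[..., 1], "Cr": ycbcr[..., 2],
        "Y'": yiq[..., 0], "I'": yiq[..., 1], "Q": yiq[..., 2],
    }
    return {name: maps[name] for name in CHANNEL_NAMES}


def yellow_white_mask(
    image: np.ndarray,
    params: ColorParams = ColorParams(),
    foreground: np.ndarray | None = None,
) -> np.ndarray:
    """Foreign-matter mask: hue in the closed yellow window, or achromatic white.

    The result is restricted to ``foreground`` when one is given.
    """
    H, S, I = hue_saturation_intensity(image)
    mask = (H >= params.hue_min) & (H <= params.hue_max)
    mask |= (S < params.white_saturation_max) & (I > params.white_intensity_min * 255.0)
    if foreground is not None:
        foreground = np.asarray(foreground, dtype=bool)
        if foreground.shape != mask.shape:
            raise ValueError("foreground mask shape mismatch")
        mask &= foreground
    return mask


def composition(foreground: np.ndarray, foreign: np.ndarray) -> CompositionFractions:
    """Composition percentages from the foreground and foreign-matter masks.

    ``foreign`` must be a subset of ``foreground``. When every foreground
    pixel is foreign the foreign-to-stigma ratio is reported as +inf with a
    warning.
    """
    foreground = np.asarray(foreground, dtype=bool)
    foreign = np.asarray(foreign, dtype=bool)
    if foreign.shape != foreground.shape:
        raise ValueError("mask shape mismatch")
    if np.any(foreign & ~foreground):
        raise ValueError("foreign mask must be a subset of the foreground mask")
    n_fg = int(foreground.sum())
    if n_fg == 0:
        raise ValueError("empty foreground: composition undefined")
    n_foreign = int(foreign.sum())
    foreign_pct = 100.0 * n_foreign / n_fg
    stigma_pct = 100.0 - foreign_pct
    n_stigma = n_fg - n_foreign
    if n_stigma == 0:
        warnings.warn("no stigma pixels: foreign-to-stigma ratio is infinite")
        ratio = np.inf
    else:
        ratio = 100.0 * n_foreign / n_stigma
    return CompositionFractions(foreign_pct, stigma_pct, ratio)


def color_feature_names(params: ColorParams = ColorParams()) -> list[str]:
    """The 21 color feature names, in block order."""
    return [f"color.mean_{name}" for name in params.channel_list] + [
        "color.foreign_pct",
        "color.stigma_pct",
        "color.foreign_to_stigma_pct",
    ]


def color_feature_block(
    image: np.ndarray,
    foreground: np.ndarray,
    params: ColorParams = ColorParams(),
) -> dict[str, float]:
    """The 21-entry color block: 18 foreground channel means + 3 percentages."""
    foreground = np.asarray(foreground, dtype=bool)
    channels = to_channels(image)
    if foreground.shape != next(iter(channels.values())).shape:
        raise ValueError("foreground mask shape mismatch")
    if not foreground.any():
        raise ValueError("empty foreground: color features undefined")
    feats: dict[str, float] = {}
    for name in params.channel_list:
        feats[f"color.mean_{name}"] = float(channels[name][foreground].mean())
    foreign = yellow_white_mask(image, params, foreground)
    comp = composition(foreground, foreign)
    feats["color.foreign_pct"] = comp.foreign_pct
    feats["color.stigma_pct"] = comp.stigma_pct
    feats["color.foreign_to_stigma_pct"] = comp.foreign_to_stigma_pct
    return feats
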