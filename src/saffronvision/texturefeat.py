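"""Texture features: GLCM statistics, local entropy/STD maps, LBP, histograms.

The texture block describes the spatial arrangement of gray levels inside
the segmented saffron region. Four families are combined into a fixed
99-entry registry:

* gray-level co-occurrence matrix (GLCM) contrast, correlation, energy and
  homogeneity at 4 angles x 2 distances (32), plus their offset averages (4);
* seven first-order histogram statistics (mean, standard deviation,
  smoothness, third moment, uniformity, entropy, gray-level range) of the
  local-entropy map, the local-STD map and the LBP code map (21) and of the
  raw gray levels (7);
* a 25-bin normalized gray-level histogram (25);
* a 10-bin rotation-invariant-uniform LBP code histogram (10).

All statistics are computed over the foreground mask only: GLCM pairs must
have both pixels in the mask, and map statistics are taken at mask pixels
(filter windows near the mask boundary may touch background — see the
methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .preprocess import intensity

__all__ = [
    "TextureParams",
    "Glcm",
    "to_gray",
    "glcm",
    "glcm_stats",
    "local_entropy",
    "local_std",
    "lbp",
    "lbp_riu2_histogram",
    "table1_stats",
    "histogram25",
    "texture_feature_block",
    "texture_feature_names",
    "FIRST_ORDER_STAT_NAMES",
]

FIRST_ORDER_STAT_NAMES = (
    "mean", "std", "smoothness", "third_moment", "uniformity", "entropy", "range",
)

GLCM_STAT_NAMES = ("contrast", "correlation", "energy", "homogeneity")

#: (row, col) steps for the standard GLCM angles, at unit distance.
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class TextureParams:
    glcm_levels: int = 8
    glcm_distances: tuple[int, ...] = (1, 2)
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    entropy_window: int = 9
    entropy_levels: int = 32
    std_window: int = 3
    histogram_bins: int = 25
    table1_levels: int = 256

    def __post_init__(self) -> None:
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        for w, name in ((self.entropy_window, "entropy_window"), (self.std_window, "std_window")):
            if w <= 0 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {w}")
        for a in self.glcm_angles:
            if a not in _ANGLE_STEPS:
                raise ValueError(f"unsupported GLCM angle {a}; use 0/45/90/135")


@dataclass
class Glcm:
    """Normalized gray-level co-occurrence matrix with its marginals."""

    p: np.ndarray
    levels: int
    offset: tuple[int, int]

    @property
    def mu_i(self) -> float:
        i = np.arange(self.levels)
        return float((i[:, None] * self.p).sum())

    @property
    def mu_j(self) -> float:
        j = np.arange(self.levels)
        return float((j[None, :] * self.p).sum())

    @property
    def sigma_i(self) -> float:
        i = np.arange(self.levels)
        return float(np.sqrt((((i[:, None] - self.mu_i) ** 2) * self.p).sum()))

    @property
    def sigma_j(self) -> float:
        j = np.arange(self.levels)
        return float(np.sqrt((((j[None, :] - self.mu_j) ** 2) * self.p).sum()))


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luma grayscale (same definition as the preprocessing intensity)."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    return intensity(image)


def _quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform binning of [0, 255] into ``levels`` bins."""
    return (np.asarray(gray).astype(np.int64) * levels) // 256


def glcm(
    gray: np.ndarray,
    offset: tuple[int, int],
    levels: int = 8,
    mask: np.ndarray | None = None,
) -> Glcm:
    """Symmetric normalized co-occurrence matrix for one pixel offset.

    A pair is counted when both the pixel and the offset pixel lie inside
    the image (and the mask, if given); each pair is counted in both
    directions, and the matrix is normalized to sum to 1.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("gray must be 2-D")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    dr, dc = offset
    h, w = gray.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} exceeds image extent {gray.shape}")
    q = _quantize(gray, levels)
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)

    # slice the overlap of the image with its offset copy
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        raise ValueError(f"no valid pixel pair for offset {offset}")
    codes = a[valid] * levels + b[valid]
    counts = np.bincount(codes, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetrize: count both directions
    p = counts / counts.sum()
    return Glcm(p=p, levels=levels, offset=(dr, dc))


def glcm_stats(g: Glcm) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM.

    Correlation of a degenerate matrix (zero marginal deviation) is defined
    as 0, with a warning.
    """
    p = g.p
    i = np.arange(g.levels)[:, None]
    j = np.arange(g.levels)[None, :]
    contrast = float((((i - j) ** 2) * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    si, sj = g.sigma_i, g.sigma_j
    if si == 0.0 or sj == 0.0:
        warnings.warn("degenerate GLCM (zero marginal deviation): correlation set to 0")
        correlation = 0.0
    else:
        correlation = float((((i - g.mu_i) * (j - g.mu_j) * p).sum()) / (si * sj))
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def local_entropy(gray: np.ndarray, window: int = 9, levels: int = 32) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the windowed gray-level histogram.

    Gray values are quantized into ``levels`` uniform bins of [0, 255]
    before the window histogram is formed; boundaries use symmetric
    padding. A moving-average filter per occupied level gives the window
    probabilities, so cost scales with the number of distinct levels.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    gray = np.asarray(gray)
    q = _quantize(gray, levels)
    ent = np.zeros(gray.shape, dtype=np.float64)
    for v in np.unique(q):
        p = ndi.uniform_filter((q == v).astype(np.float64), size=window, mode="reflect")
        np.clip(p, 0.0, 1.0, out=p)
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    np.clip(ent, 0.0, None, out=ent)
    return ent


def local_std(gray: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-pixel population standard deviation over the window (symmetric padding)."""
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    g = np.asarray(gray, dtype=np.float64)
    m = ndi.uniform_filter(g, size=window, mode="reflect")
    m2 = ndi.uniform_filter(g * g, size=window, mode="reflect")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


# clockwise from the top-left neighbor, weights 2^0 .. 2^7
_LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp(gray: np.ndarray) -> np.ndarray:
    """Basic 3x3 local binary pattern codes (0-255) for interior pixels.

    A neighbor contributes its weight when it is >= the center value (ties
    count as 1); weights 2^0..2^7 run clockwise from the top-left neighbor.
    The output has shape (H-2, W-2): border pixels have no full 3x3
    neighborhood and are excluded.
    """
    g = np.asarray(gray, dtype=np.int64)
    if g.ndim != 2 or g.shape[0] < 3 or g.shape[1] < 3:
        raise ValueError("gray must be 2-D and at least 3 x 3")
    center = g[1:-1, 1:-1]
    code = np.zeros(center.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = g[1 + dr : g.shape[0] - 1 + dr, 1 + dc : g.shape[1] - 1 + dc]
        code |= (nb >= center).astype(np.int64) << bit
    return code


def _riu2_table() -> np.ndarray:
    """Map each 8-bit LBP code to its rotation-invariant-uniform bin (0-9)."""
    table = np.empty(256, dtype=np.int64)
    for c in range(256):
        bits = [(c >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        table[c] = sum(bits) if transitions <= 2 else 9
    return table


_RIU2 = _riu2_table()


def lbp_riu2_histogram(codes: np.ndarray) -> np.ndarray:
    """Normalized 10-bin histogram of rotation-invariant-uniform LBP labels."""
    codes = np.asarray(codes).ravel()
    if codes.size == 0:
        raise ValueError("empty code collection")
    hist = np.bincount(_RIU2[codes], minlength=10).astype(np.float64)
    return hist / hist.sum()


def table1_stats(
    values: np.ndarray,
    levels: int = 256,
    value_range: tuple[float, float] = (0.0, 255.0),
) -> dict[str, float]:
    """Seven first-order statistics of the normalized level histogram.

    The histogram has ``levels`` equal-width bins spanning ``value_range``
    (values clipped into it); all statistics are in bin-index units:
    mean, standard deviation, smoothness 1 - 1/(1+sigma^2), third central
    moment, uniformity sum(p_i^2), entropy -sum(p_i log2 p_i), and the
    occupied gray-level range max{i: p_i>0} - min{i: p_i>0}.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty value collection")
    lo, hi = value_range
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=levels, range=(lo, hi))
    p = counts / counts.sum()
    i = np.arange(levels, dtype=np.float64)
    mu = float((i * p).sum())
    var = float((((i - mu) ** 2) * p).sum())
    sigma = float(np.sqrt(var))
    nz = np.flatnonzero(p)
    pn = p[nz]
    return {
        "mean": mu,
        "std": sigma,
        "smoothness": 1.0 - 1.0 / (1.0 + var),
        "third_moment": float((((i - mu) ** 3) * p).sum()),
        "uniformity": float((p**2).sum()),
        "entropy": float(-(pn * np.log2(pn)).sum()),
        "range": float(nz[-1] - nz[0]),
    }


def histogram25(values: np.ndarray, bins: int = 25) -> np.ndarray:
    """Normalized gray-level histogram, 25 equal-width bins over [0, 255]."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty value collection")
    counts, _ = np.histogram(np.clip(values, 0, 255), bins=bins, range=(0.0, 255.0))
    return counts / counts.sum()


def _offsets(params: TextureParams) -> list[tuple[int, int, tuple[int, int]]]:
    out = []
    for d in params.glcm_distances:
        for a in params.glcm_angles:
            sr, sc = _ANGLE_STEPS[a]
            out.append((d, a, (sr * d, sc * d)))
    return out


def texture_feature_names(params: TextureParams = TextureParams()) -> list[str]:
    """The 99 texture feature names, in registry order."""
    names: list[str] = []
    for d, a, _ in _offsets(params):
        for s in GLCM_STAT_NAMES:
            names.append(f"tex.glcm_{s}_d{d}_a{a}")
    for s in GLCM_STAT_NAMES:
        names.append(f"tex.glcm_{s}_mean")
    for source in ("entropy", "std", "lbp"):
        for s in FIRST_ORDER_STAT_NAMES:
            names.append(f"tex.{source}_{s}")
    for s in FIRST_ORDER_STAT_NAMES:
        names.append(f"tex.gray_{s}")
    for b in range(params.histogram_bins):
        names.append(f"tex.hist_bin{b:02d}")
    for b in range(10):
        names.append(f"tex.lbp_riu2_{b:02d}")
    return names


def texture_feature_block(
    gray: np.ndarray,
    mask: np.ndarray,
    params: TextureParams = TextureParams(),
) -> dict[str, float]:
    """The 99-entry texture block for a cropped gray image and its mask."""
    gray = np.asarray(gray)
    mask = np.asarray(mask, dtype=bool)
    if gray.shape != mask.shape:
        raise ValueError("gray/mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask: texture features undefined")

    feats: dict[str, float] = {}
    per_stat: dict[str, list[float]] = {s: [] for s in GLCM_STAT_NAMES}
    for d, a, off in _offsets(params):
        stats = glcm_stats(glcm(gray, off, params.glcm_levels, mask))
        for s in GLCM_STAT_NAMES:
            feats[f"tex.glcm_{s}_d{d}_a{a}"] = stats[s]
            per_stat[s].append(stats[s])
    for s in GLCM_STAT_NAMES:
        feats[f"tex.glcm_{s}_mean"] = float(np.mean(per_stat[s]))

    ent_map = local_entropy(gray, params.entropy_window, params.entropy_levels)
    std_map = local_std(gray, params.std_window)
    codes = lbp(gray)
    inner = mask[1:-1, 1:-1]
    if not inner.any():
        raise ValueError("mask has no interior pixels for LBP statistics")

    sources = {
        "entropy": (ent_map[mask], (0.0, float(np.log2(params.entropy_levels)))),
        "std": (std_map[mask], (0.0, 255.0)),
        "lbp": (codes[inner].astype(np.float64), (0.0, 255.0)),
    }
    for source, (vals, rng) in sources.items():
        stats = table1_stats(vals, params.table1_levels, rng)
        for s in FIRST_ORDER_STAT_NAMES:
            feats[f"tex.{source}_{s}"] = stats[s]

    gray_vals = gray[mask].astype(np.float64)
    stats = table1_stats(gray_vals, params.table1_levels, (0.0, 255.0))
    for s in FIRST_ORDER_STAT_NAMES:
        feats[f"tex.gray_{s}"] = stats[s]

    hist = histogram25(gray_vals, params.histogram_bins)
    for b, v in enumerate(hist):
        feats[f"tex.hist_bin{b:02d}"] = float(v)
    riu = lbp_riu2_histogram(codes[inner])
    for b, v in enumerate(riu):
        feats[f"tex.lbp_riu2_{b:02d}"] = float(v)
    return feats
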