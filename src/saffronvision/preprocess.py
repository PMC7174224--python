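"""Foreground segmentation and cropping of bulk-saffron images.

The imaging protocol places saffron threads on a near-black background, so
foreground extraction reduces to: low-pass smoothing, a global intensity
threshold, removal of small connected components (dust, stray fibres),
morphological opening, and a tight crop around the remaining foreground.

Conventions: pixel coordinates are 0-based; crop windows are half-open
``[row_min, row_max) x [col_min, col_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

__all__ = [
    "PreprocessParams",
    "CropWindow",
    "intensity",
    "smooth",
    "foreground_mask",
    "remove_small_components",
    "morph_refine",
    "crop_window",
    "preprocess_image",
]

#: ITU-R BT.601 luma weights; "intensity" of an RGB pixel throughout the package.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs of the segmentation stage.

    Parameters
    ----------
    smoothing_kernel_size : odd int
        Side of the Gaussian smoothing kernel, in pixels.
    smoothing_sigma : float
        Gaussian standard deviation, in pixels.
    intensity_threshold : int
        A pixel is foreground when its luma intensity is *strictly* greater
        than this value. The protocol's black background sits below 20.
    min_component_area : int
        Connected components with fewer pixels than this are discarded.
        The default matches the protocol's full-resolution camera frames;
        scale it down proportionally for smaller canvases.
    structuring_radius : int
        Radius of the disk used for the morphological opening.
    """

    smoothing_kernel_size: int = 5
    smoothing_sigma: float = 1.0
    intensity_threshold: int = 20
    min_component_area: int = 3000
    structuring_radius: int = 5

    def __post_init__(self) -> None:
        if self.smoothing_kernel_size <= 0 or self.smoothing_kernel_size % 2 == 0:
            raise ValueError(
                f"smoothing_kernel_size must be odd and positive, got "
                f"{self.smoothing_kernel_size}"
            )
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be positive")
        if self.min_component_area <= 0:
            raise ValueError("min_component_area must be positive")
        if self.structuring_radius <= 0:
            raise ValueError("structuring_radius must be positive")


@dataclass(frozen=True)
class CropWindow:
    """Half-open bounding window ``[row_min, row_max) x [col_min, col_max)``."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate crop window {self}")

    def apply(self, array: np.ndarray) -> np.ndarray:
        """Crop a (H, W) or (H, W, C) array to this window."""
        return array[self.row_min : self.row_max, self.col_min : self.col_max]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("empty image")
    return image


def intensity(image: np.ndarray) -> np.ndarray:
    """Luma intensity map (0.299 R + 0.587 G + 0.114 B), rounded to integer."""
    image = _check_rgb(image)
    gray = image.astype(np.float64) @ LUMA_WEIGHTS
    return np.rint(gray).astype(np.uint8)


def smooth(image: np.ndarray, params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Gaussian low-pass filter applied per channel.

    The kernel is truncated to exactly ``smoothing_kernel_size`` taps per
    axis; boundaries are handled by symmetric reflection. Output is uint8.
    """
    image = _check_rgb(image)
    half = (params.smoothing_kernel_size - 1) // 2
    truncate = half / params.smoothing_sigma
    out = np.empty_like(image, dtype=np.float64)
    for c in range(3):
        out[..., c] = ndi.gaussian_filter(
            image[..., c].astype(np.float64),
            sigma=params.smoothing_sigma,
            truncate=truncate,
            mode="reflect",
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def foreground_mask(
    image: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Boolean mask of pixels with intensity strictly above the threshold."""
    return intensity(image) > params.intensity_threshold


def remove_small_components(
    mask: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_component_area`` pixels."""
    mask = np.asarray(mask, dtype=bool)
    # max_size removes components of area <= max_size; areas are integers,
    # so <= min_component_area - 1 is exactly "fewer than min_component_area"
    return morphology.remove_small_objects(
        mask, connectivity=2, max_size=params.min_component_area - 1
    )


def morph_refine(
    mask: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a discrete disk.

    The structuring element is the exact discrete disk
    ``{(x, y): x^2 + y^2 <= r^2}``, which is what
    :func:`skimage.morphology.disk` constructs.
    """
    mask = np.asarray(mask, dtype=bool)
    selem = morphology.disk(params.structuring_radius)
    return morphology.opening(mask, selem).astype(bool)


def crop_window(mask: np.ndarray) -> CropWindow:
    """Tight bounding window of the true pixels of ``mask``.

    Raises
    ------
    ValueError
        If the mask is empty — no saffron found in the frame.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("no saffron found: foreground mask is empty")
    return CropWindow(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def preprocess_image(
    image: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> tuple[np.ndarray, np.ndarray, CropWindow]:
    """Full segmentation stage: smooth, threshold, filter, open, crop.

    Returns
    -------
    cropped : uint8 array
        The smoothed image restricted to the crop window.
    mask : bool array
        Final foreground mask, aligned with ``cropped``.
    window : CropWindow
        Crop window in the original image's coordinates.
    """
    smoothed = smooth(image, params)
    mask = foreground_mask(smoothed, params)
    mask = remove_small_components(mask, params)
    mask = morph_refine(mask, params)
    window = crop_window(mask)
    return window.apply(smoothed), window.apply(mask), window
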