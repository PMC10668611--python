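"""Denoising, contrast enhancement, and approximate edge maps.

The pipeline order is median denoising, then contrast-limited adaptive
histogram equalization, then a polarity-selected axial derivative cleaned
by morphological (area) opening. All operations are deterministic,
shape-preserving, and pass scan metadata through untouched. Intensities
are handled in [0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from .core import BScan, EdgeMap, InvalidParameterError


def denoise_median(scan: BScan, window: int = 5) -> BScan:
    """Median-filter the scan with a square window; borders by reflection."""
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("median window must be odd and >= 1")
    filtered = ndimage.median_filter(scan.pixels, size=window, mode="reflect")
    return scan.replace_pixels(filtered)


def enhance_clahe(
    scan: BScan, clip_limit: float = 0.002, tiles: tuple[int, int] = (4, 4)
) -> BScan:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is the normalized clipping fraction in (0, 1]; ``tiles``
    the (rows, cols) tile grid. Output intensities stay within [0, 1].
    """
    if not 0 < clip_limit <= 1:
        raise InvalidParameterError("clip_limit must be in (0, 1]")
    tr, tc = tiles
    if tr < 1 or tc < 1:
        raise InvalidParameterError("tiles must be >= (1, 1)")
    h, w = scan.pixels.shape
    kh, kw = h // tr, w // tc
    if kh < 1 or kw < 1:
        raise InvalidParameterError("tile grid finer than the image")
    img = np.clip(scan.pixels, 0.0, 1.0)
    if np.ptp(img) == 0:
        return scan.replace_pixels(img)  # constant image: nothing to equalize
    out = exposure.equalize_adapthist(img, kernel_size=(kh, kw), clip_limit=clip_limit)
    return scan.replace_pixels(out)


def build_edge_map(
    scan: BScan,
    polarity: str = "dark_to_bright",
    smoothing_scale: float = 2.0,
    min_component_px: int = 10,
) -> EdgeMap:
    """Polarity-selected axial derivative with small-component cleanup.

    The image is optionally Gaussian-smoothed, differentiated along the
    axial (row) direction by central differences, and rectified so the map
    responds only to the requested transition (``dark_to_bright``: intensity
    increasing with depth; ``bright_to_dark``: decreasing). Connected
    regions of support smaller than ``min_component_px`` are removed by an
    area opening; surviving responses keep their gradient magnitudes.
    """
    if smoothing_scale < 0:
        raise InvalidParameterError("smoothing_scale must be >= 0")
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise InvalidParameterError(f"unknown polarity {polarity!r}")
    img = scan.pixels
    if smoothing_scale > 0:
        img = ndimage.gaussian_filter(img, smoothing_scale, mode="reflect")
    deriv = np.gradient(img, axis=0)
    g = deriv if polarity == "dark_to_bright" else -deriv
    g = np.clip(g, 0.0, None)
    if min_component_px > 1:
        # area opening: drop connected responses smaller than min_component_px
        support = morphology.remove_small_objects(g > 0, max_size=min_component_px - 1)
        g = np.where(support, g, 0.0)
    return EdgeMap(gradient=g, polarity=polarity)
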