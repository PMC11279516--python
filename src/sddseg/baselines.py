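"""Reference segmenters for three-way comparisons.

Two conventional thresholding families serve as comparison points for the
entropy-optimized SDD method: a single global histogram threshold (Otsu's
between-class-variance criterion) and a dynamic (adaptive) threshold where
each pixel is compared against a local Gaussian-weighted mean minus an
offset.  Both are standard interpretations — global histogram thresholding
is pinned to Otsu and dynamic thresholding to the adaptive Gaussian mean.
"""

from __future__ import annotations

import numpy as np
from skimage import filters

from .config import BaselineConfig
from .image_io import GrayImage

__all__ = ["histogram_threshold", "dynamic_threshold"]


def histogram_threshold(img: GrayImage) -> tuple[int, np.ndarray]:
    """Otsu's global threshold on the intensity histogram, dark polarity.

    Returns (threshold level, mask) where the mask marks pixels strictly
    below the threshold.
    """
    px = img.pixels
    if px.min() == px.max():
        raise ValueError("constant image: histogram threshold undefined")
    counts = np.bincount(px.ravel(), minlength=img.levels)
    # threshold_otsu returns the top level of the lower class; shift by one
    # so the dark class is exactly {n < t}
    t = int(filters.threshold_otsu(hist=(counts, np.arange(img.levels)))) + 1
    return t, px < t


def dynamic_threshold(img: GrayImage, cfg: BaselineConfig | None = None) -> np.ndarray:
    """Adaptive threshold: pixel is particle when its intensity is below the
    local Gaussian-weighted mean over a block_size window minus offset."""
    cfg = cfg or BaselineConfig(method="dynamic")
    cfg.validate()
    if cfg.block_size >= min(img.height, img.width):
        raise ValueError(
            f"block_size {cfg.block_size} must be smaller than the image "
            f"extent {img.height}x{img.width}"
        )
    local = filters.threshold_local(
        img.astype_float(), block_size=cfg.block_size, method="gaussian",
        offset=cfg.offset)
    return img.astype_float() < local
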