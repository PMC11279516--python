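"""Noise reduction ahead of segmentation.

TEM micrographs of weakly scattering particles (low dose, cryo conditions,
carbon-based materials) carry substantial shot and detector noise.  A
non-local-means (NLM) filter averages pixels over similar patches anywhere
in a search window, which suppresses that noise while keeping particle
edges — the feature the downstream gradient analysis depends on — sharp.
"""

from __future__ import annotations

import numpy as np
from skimage.restoration import denoise_nl_means, estimate_sigma

from .config import DenoiseConfig
from .image_io import GrayImage

__all__ = ["denoise_nlm", "estimate_noise_sigma"]

#: NLM filtering strength as a multiple of the estimated noise sigma.
_AUTO_H_FACTOR = 0.8


def estimate_noise_sigma(img: GrayImage) -> float:
    """Estimate the Gaussian noise standard deviation in intensity levels
    (wavelet-based median absolute deviation estimator)."""
    return float(estimate_sigma(img.astype_float()))


def denoise_nlm(img: GrayImage, cfg: DenoiseConfig | None = None) -> GrayImage:
    """Apply non-local-means denoising; returns an image of the same shape
    and bit depth on the same integer level set.

    With ``auto_strength`` the filtering parameter h is scaled from the
    estimated noise sigma (h = 0.8 sigma), so noisier inputs are smoothed
    harder; a constant image passes through unchanged.
    """
    cfg = cfg or DenoiseConfig()
    cfg.validate()
    if cfg.patch_size > min(img.height, img.width):
        raise ValueError(
            f"patch_size {cfg.patch_size} exceeds image extent "
            f"{img.height}x{img.width}"
        )
    data = img.astype_float()
    if cfg.auto_strength:
        sigma = float(estimate_sigma(data))
        h = _AUTO_H_FACTOR * sigma
        if h <= 0:  # noise-free input: nothing to average away
            return GrayImage(img.pixels.copy(), img.bitdepth, img.pixel_size)
    else:
        sigma = None
        h = float(cfg.strength)
    out = denoise_nl_means(
        data,
        patch_size=cfg.patch_size,
        patch_distance=cfg.search_window // 2,
        h=h,
        sigma=sigma if sigma else 0.0,
        fast_mode=True,
        preserve_range=True,
    )
    out = np.clip(np.rint(out), 0, img.levels - 1).astype(np.int64)
    return GrayImage(out, bitdepth=img.bitdepth, pixel_size=img.pixel_size)
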