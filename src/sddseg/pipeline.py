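"""End-to-end segmentation runs and method comparison.

The main entry point :func:`run_seosdd` chains the stages: non-local-means
denoising, slope-difference candidate discovery on the histogram,
entropy-maximizing binary search for the threshold, binarization and mask
clean-up, and component labeling with contours.  :func:`run_method`
dispatches between this and the two baseline segmenters so all three can
be compared on one image with identical clean-up settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import dynamic_threshold, histogram_threshold
from .config import PipelineConfig
from .entropy import ThresholdSearchTrace, binary_search_threshold
from .image_io import GrayImage
from .metrics import count_particles, counting_accuracy, relative_error
from .preprocess import denoise_nlm
from .sdd import SDDProfile, sdd_profile_from_image
from .segment import SegmentationResult, component_stats, segment_mask

__all__ = ["PipelineResult", "run_seosdd", "run_method", "compare_methods"]

METHODS = ("seosdd", "histogram", "dynamic")


@dataclass
class PipelineResult:
    """Everything one segmentation run produced."""

    method: str
    threshold: int | None
    segmentation: SegmentationResult
    denoised: GrayImage | None = None
    profile: SDDProfile | None = None
    trace: ThresholdSearchTrace | None = None

    @property
    def count(self) -> int:
        return self.segmentation.n_components

    def trace_frame(self) -> pd.DataFrame:
        """Threshold-search trace as a table (iteration, level, H, H_norm)."""
        if self.trace is None:
            return pd.DataFrame(columns=["iteration", "level", "H_bits", "H_norm"])
        rows = [(i, lvl, h, hn) for (i, lvl, h), hn in
                zip(self.trace.iterations, self.trace.H_normalized)]
        return pd.DataFrame(rows, columns=["iteration", "level", "H_bits", "H_norm"])

    def profile_frame(self) -> pd.DataFrame:
        """Diagnostic curve table (level, P, s, ds) for threshold plots."""
        if self.profile is None:
            return pd.DataFrame(columns=["level", "P", "s", "ds"])
        return pd.DataFrame({
            "level": self.profile.levels,
            "P": self.profile.P,
            "s": self.profile.s,
            "ds": self.profile.ds,
        })


def run_seosdd(img: GrayImage, config: PipelineConfig | None = None) -> PipelineResult:
    """Segment one image with entropy-optimized SDD thresholding."""
    config = config or PipelineConfig()
    config.validate()
    work = denoise_nlm(img, config.denoise) if config.denoise.enabled else img
    profile = sdd_profile_from_image(work, config.sdd)
    trace = binary_search_threshold(work, profile, config.entropy)
    seg_cfg = config.segment
    seg_cfg = seg_cfg.with_profile(seg_cfg.profile)
    result = segment_mask(work, trace.selected, seg_cfg)
    return PipelineResult(method="seosdd", threshold=trace.selected,
                          segmentation=result, denoised=work,
                          profile=profile, trace=trace)


def run_method(img: GrayImage, method: str,
               config: PipelineConfig | None = None) -> PipelineResult:
    """Run one of the three segmenters with shared mask clean-up settings."""
    config = config or PipelineConfig()
    config.validate()
    if method == "seosdd":
        return run_seosdd(img, config)
    work = denoise_nlm(img, config.denoise) if config.denoise.enabled else img
    if method == "histogram":
        t, mask = histogram_threshold(work)
        threshold: int | None = t
    elif method == "dynamic":
        mask = dynamic_threshold(work, config.baseline)
        threshold = None
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    from .segment import label_components, postprocess
    seg_cfg = config.segment.with_profile(config.segment.profile)
    mask = postprocess(mask, min_area=seg_cfg.min_area,
                       fill_holes=seg_cfg.fill_holes,
                       convexity_min=seg_cfg.convexity_min,
                       max_area=seg_cfg.max_area)
    result = label_components(mask)
    return PipelineResult(method=method, threshold=threshold,
                          segmentation=result, denoised=work)


def compare_methods(img: GrayImage, reference_count: int,
                    score_kind: str = "accuracy",
                    config: PipelineConfig | None = None,
                    count_mode: str = "components") -> pd.DataFrame:
    """Run all three methods on one image and tabulate counts and scores.

    ``score_kind='accuracy'`` scores against a ground-truth count;
    ``'relative_error'`` against a manual count.
    """
    config = config or PipelineConfig()
    rows = []
    ref_label = "Ground truth" if score_kind == "accuracy" else "Manual counting"
    ref_score = 100.0 if score_kind == "accuracy" else 0.0
    rows.append({"method": ref_label, "count": reference_count, "score": ref_score})
    names = {"seosdd": "SDD (entropy-optimized)", "histogram": "Histogram threshold",
             "dynamic": "Dynamic threshold"}
    for method in METHODS:
        res = run_method(img, method, config)
        n = count_particles(res.segmentation, mode=count_mode,
                            grid=config.grid if count_mode == "grid" else None)
        if score_kind == "accuracy":
            score = counting_accuracy(n, reference_count)
        elif score_kind == "relative_error":
            score = relative_error(n, reference_count)
        else:
            raise ValueError(f"unknown score_kind {score_kind!r}")
        rows.append({"method": names[method], "count": n, "score": score})
    return pd.DataFrame(rows, columns=["method", "count", "score"])
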