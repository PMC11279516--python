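"""Binarization, mask clean-up, component labeling and contour extraction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, measure, morphology

from .config import SegmentConfig
from .image_io import GrayImage

__all__ = [
    "SegmentationResult",
    "binarize",
    "postprocess",
    "label_components",
    "extract_contours",
    "component_stats",
    "trace_boundary",
    "contour_perimeter",
]


@dataclass
class SegmentationResult:
    """Binary mask with 8-connected component labels and contours."""

    mask: np.ndarray
    labels: np.ndarray
    n_components: int
    areas: dict[int, int] = field(default_factory=dict)
    contours: dict[int, np.ndarray] = field(default_factory=dict)


def binarize(img: GrayImage, t: int, polarity: str = "dark") -> np.ndarray:
    """Threshold the image: dark polarity marks intensity < t as particle,
    bright polarity intensity > t."""
    if not (0 <= t <= img.levels - 1):
        raise ValueError(f"threshold {t} outside [0, {img.levels - 1}]")
    if polarity == "dark":
        return img.pixels < t
    if polarity == "bright":
        return img.pixels > t
    raise ValueError(f"unknown polarity {polarity!r}")


def postprocess(mask: np.ndarray, min_area: int = 9, fill_holes: bool = True,
                convexity_min: float | None = None,
                max_area: int | None = None) -> np.ndarray:
    """Clean a binary mask: optionally fill holes, then drop components by
    minimum area, convexity (solidity = area / convex-hull area) and
    maximum area.  Idempotent.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if min_area > 0 or convexity_min is not None or max_area is not None:
        labels, n = measure.label(mask, connectivity=2, return_num=True)
        if n:
            drop = np.zeros(n + 1, dtype=bool)
            areas = np.bincount(labels.ravel(), minlength=n + 1)
            drop[1:] |= areas[1:] < min_area
            if max_area is not None:
                drop[1:] |= areas[1:] > max_area
            if convexity_min is not None:
                for region in measure.regionprops(labels):
                    if not drop[region.label] and region.solidity < convexity_min:
                        drop[region.label] = True
            if drop.any():
                mask = mask & ~drop[labels]
    return mask


def label_components(mask: np.ndarray) -> SegmentationResult:
    """8-connectivity component labeling with per-component pixel areas."""
    mask = np.asarray(mask).astype(bool)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    areas = {}
    if n:
        counts = np.bincount(labels.ravel())
        areas = {i: int(counts[i]) for i in range(1, n + 1)}
    return SegmentationResult(mask=mask, labels=labels, n_components=n, areas=areas)


# Moore neighborhood scanned clockwise in (row, col) image coordinates,
# starting from the west neighbor; with y pointing up this traces the
# outer boundary counter-clockwise.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {d: k for k, d in enumerate(_MOORE)}


def trace_boundary(component: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary trace of a single connected component.

    Returns the ordered closed chain of boundary pixels as an (n, 2) array
    of (row, col); a single pixel yields a one-pixel chain.  Terminates
    when the initial (pixel, successor) move repeats, so one-pixel-wide
    spurs are traversed in both directions as part of the closed chain.
    """
    comp = np.asarray(component).astype(bool)
    pts = np.argwhere(comp)
    if len(pts) == 0:
        return np.empty((0, 2), dtype=int)
    if len(pts) == 1:
        return pts.astype(int)
    padded = np.pad(comp, 1)  # neighbor lookups never leave the array
    start = tuple(pts[0] + 1)  # topmost then leftmost: west neighbor is background
    cur = start
    prev = (start[0], start[1] - 1)  # background pixel we "came from"
    chain = [start]
    first_move: tuple | None = None
    while True:
        d0 = _MOORE_INDEX[(prev[0] - cur[0], prev[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            d = (d0 + k) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if padded[cand]:
                nxt = cand
                dp = (d0 + k - 1) % 8
                prev = (cur[0] + _MOORE[dp][0], cur[1] + _MOORE[dp][1])
                break
        if nxt is None:  # no foreground neighbor: single pixel, handled above
            break
        if first_move is None:
            first_move = (cur, nxt)
        elif (cur, nxt) == first_move:
            break
        chain.append(nxt)
        cur = nxt
    if len(chain) > 1 and chain[-1] == chain[0]:
        chain = chain[:-1]
    return np.array(chain, dtype=int) - 1  # undo padding offset


def contour_perimeter(chain: np.ndarray) -> float:
    """Perimeter of a closed pixel chain: unit steps for 4-neighbors,
    sqrt(2) for diagonal steps."""
    chain = np.asarray(chain)
    if len(chain) < 2:
        return 0.0
    diffs = np.diff(np.vstack([chain, chain[:1]]), axis=0)
    return float(np.sqrt((diffs ** 2).sum(axis=1)).sum())


def extract_contours(result: SegmentationResult, method: str = "boundary",
                     intensity: GrayImage | None = None) -> dict[int, np.ndarray]:
    """Extract per-component contours.

    ``boundary`` traces each component's outer boundary (ordered,
    counter-clockwise, 8-connected, deterministic).  ``canny`` runs a Canny
    edge detector on the mask (or on the masked intensity image when one is
    given) and assigns edge pixels to the nearest component; the Canny
    hysteresis thresholds derive from Otsu on the gradient magnitude.
    """
    contours: dict[int, np.ndarray] = {}
    if method == "boundary":
        slices = ndimage.find_objects(result.labels)
        for cid in range(1, result.n_components + 1):
            sl = slices[cid - 1]
            comp = result.labels[sl] == cid
            chain = trace_boundary(comp)
            chain[:, 0] += sl[0].start
            chain[:, 1] += sl[1].start
            contours[cid] = chain
    elif method == "canny":
        if intensity is not None:
            data = intensity.astype_float() * result.mask
        else:
            data = result.mask.astype(float)
        edges = feature.canny(data)
        # assign each edge pixel to the closest labeled component
        _, (ir, ic) = ndimage.distance_transform_edt(
            result.labels == 0, return_indices=True)
        owner = result.labels[ir, ic]
        for cid in range(1, result.n_components + 1):
            pts = np.argwhere(edges & (owner == cid))
            contours[cid] = pts
    else:
        raise ValueError(f"unknown contour method {method!r}")
    result.contours = contours
    return contours


def component_stats(result: SegmentationResult) -> pd.DataFrame:
    """Per-component table: id, area, centroid, equivalent diameter."""
    rows = []
    for region in measure.regionprops(result.labels):
        rows.append({
            "component_id": region.label,
            "area_px": int(region.area),
            "centroid_row": region.centroid[0],
            "centroid_col": region.centroid[1],
            "equiv_diameter_px": region.equivalent_diameter_area,
        })
    return pd.DataFrame(rows, columns=["component_id", "area_px", "centroid_row",
                                       "centroid_col", "equiv_diameter_px"])


def segment_mask(img: GrayImage, t: int, cfg: SegmentConfig | None = None) -> SegmentationResult:
    """Binarize at t and run the configured clean-up and labeling."""
    cfg = cfg or SegmentConfig()
    cfg.validate()
    mask = binarize(img, t, cfg.polarity)
    mask = postprocess(mask, min_area=cfg.min_area, fill_holes=cfg.fill_holes,
                       convexity_min=cfg.convexity_min, max_area=cfg.max_area)
    result = label_components(mask)
    extract_contours(result, cfg.contour_method,
                     intensity=img if cfg.contour_method == "canny" else None)
    return result
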