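"""Counting-based evaluation: accuracy against ground truth, relative error
against manual counts, and grid-cell counting for dense aggregates.

All scores are count-based (not pixel overlap): against a simulated ground
truth the accuracy is

    accuracy = 100% * (1 - |count_method - count_truth| / count_truth)

and against an expert manual count the relative error is

    RE = |count_method - count_manual| / count_manual * 100%.

For aggregated particles whose individual outlines merge, counting uses a
grid of cells close to one particle diameter in size; a cell counts as one
particle when its foreground coverage exceeds half the cell area.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .config import GridConfig
from .segment import SegmentationResult

__all__ = [
    "CountReport",
    "counting_accuracy",
    "relative_error",
    "grid_count",
    "grid_count_sweep",
    "count_particles",
    "round2",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (report convention for percentages)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class CountReport:
    """One row of a method-comparison table."""

    method_name: str
    count: int
    reference_count: int
    score: float
    score_kind: str  # "accuracy" | "relative_error"


def counting_accuracy(count_method: int, count_truth: int) -> float:
    """Percent counting accuracy against a known ground-truth count,
    rounded half-up to 2 decimals."""
    if count_truth <= 0:
        raise ValueError("ground-truth count must be > 0")
    acc = 100.0 * (1.0 - abs(count_method - count_truth) / count_truth)
    return round2(acc)


def relative_error(count_seg: int, count_manual: int) -> float:
    """Percent relative error of a segmentation count against a manual
    reference count, rounded half-up to 2 decimals."""
    if count_manual <= 0:
        raise ValueError("manual count must be > 0")
    re = 100.0 * abs(count_seg - count_manual) / count_manual
    return round2(re)


def grid_count(mask: np.ndarray, grid: GridConfig | None = None) -> int:
    """Count grid cells whose foreground coverage exceeds ``coverage_frac``.

    The image is tiled into cell_size x cell_size cells starting at
    ``origin`` (shifted toward negative so the whole image is covered);
    partial border cells participate with their actual pixel area.  The
    coverage comparison is strictly greater than.
    """
    grid = grid or GridConfig()
    grid.validate()
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if grid.cell_size > min(h, w):
        raise ValueError("cell_size exceeds image extent")
    cs = grid.cell_size
    r0 = grid.origin[0] % cs
    c0 = grid.origin[1] % cs
    row_edges = [0] + list(range(r0 if r0 else cs, h, cs)) + [h]
    col_edges = [0] + list(range(c0 if c0 else cs, w, cs)) + [w]
    row_edges = sorted(set(row_edges))
    col_edges = sorted(set(col_edges))
    count = 0
    for ra, rb in zip(row_edges[:-1], row_edges[1:]):
        for ca, cb in zip(col_edges[:-1], col_edges[1:]):
            tile = mask[ra:rb, ca:cb]
            if tile.sum() > grid.coverage_frac * tile.size:
                count += 1
    return count


def grid_count_sweep(mask: np.ndarray, grid: GridConfig | None = None,
                     offsets: int = 3) -> tuple[int, float, int]:
    """(min, median, max) grid counts over an offsets x offsets sweep of the
    grid origin; the count depends on alignment, so the sweep bounds that
    sensitivity."""
    grid = grid or GridConfig()
    step = max(1, grid.cell_size // offsets)
    counts = []
    for dr in range(0, grid.cell_size, step):
        for dc in range(0, grid.cell_size, step):
            g = GridConfig(cell_size=grid.cell_size, origin=(dr, dc),
                           coverage_frac=grid.coverage_frac)
            counts.append(grid_count(mask, g))
    return min(counts), float(np.median(counts)), max(counts)


def count_particles(result: SegmentationResult, mode: str = "components",
                    grid: GridConfig | None = None) -> int:
    """Particle count of a segmentation: connected components for isolated
    particles, grid cells for dense aggregates."""
    if mode == "components":
        return result.n_components
    if mode == "grid":
        if grid is None:
            raise ValueError("grid mode requires a GridConfig")
        return grid_count(result.mask, grid)
    raise ValueError(f"unknown counting mode {mode!r}")
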