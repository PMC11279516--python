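"""Reading, writing and validating grayscale micrographs.

Everything downstream works on :class:`GrayImage`: an integer raster on the
level set ``{0 .. 2**bitdepth - 1}``.  Histogram arithmetic is done on these
integer levels (never rescaled floats) so that bin identity is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "GrayImage",
    "read_image",
    "write_image",
    "write_contours_csv",
    "write_stats_csv",
    "write_counts_csv",
]

#: Rec. 601 luma weights for RGB collapse.
_LUMA = np.array([0.299, 0.587, 0.114])

_MIN_SIDE = 8


@dataclass
class GrayImage:
    """2-D grayscale intensity raster.

    Parameters
    ----------
    pixels
        Integer array of shape (height, width) with values in ``[0, L-1]``
        where ``L = 2**bitdepth``.
    bitdepth
        8 or 16.
    pixel_size
        Optional physical length per pixel (nm/px); carried as metadata.
    """

    pixels: np.ndarray
    bitdepth: int = 8
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {px.shape}")
        if self.bitdepth not in (8, 16):
            raise ValueError(f"bitdepth must be 8 or 16, got {self.bitdepth}")
        h, w = px.shape
        if h < _MIN_SIDE or w < _MIN_SIDE:
            raise ValueError(
                f"image too small ({h}x{w}); at least {_MIN_SIDE}x{_MIN_SIDE} required"
            )
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixels must be integer levels, got dtype {px.dtype}")
        if px.min() < 0 or px.max() > self.levels - 1:
            raise ValueError(
                f"pixel values outside [0, {self.levels - 1}] for bitdepth {self.bitdepth}"
            )
        dtype = np.uint8 if self.bitdepth == 8 else np.uint16
        self.pixels = px.astype(dtype, copy=False)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def levels(self) -> int:
        """Number of intensity levels L = 2**bitdepth."""
        return 1 << self.bitdepth

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def invert(self) -> "GrayImage":
        """Return the intensity-inverted image (level n -> L-1-n)."""
        return GrayImage(self.levels - 1 - self.pixels.astype(np.int64),
                         bitdepth=self.bitdepth, pixel_size=self.pixel_size)


def _to_luma(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3|4) array to luminance with Rec. 601 weights."""
    rgb = arr[..., :3].astype(np.float64)
    return np.rint(rgb @ _LUMA)


def read_image(path: str | Path) -> GrayImage:
    """Read a single-channel or RGB TIFF/PNG into a :class:`GrayImage`.

    RGB input is collapsed to luminance (Rec. 601, rounded to nearest
    integer level); 16-bit data is preserved at 16-bit depth.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            n_pages = len(tf.pages)
            if n_pages != 1:
                raise IOError(
                    f"multi-page TIFF not supported: {path} has {n_pages} pages"
                )
            arr = tf.asarray()
    else:
        try:
            with Image.open(path) as im:
                if getattr(im, "n_frames", 1) != 1:
                    raise IOError(
                        f"multi-frame image not supported: {path} has {im.n_frames} frames"
                    )
                arr = np.asarray(im)
        except (OSError, SyntaxError) as exc:
            raise IOError(f"unreadable image file {path}: {exc}") from exc

    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise IOError(f"unsupported channel count {arr.shape[2]} in {path}")
        bitdepth = 16 if arr.dtype.itemsize > 1 else 8
        arr = _to_luma(arr)
    elif arr.ndim == 2:
        if arr.dtype == np.bool_:
            arr = arr.astype(np.uint8) * 255
        bitdepth = 16 if np.asarray(arr).dtype.itemsize > 1 else 8
    else:
        raise IOError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    return GrayImage(np.asarray(arr).astype(np.int64), bitdepth=bitdepth)


def write_image(img: GrayImage | np.ndarray, path: str | Path) -> None:
    """Write an image or a binary mask losslessly.

    Binary (boolean or {0,1}) masks are written as 8-bit {0, 255}.  PNG is
    used for 8-bit output and either PNG or TIFF for 16-bit, chosen by the
    file extension.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")

    if isinstance(img, GrayImage):
        arr = img.pixels
        bitdepth = img.bitdepth
    else:
        arr = np.asarray(img)
        if arr.dtype == np.bool_ or (arr.ndim == 2 and arr.size and set(np.unique(arr)) <= {0, 1}):
            arr = (arr.astype(np.uint8)) * 255
            bitdepth = 8
        else:
            bitdepth = 16 if arr.dtype.itemsize > 1 else 8

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.uint16 if bitdepth == 16 else np.uint8))
    else:
        if bitdepth == 16:
            Image.fromarray(arr.astype(np.uint16)).save(path, format="PNG")
        else:
            Image.fromarray(arr.astype(np.uint8), mode="L").save(path, format="PNG")


def write_contours_csv(contours: dict[int, np.ndarray], path: str | Path) -> None:
    """Write contours as CSV rows (component_id, x, y), x = column, y = row."""
    rows = []
    for cid in sorted(contours):
        chain = np.asarray(contours[cid])
        for r, c in chain:
            rows.append((cid, int(c), int(r)))
    pd.DataFrame(rows, columns=["component_id", "x", "y"]).to_csv(path, index=False)


def write_stats_csv(stats: pd.DataFrame, path: str | Path) -> None:
    """Write the per-component statistics table with a header row."""
    stats.to_csv(path, index=False)


def write_counts_csv(report: pd.DataFrame, path: str | Path) -> None:
    """Write a (method, count, score) comparison table."""
    report.to_csv(path, index=False)
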