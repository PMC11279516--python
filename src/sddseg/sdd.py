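"""Slope-difference-distribution (SDD) threshold discovery.

The SDD treats an intensity (or gradient-magnitude) histogram as a mixture
of "intensity clusters" and locates their centers without fitting a
parametric mixture.  At every histogram position n, straight lines are
least-squares fitted to the W points on the left and on the right of n; the
difference of the two slopes,

    s(n) = a_L(n) - a_R(n),

peaks where the histogram bends downward (a mode or the shoulder of a
plateau) and dips where it bends upward (a valley).  Zero crossings of
ds/dn from + to - with s > 0 are therefore the cluster centers, which serve
as the candidate thresholds handed to the entropy-maximizing search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, sobel

from .config import SDDConfig
from .image_io import GrayImage

__all__ = [
    "GradientImage",
    "GradientHistogram",
    "SDDProfile",
    "gradient_image",
    "gradient_histogram",
    "intensity_histogram",
    "slope_difference",
    "find_candidates",
    "select_range",
    "sdd_profile_from_image",
]


@dataclass
class GradientImage:
    """Gradient magnitude and direction of a grayscale image."""

    magnitude: np.ndarray  # >= 0, intensity levels per pixel
    direction: np.ndarray  # radians in (-pi, pi]
    gx: np.ndarray  # column-direction derivative
    gy: np.ndarray  # row-direction derivative


@dataclass
class GradientHistogram:
    """Max-normalized histogram: P(n) = f_n / f_max.

    ``levels`` holds the value represented by each bin (integer intensity
    levels when binning an 8-bit intensity image one level per bin; bin
    centers otherwise).
    """

    levels: np.ndarray
    freq: np.ndarray
    P: np.ndarray
    f_max: float


@dataclass
class SDDProfile:
    """Slope-difference curve with its derivative and candidate thresholds."""

    levels: np.ndarray
    P: np.ndarray
    s: np.ndarray
    ds: np.ndarray
    fit_window: int
    candidates: list[int] = field(default_factory=list)
    range_A: int | None = None
    range_B: int | None = None


def gradient_image(img: GrayImage) -> GradientImage:
    """Sobel gradient magnitude and direction with edge replication.

    The 3x3 Sobel stencils are normalized by 1/8 so that on a linear ramp
    the response equals the per-pixel intensity slope.
    """
    data = img.astype_float()
    gy = sobel(data, axis=0, mode="nearest") / 8.0
    gx = sobel(data, axis=1, mode="nearest") / 8.0
    magnitude = np.hypot(gx, gy)
    direction = np.arctan2(gy, gx)
    return GradientImage(magnitude=magnitude, direction=direction, gx=gx, gy=gy)


def gradient_histogram(grad: GradientImage, n_bins: int = 256) -> GradientHistogram:
    """Histogram the gradient magnitudes into ``n_bins`` uniform bins over
    [0, max magnitude] and max-normalize."""
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    mags = np.asarray(grad.magnitude).ravel()
    top = float(mags.max())
    if top == 0:
        raise ValueError("degenerate gradient histogram: image has no gradient")
    freq, edges = np.histogram(mags, bins=n_bins, range=(0.0, top))
    centers = 0.5 * (edges[:-1] + edges[1:])
    f_max = float(freq.max())
    return GradientHistogram(levels=centers, freq=freq.astype(np.int64),
                             P=freq / f_max, f_max=f_max)


def intensity_histogram(img: GrayImage, n_bins: int = 256) -> GradientHistogram:
    """Max-normalized histogram of the intensity image itself.

    For an 8-bit image with 256 bins each bin is one integer level, so
    candidate positions are intensity levels directly; otherwise levels are
    rounded bin centers over [0, L-1].
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    px = img.pixels.ravel()
    if img.levels == n_bins:
        freq = np.bincount(px, minlength=n_bins)
        levels = np.arange(n_bins, dtype=np.float64)
    else:
        freq, edges = np.histogram(px, bins=n_bins, range=(0, img.levels - 1))
        levels = np.rint(0.5 * (edges[:-1] + edges[1:]))
    f_max = float(freq.max())
    if f_max == 0:
        raise ValueError("empty histogram")
    return GradientHistogram(levels=levels, freq=freq.astype(np.int64),
                             P=freq / f_max, f_max=f_max)


def _window_slopes(P: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line slopes over the left window {n-w..n} and the right
    window {n..n+w} of every position n (NaN where the window leaves the
    profile)."""
    n = len(P)
    x = np.arange(w + 1, dtype=np.float64)
    xc = x - x.mean()
    denom = float((xc ** 2).sum())
    # slope over points P[i..i+w] for every start i, via correlation
    seg = np.correlate(P, xc, mode="valid") / denom  # length n - w
    a_left = np.full(n, np.nan)
    a_right = np.full(n, np.nan)
    a_left[w:] = seg          # left window of n starts at n - w
    a_right[: n - w] = seg    # right window of n starts at n
    return a_left, a_right


def slope_difference(hist: GradientHistogram, fit_window: int = 5,
                     smooth_sigma: float = 2.0) -> SDDProfile:
    """Compute the slope-difference curve s(n) = a_L(n) - a_R(n) and its
    derivative.

    The profile P is smoothed with a Gaussian of ``smooth_sigma`` bins
    before fitting (sigma = 0 disables smoothing); raw counts produce
    spurious zero crossings of ds.  The first and last ``fit_window`` bins
    have no complete window and are left NaN.
    """
    if fit_window < 2:
        raise ValueError("fit_window must be >= 2")
    n = len(hist.P)
    if n < 2 * fit_window + 1:
        raise ValueError(
            f"histogram has {n} bins; need at least {2 * fit_window + 1} "
            f"for fit_window={fit_window}"
        )
    P = hist.P.astype(np.float64)
    if smooth_sigma > 0:
        P = gaussian_filter1d(P, smooth_sigma, mode="nearest")
        top = P.max()
        if top > 0:
            P = P / top
    a_left, a_right = _window_slopes(P, fit_window)
    s = a_left - a_right
    ds = np.full(n, np.nan)
    valid = ~np.isnan(s)
    idx = np.where(valid)[0]
    if len(idx) >= 3:
        lo, hi = idx[0], idx[-1]
        ds[lo + 1:hi] = 0.5 * (s[lo + 2:hi + 1] - s[lo:hi - 1])
    return SDDProfile(levels=hist.levels, P=P, s=s, ds=ds, fit_window=fit_window)


def find_candidates(profile: SDDProfile) -> SDDProfile:
    """Populate ``profile.candidates`` with the cluster centers: levels where
    ds crosses zero from + to - and s > 0.

    The sub-bin crossing position is refined by linear interpolation of ds
    between the bracketing samples and reported as the nearest integer
    level; when two adjacent bins both qualify the lower level wins.
    """
    s, ds, levels = profile.s, profile.ds, profile.levels
    cands: list[int] = []
    valid = np.where(~np.isnan(ds))[0]
    if len(valid) == 0:
        raise ValueError("no cluster centers; image may be structureless")
    # relative floor so float-noise wiggle around exact zero is not a crossing
    tol = 1e-9 * max(np.nanmax(np.abs(ds)), 1e-300)
    tol_s = 1e-9 * max(np.nanmax(np.abs(s)), 1e-300)
    for i in range(valid[0], valid[-1]):
        d0, d1 = ds[i], ds[i + 1]
        if np.isnan(d0) or np.isnan(d1):
            continue
        if d0 > tol and d1 <= tol:
            frac = d0 / (d0 - d1) if d0 != d1 else 0.0
            pos = levels[i] + frac * (levels[i + 1] - levels[i])
            # s at the refined position (linear interpolation)
            s_here = s[i] + frac * (s[i + 1] - s[i])
            if s_here > tol_s:
                level = int(np.rint(pos))
                if not cands or cands[-1] != level:
                    cands.append(level)
    if not cands:
        raise ValueError("no cluster centers; image may be structureless")
    profile.candidates = sorted(set(cands))
    return profile


def select_range(profile: SDDProfile, mode: str = "auto",
                 A: int | None = None, B: int | None = None) -> SDDProfile:
    """Set the threshold search range [A, B] and drop candidates outside it.

    Auto mode takes the full candidate span: B (largest candidate)
    separates background from particles, A (smallest) separates particles
    of different intensities.
    """
    if not profile.candidates:
        raise ValueError("no candidates to select a range from")
    if mode == "auto":
        A = min(profile.candidates)
        B = max(profile.candidates)
    elif mode == "manual":
        if A is None or B is None:
            raise ValueError("manual range mode requires both A and B")
    else:
        raise ValueError(f"unknown range mode {mode!r}")
    if A > B:
        raise ValueError(f"range lower limit A={A} exceeds upper limit B={B}")
    kept = [c for c in profile.candidates if A <= c <= B]
    if not kept:
        raise ValueError(f"no candidates inside range [{A}, {B}]")
    profile.candidates = kept
    profile.range_A = int(A)
    profile.range_B = int(B)
    return profile


def sdd_profile_from_image(img: GrayImage, cfg: SDDConfig | None = None) -> SDDProfile:
    """Full candidate discovery for one image under the given settings.

    In the (default) intensity domain, candidates are intensity levels of
    the image histogram.  In the gradient domain, candidates are found on
    the gradient-magnitude histogram and mapped to intensity levels by
    their fractional position in the histogram.
    """
    cfg = cfg or SDDConfig()
    cfg.validate()
    if cfg.domain == "intensity":
        hist = intensity_histogram(img, cfg.n_bins)
    else:
        hist = gradient_histogram(gradient_image(img), cfg.n_bins)
    profile = slope_difference(hist, cfg.fit_window, cfg.smooth_sigma)
    profile = find_candidates(profile)
    if cfg.domain == "gradient":
        # map gradient-histogram bin position -> intensity level
        top = float(hist.levels[-1])
        scale = (img.levels - 1) / top if top > 0 else 0.0
        profile.candidates = sorted({int(np.rint(c * scale))
                                     for c in profile.candidates})
    profile = select_range(profile, cfg.range_mode, cfg.range_A, cfg.range_B)
    return profile
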