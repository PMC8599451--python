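"""Shared raster primitives for the imaging stages.

All color gating uses the 8-bit HSB convention (hue, saturation and
brightness each on an integer 0-255 scale, as popularized by ImageJ's
color thresholder): every gate in the downstream morphometry recipes is
expressed on that scale. Conversion to/from fractional HSV is internal.

Automatic histogram thresholds (isodata/"default", Yen, triangle,
moments) are implemented directly on the 256-bin histogram so that each
method realizes its published criterion exactly; the test suite checks
them against exhaustive 256-candidate searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import morphology as skmorph
from skimage.restoration import rolling_ball as _rolling_ball

__all__ = [
    "SectionImage",
    "HSBRange",
    "BinaryMask",
    "rgb_to_hsb255",
    "hsb255_to_rgb",
    "hsb_threshold",
    "rolling_ball_subtract",
    "auto_threshold",
    "median_filter",
    "gaussian_blur",
    "unsharp_mask",
    "despeckle",
    "skeleton_stats",
    "analyze_particles",
]

ThresholdMethod = Literal["default_isodata", "yen", "triangle", "moments"]


@dataclass
class SectionImage:
    """An 8-bit raster (RGB ``HxWx3`` or single channel ``HxW``) with a
    physical pixel size in micrometres per pixel."""

    pixels: np.ndarray
    pixel_size: float  # µm / px
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be HxW or HxWxC")

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3 and self.pixels.shape[2] == 3

    def channel(self, index: int) -> np.ndarray:
        if not self.is_rgb:
            raise ValueError("channel() requires an RGB image")
        return self.pixels[..., index]


@dataclass(frozen=True)
class HSBRange:
    """Inclusive hue/saturation/brightness gate on the 0-255 scale.

    If ``hue_min > hue_max`` the hue interval wraps around 255->0
    (circular hue); no gate used by the morphometry recipes needs this,
    but synthetic reds near the hue origin may.
    """

    hue_min: int = 0
    hue_max: int = 255
    sat_min: int = 0
    sat_max: int = 255
    bright_min: int = 0
    bright_max: int = 255

    def __post_init__(self) -> None:
        for name in ("hue_min", "hue_max", "sat_min", "sat_max", "bright_min", "bright_max"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.sat_min > self.sat_max or self.bright_min > self.bright_max:
            raise ValueError("saturation/brightness min must be <= max")


@dataclass
class BinaryMask:
    """Boolean raster with physical pixel size and an operation log."""

    data: np.ndarray
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def area_px(self) -> int:
        return int(self.data.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2


# ---------------------------------------------------------------------------
# HSB conversion and gating


def rgb_to_hsb255(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to integer HSB on the 0-255 scale."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected HxWx3 RGB input")
    hsv = skcolor.rgb2hsv(rgb.astype(np.float64) / 255.0)
    return np.clip(np.round(hsv * 255.0), 0, 255).astype(np.uint8)


def hsb255_to_rgb(hsb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsb255` (up to 8-bit quantization)."""
    hsv = np.asarray(hsb, dtype=np.float64) / 255.0
    rgb = skcolor.hsv2rgb(hsv)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def hsb_threshold(image: SectionImage, gate: HSBRange) -> BinaryMask:
    """Select pixels whose HSB triple lies inclusively within ``gate``.

    Widening any bound of the gate can only add pixels (monotonicity).
    """
    if not image.is_rgb:
        raise ValueError("hsb_threshold requires an RGB SectionImage")
    hsb = rgb_to_hsb255(image.pixels)
    h, s, b = hsb[..., 0].astype(int), hsb[..., 1].astype(int), hsb[..., 2].astype(int)
    if gate.hue_min <= gate.hue_max:
        hue_ok = (h >= gate.hue_min) & (h <= gate.hue_max)
    else:  # circular wraparound
        hue_ok = (h >= gate.hue_min) | (h <= gate.hue_max)
    mask = (
        hue_ok
        & (s >= gate.sat_min)
        & (s <= gate.sat_max)
        & (b >= gate.bright_min)
        & (b <= gate.bright_max)
    )
    return BinaryMask(mask, image.pixel_size, {"op": "hsb_threshold", "gate": gate})


# ---------------------------------------------------------------------------
# Filters


def rolling_ball_subtract(image: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background subtraction (background removed, clipped at 0).

    ``radius`` is the ball radius in pixels. Features smaller than the ball
    are preserved; smooth backgrounds (including constants) are flattened
    to ~0.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("rolling_ball_subtract expects a single channel")
    background = _rolling_ball(img, radius=radius)
    return np.clip(img - background, 0, None)


def median_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """Median filter with a disk footprint of the given pixel radius."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    img = np.asarray(image)
    footprint = skmorph.disk(radius)
    return ndi.median_filter(img, footprint=footprint, mode="nearest")


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur preserving range and mean intensity."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return ndi.gaussian_filter(np.asarray(image, dtype=np.float64), sigma=sigma, mode="nearest")


def unsharp_mask(image: np.ndarray, radius: float, weight: float) -> np.ndarray:
    """Unsharp mask: ``(image - weight * blur(image, radius)) / (1 - weight)``.

    Output is float and *not* clipped, so the closed-form composition holds
    exactly; 8-bit pipelines clip afterwards.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not (0 <= weight < 1):
        raise ValueError("weight must lie in [0, 1)")
    img = np.asarray(image, dtype=np.float64)
    return (img - weight * gaussian_blur(img, radius)) / (1.0 - weight)


def despeckle(mask_or_image: np.ndarray) -> np.ndarray:
    """ImageJ-style despeckle: a radius-1 median filter (removes isolated
    single-pixel noise; works on binary or grayscale rasters)."""
    data = np.asarray(mask_or_image)
    if data.dtype == bool:
        return median_filter(data.astype(np.uint8), 1).astype(bool)
    return median_filter(data, 1)


# ---------------------------------------------------------------------------
# Automatic histogram thresholds


def _histogram256(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    data = np.clip(np.round(img.astype(np.float64)), 0, 255).astype(np.uint8)
    return np.bincount(data.ravel(), minlength=256).astype(np.float64)


def _isodata_threshold(hist: np.ndarray) -> int:
    # iterative intermeans: t <- round((mean_below + mean_above) / 2)
    levels = np.arange(256, dtype=np.float64)
    t = int(round((levels * hist).sum() / hist.sum()))
    for _ in range(256):
        below = hist[: t + 1]
        above = hist[t + 1 :]
        if below.sum() == 0:
            mean_b = 0.0
        else:
            mean_b = (levels[: t + 1] * below).sum() / below.sum()
        if above.sum() == 0:
            mean_a = 255.0
        else:
            mean_a = (levels[t + 1 :] * above).sum() / above.sum()
        t_new = int(round((mean_b + mean_a) / 2.0))
        if t_new == t:
            break
        t = t_new
    return t

def _yen_threshold(hist: np.ndarray) -> int:
    # Yen's maximum correlation criterion, maximized over all 256 candidates
    counts = np.cumsum(hist)
    total = counts[-1]
    p = hist / total
    p1 = np.cumsum(p)
    p1sq = np.cumsum(p * p)
    p2sq = p1sq[-1] - p1sq
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(np.maximum(p1sq * p2sq, 1e-300)) + 2.0 * np.log(
            np.maximum(p1 * (1.0 - p1), 1e-300)
        )
    # both classes must be non-empty (exact integer check, not float p1)
    valid = (counts > 0) & (counts < total)
    if not valid.any():
        raise ValueError("degenerate histogram: single gray level")
    crit[~valid] = -np.inf
    return int(np.argmax(crit))


def _triangle_threshold(hist: np.ndarray) -> int:
    # geometric triangle method on the longer tail of the histogram peak
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    peak = int(np.argmax(hist))
    # work on the longer side of the peak; mirror if the tail is on the left
    flipped = (peak - first) > (last - peak)
    h = hist[::-1].copy() if flipped else hist.copy()
    if flipped:
        peak = 255 - peak
        tail_end = 255 - first
    else:
        tail_end = last
    # line from (peak, h[peak]) to (tail_end, 0); maximize vertical offset
    if tail_end == peak:
        raise ValueError("degenerate histogram: single gray level")
    xs = np.arange(peak, tail_end + 1, dtype=np.float64)
    line = h[peak] * (1.0 - (xs - peak) / (tail_end - peak))
    dist = line - h[peak : tail_end + 1]
    t = peak + int(np.argmax(dist))
    return 255 - t if flipped else t


def _moments_threshold(hist: np.ndarray) -> int:
    # Tsai's moment-preserving threshold: match the first three gray-level
    # moments with a two-level image, then split at the p0-tile.
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    m1 = (levels * p).sum()
    m2 = (levels**2 * p).sum()
    m3 = (levels**3 * p).sum()
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram: single gray level")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    disc = max(disc, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    # threshold at the gray level whose cumulative fraction is closest to p0
    cum = np.cumsum(p)
    return int(np.argmin(np.abs(cum - p0)))


_THRESHOLD_FUNCS = {
    "default_isodata": _isodata_threshold,
    "yen": _yen_threshold,
    "triangle": _triangle_threshold,
    "moments": _moments_threshold,
}


def auto_threshold(
    image: np.ndarray,
    method: ThresholdMethod,
    pixel_size: float = 1.0,
    bright_foreground: bool = True,
) -> tuple[BinaryMask, int]:
    """Threshold a single-channel image by a named histogram criterion.

    Returns ``(mask, threshold)`` where foreground pixels satisfy
    ``value > threshold`` (or ``<=`` when ``bright_foreground=False``).
    Raises on a constant (degenerate) histogram.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("auto_threshold expects a single channel")
    if method not in _THRESHOLD_FUNCS:
        raise ValueError(f"unknown threshold method {method!r}")
    hist = _histogram256(img)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: constant image")
    t = _THRESHOLD_FUNCS[method](hist)
    quantized = np.clip(np.round(img.astype(np.float64)), 0, 255)
    mask = quantized > t if bright_foreground else quantized <= t
    return (
        BinaryMask(mask, pixel_size, {"op": "auto_threshold", "method": method, "threshold": t}),
        t,
    )


# ---------------------------------------------------------------------------
# Skeleton topology


def skeleton_stats(mask: BinaryMask) -> tuple[BinaryMask, int, int]:
    """Skeletonize a binary mask and count 2-D branches and junctions.

    A junction is a skeleton pixel with >= 3 skeleton neighbors under
    8-connectivity; adjacent junction pixels are merged into a single
    junction. A branch is a maximal skeleton path free of junctions, i.e.
    a connected component of the skeleton after junction pixels are
    removed.
    """
    if mask.data.sum() == 0:
        return BinaryMask(np.zeros_like(mask.data), mask.pixel_size), 0, 0
    skel = skmorph.skeletonize(mask.data)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    neighbor_count = ndi.convolve(skel.astype(int), kernel, mode="constant")
    junction_px = skel & (neighbor_count >= 3)
    _, n_junctions = ndi.label(junction_px, structure=np.ones((3, 3)))
    branch_px = skel & ~junction_px
    _, n_branches = ndi.label(branch_px, structure=np.ones((3, 3)))
    return (
        BinaryMask(skel, mask.pixel_size, {"op": "skeletonize"}),
        int(n_branches),
        int(n_junctions),
    )


# ---------------------------------------------------------------------------
# Particle analysis (ImageJ "Analyze Particles" semantics)


def analyze_particles(
    mask: BinaryMask,
    exclude_edges: bool = True,
    include_holes: bool = True,
    min_area_px: int = 1,
) -> tuple[np.ndarray, int]:
    """Label connected components with ImageJ particle-analysis options.

    ``exclude_edges`` drops components touching any image border;
    ``include_holes`` fills internal holes of each retained component.
    Returns ``(label_image, n_particles)`` with labels 1..n.
    """
    labels, _ = ndi.label(mask.data, structure=np.ones((3, 3)))
    if exclude_edges:
        border = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        for lbl in border:
            if lbl != 0:
                labels[labels == lbl] = 0
    out = np.zeros_like(labels)
    next_id = 0
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        comp = labels == lbl
        if comp.sum() < min_area_px:
            continue
        if include_holes:
            comp = ndi.binary_fill_holes(comp)
        next_id += 1
        out[comp] = next_id
    return out, next_id
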