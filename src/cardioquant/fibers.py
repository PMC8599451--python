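"""Collagen/ECM fiber organization metrics.

Four complementary descriptors of scar architecture:

* **Waviness** ``W`` of a traced fiber: arc length of the polyline
  divided by the straight-line distance between its endpoints; ``W = 1``
  for a straight fiber, larger for crimped ones.
* **Anisotropy** of a fiber field: per-pixel intensity gradients inside a
  region of interest are accumulated into a 2x2 structure (nematic)
  tensor; the score is ``(l1 - l2) / (l1 + l2)`` of its eigenvalues (0 =
  isotropic, 1 = perfectly aligned), and the reported orientation is the
  dominant fiber axis (perpendicular to the dominant gradient) in
  degrees [0, 180).
* **Box-counting fractal dimension** ``D``: slope of ``log N(eps)``
  against ``log (1/eps)`` over a series of grid sizes, averaged over
  translated ("slipping") grid origins.
* **Lacunarity** ``Lambda``: per grid size, ``(sigma/mu)^2 + 1`` of the
  per-box foreground mass over occupied boxes, averaged over sizes and
  grid origins; measures gappiness at equal density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import scharr_h, scharr_v

from .imageops import (
    BinaryMask,
    auto_threshold,
    despeckle,
    median_filter,
    rolling_ball_subtract,
    unsharp_mask,
)

__all__ = [
    "FiberTrace",
    "waviness",
    "waviness_batch",
    "anisotropy",
    "fractal_lacunarity",
    "default_box_sizes",
    "preprocess_for_fractal",
]


@dataclass
class FiberTrace:
    """Ordered polyline vertices of one traced fiber (x, y in px or µm)."""

    vertices: np.ndarray  # (n, 2)
    fiber_id: int = 0
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 2:
            raise ValueError("a fiber trace needs at least 2 vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")


def waviness(trace: FiberTrace) -> float:
    """W = curved length / linear (endpoint chord) length; W >= 1."""
    seg = np.diff(trace.vertices, axis=0)
    curved = float(np.sqrt((seg**2).sum(axis=1)).sum())
    linear = float(np.linalg.norm(trace.vertices[-1] - trace.vertices[0]))
    if linear == 0:
        raise ValueError("coincident endpoints: linear length is zero")
    return curved / linear


def waviness_batch(
    traces: list[FiberTrace], min_fibers: int = 10, min_frames: int = 6
) -> dict:
    """Per-frame means then the grand mean over frames.

    Frames with fewer than ``min_fibers`` fibers (or fewer than
    ``min_frames`` frames overall) are retained but trigger a warning, so
    sparse tracings are visible without being discarded.
    """
    if not traces:
        raise ValueError("no fiber traces supplied")
    by_frame: dict[int, list[float]] = {}
    for t in traces:
        by_frame.setdefault(t.frame_id, []).append(waviness(t))
    if len(by_frame) < min_frames:
        warnings.warn(
            f"only {len(by_frame)} frames (expected >= {min_frames})", stacklevel=2
        )
    for frame, ws in by_frame.items():
        if len(ws) < min_fibers:
            warnings.warn(
                f"frame {frame} has {len(ws)} fibers (expected >= {min_fibers})",
                stacklevel=2,
            )
    frame_means = {f: float(np.mean(ws)) for f, ws in by_frame.items()}
    all_w = [w for ws in by_frame.values() for w in ws]
    means = np.array(list(frame_means.values()))
    return {
        "per_frame_mean": frame_means,
        "per_frame_count": {f: len(ws) for f, ws in by_frame.items()},
        "grand_mean": float(means.mean()),
        "grand_sd": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        "n_fibers": len(all_w),
        "fiber_sd": float(np.std(all_w, ddof=1)) if len(all_w) > 1 else 0.0,
    }


def anisotropy(
    image: np.ndarray, roi: np.ndarray | None = None
) -> tuple[float, float]:
    """Structure-tensor anisotropy score and mean fiber orientation.

    Returns ``(score, orientation_deg)`` with score in [0, 1] and the
    orientation of the dominant *fiber* axis in [0, 180) measured
    counterclockwise from the +x axis (rows are y, pointing down in image
    coordinates; orientation follows mathematical convention on (x, y)).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("anisotropy expects a single-channel image")
    # Scharr kernels: near-optimal rotational invariance of the gradient
    gx = scharr_v(img)
    gy = scharr_h(img)
    if roi is not None:
        roi_data = roi.data if isinstance(roi, BinaryMask) else np.asarray(roi, dtype=bool)
        gx, gy = gx[roi_data], gy[roi_data]
    jxx = float((gx * gx).sum())
    jyy = float((gy * gy).sum())
    jxy = float((gx * gy).sum())
    trace = jxx + jyy
    if trace <= 0:
        raise ValueError("constant ROI: no gradient signal")
    # eigenvalues of [[jxx, jxy], [jxy, jyy]]
    half_diff = np.hypot((jxx - jyy) / 2.0, jxy)
    l1 = trace / 2.0 + half_diff
    l2 = trace / 2.0 - half_diff
    score = (l1 - l2) / (l1 + l2)
    # dominant gradient direction; fibers run perpendicular to it.
    # Image rows point down, so negate to report standard CCW orientation.
    grad_angle = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    orientation = (-np.degrees(grad_angle) + 90.0) % 180.0
    return float(score), float(orientation)


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 px up to 45% of the shorter image side."""
    limit = int(0.45 * min(shape))
    sizes = []
    s = 2
    while s <= limit:
        sizes.append(s)
        s *= 2
    return sizes


def _box_counts(mask: np.ndarray, eps: int, oy: int, ox: int) -> np.ndarray:
    """Per-box foreground mass for a grid of size ``eps`` anchored at
    ``(-oy, -ox)``; the mask is zero-padded to a multiple of eps."""
    h, w = mask.shape
    padded_h = int(np.ceil((h + oy) / eps)) * eps
    padded_w = int(np.ceil((w + ox) / eps)) * eps
    padded = np.zeros((padded_h, padded_w), dtype=np.int64)
    padded[oy : oy + h, ox : ox + w] = mask
    return padded.reshape(padded_h // eps, eps, padded_w // eps, eps).sum(axis=(1, 3))


@dataclass
class FractalResult:
    dimension: float
    lacunarity: float
    table: pd.DataFrame  # per (size, offset): n_boxes, lacunarity
    flagged_scans: list = field(default_factory=list)


def fractal_lacunarity(
    mask: BinaryMask | np.ndarray,
    box_sizes: list[int] | None = None,
    grid_offsets: int = 4,
    min_density: float = 0.40,
) -> FractalResult:
    """Box-counting dimension and lacunarity over translated grids.

    For each box size and each of ``grid_offsets`` grid origins (the
    origin-anchored grid plus diagonally slipped ones), boxes containing
    foreground are counted and per-box masses recorded. Per size the
    *tightened* count — the minimum over grid origins, i.e. the best
    covering found — enters the dimension fit, so partial boxes from an
    unluckily placed grid do not flatten the slope; ``D`` is the
    least-squares slope of ``log N`` vs ``log (1/eps)``. ``Lambda`` is
    the mean of ``(CV^2 + 1)`` of box masses over occupied boxes, over
    sizes and grid origins. Scans whose overall sampled foreground
    density falls below ``min_density`` times the mean scan density are
    flagged and excluded from the lacunarity average (configurable
    density filter).
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if data.sum() == 0:
        raise ValueError("empty mask")
    if box_sizes is None:
        box_sizes = default_box_sizes(data.shape)
    if len(box_sizes) < 3:
        raise ValueError(f"need at least 3 box sizes, got {len(box_sizes)}")

    rows = []
    for off in range(grid_offsets):
        for eps in box_sizes:
            shift = (off * eps) // grid_offsets
            masses = _box_counts(data, eps, shift, shift)
            occupied = masses[masses > 0]
            n_boxes = occupied.size
            mu = occupied.mean()
            lam = float((occupied.std() / mu) ** 2 + 1.0)
            rows.append(
                {
                    "offset": off,
                    "box_size": eps,
                    "n_boxes": n_boxes,
                    "lacunarity": lam,
                    "density": occupied.sum() / (n_boxes * eps * eps),
                }
            )
    table = pd.DataFrame(rows)

    scan_density = table.groupby("offset")["density"].mean()
    mean_density = scan_density.mean()
    flagged = scan_density.index[scan_density < min_density * mean_density].tolist()
    kept = table[~table["offset"].isin(flagged)]

    tight = kept.groupby("box_size")["n_boxes"].min()
    log_inv_eps = -np.log(tight.index.to_numpy(dtype=float))
    log_n = np.log(tight.to_numpy(dtype=float))
    dimension = float(np.polyfit(log_inv_eps, log_n, 1)[0])
    return FractalResult(
        dimension=dimension,
        lacunarity=float(kept["lacunarity"].mean()),
        table=table,
        flagged_scans=flagged,
    )


def preprocess_for_fractal(image: np.ndarray, pixel_size: float = 1.0) -> BinaryMask:
    """Binarization chain for fractal analysis of fiber images.

    Exact order: rolling-ball background subtraction (radius 75) ->
    unsharp mask (radius 2, weight 0.60) -> median filter (radius 1) ->
    isodata ("default") threshold with bright foreground -> despeckle.
    The order is part of the contract; permuting it changes the result.
    """
    img = np.asarray(image, dtype=np.float64)
    img = rolling_ball_subtract(img, 75)
    img = unsharp_mask(img, 2, 0.60)
    img = np.clip(img, 0, 255)
    img = median_filter(img, 1)
    mask, _ = auto_threshold(img, "default_isodata", pixel_size=pixel_size)
    clean = despeckle(mask.data)
    return BinaryMask(clean, pixel_size, {"op": "preprocess_for_fractal"})
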