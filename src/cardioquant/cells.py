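"""Fluorescence counting recipes for nuclei, markers, vessels and coverage.

Each recipe mirrors a declarative ImageJ-style macro: rolling-ball
background subtraction, a median filter, an automatic histogram
threshold, then particle analysis with edge exclusion and hole
inclusion. Recipes record their parameters into the result provenance so
a count can be replayed.

Channel naming follows the stains: ``hoechst`` (all nuclei), ``edu`` /
``phh3`` (S-phase / mitosis markers), ``wga`` (scar region), ``mlc2v``
(cardiomyocytes), ``isolectin`` (capillaries), ``asma`` (arterial smooth
muscle), ``pdgfrb`` (fibroblasts), ``erg`` (endothelial nuclei).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .imageops import (
    BinaryMask,
    analyze_particles,
    auto_threshold,
    median_filter,
    rolling_ball_subtract,
)

__all__ = [
    "ChannelStack",
    "CountResult",
    "VesselRecord",
    "count_nuclei",
    "scar_roi",
    "positive_fraction_in_roi",
    "cm_proliferation",
    "count_arteries",
    "coverage_fraction",
    "cm_surface_area",
]


@dataclass
class ChannelStack:
    """Aligned named fluorescence channels with a shared pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm / px

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        shapes = {np.asarray(c).shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} missing; available: {sorted(self.channels)}"
            )
        return np.asarray(self.channels[name])


@dataclass(frozen=True)
class CountResult:
    total_nuclei: int
    positive_nuclei: int
    fraction_percent: float
    roi_area_um2: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.positive_nuclei > self.total_nuclei:
            raise ValueError("positive count cannot exceed total")


@dataclass(frozen=True)
class VesselRecord:
    centroid: tuple[float, float]
    max_diameter_um: float
    inside_scar: bool


def _is_constant(channel: np.ndarray) -> bool:
    return np.ptp(np.asarray(channel)) == 0


def _recipe_mask(
    channel: np.ndarray,
    ball_radius: float,
    median_radius: int,
    method: str,
    pixel_size: float,
) -> BinaryMask:
    img = rolling_ball_subtract(np.asarray(channel, dtype=np.float64), ball_radius)
    img = median_filter(img, median_radius)
    mask, _ = auto_threshold(img, method, pixel_size=pixel_size)
    mask.provenance.update(
        {"ball_radius": ball_radius, "median_radius": median_radius, "method": method}
    )
    return mask


def count_nuclei(
    channel: np.ndarray,
    method: str = "default_isodata",
    pixel_size: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Count nuclei: rolling-ball(50) -> median(1) -> threshold ->
    particles (edges excluded, holes included).

    A blank (constant) channel contains no nuclei and returns 0.
    """
    if _is_constant(channel):
        return 0, np.zeros(np.asarray(channel).shape, dtype=int)
    mask = _recipe_mask(channel, 50, 1, method, pixel_size)
    labels, n = analyze_particles(mask, exclude_edges=True, include_holes=True)
    return n, labels


def scar_roi(wga_channel: np.ndarray, pixel_size: float = 1.0) -> BinaryMask:
    """Scar region of interest from the WGA channel: rolling-ball(50) ->
    median(20) -> Yen threshold. The wide median turns the granular WGA
    signal into a solid region."""
    if _is_constant(wga_channel):
        raise ValueError("blank WGA channel: cannot derive a scar ROI")
    return _recipe_mask(wga_channel, 50, 20, "yen", pixel_size)


def _marker_mask(channel: np.ndarray, method: str, pixel_size: float) -> np.ndarray:
    """Thresholded marker mask; a blank channel yields an empty mask."""
    if _is_constant(channel):
        return np.zeros(np.asarray(channel).shape, dtype=bool)
    return _recipe_mask(channel, 50, 1, method, pixel_size).data


def _centroid_in(labels: np.ndarray, region: np.ndarray) -> list[int]:
    kept = []
    for prop in regionprops(labels):
        cy, cx = (int(round(c)) for c in prop.centroid)
        if region[cy, cx]:
            kept.append(prop.label)
    return kept


def positive_fraction_in_roi(
    nuclei_channel: np.ndarray,
    marker_channel: np.ndarray,
    roi: BinaryMask,
    nuclei_method: str = "default_isodata",
    marker_method: str = "yen",
    pixel_size: float = 1.0,
) -> CountResult:
    """Fraction of nuclei inside the ROI whose component overlaps the
    thresholded marker mask (>= 1 px overlap)."""
    if roi.data.sum() == 0:
        raise ValueError("empty ROI")
    _, labels = count_nuclei(nuclei_channel, nuclei_method, pixel_size)
    marker = _marker_mask(marker_channel, marker_method, pixel_size)
    kept = _centroid_in(labels, roi.data)
    positive = sum(1 for lbl in kept if marker[labels == lbl].any())
    total = len(kept)
    return CountResult(
        total_nuclei=total,
        positive_nuclei=positive,
        fraction_percent=100.0 * positive / total if total else 0.0,
        roi_area_um2=roi.area_um2,
        provenance={
            "recipe": "positive_fraction_in_roi",
            "nuclei_method": nuclei_method,
            "marker_method": marker_method,
        },
    )


def cm_proliferation(stack: ChannelStack, marker: str = "edu") -> CountResult:
    """Dividing-cardiomyocyte fraction with capillary exclusion.

    The MLC-2v (cardiomyocyte) segment — rolling-ball(50), median(1),
    isodata — minus the capillary segment from isolectin B4 —
    rolling-ball(5), median(20), isodata — defines the counting region.
    Nuclei (Hoechst) whose centroid lies in the region are counted; a
    nucleus is positive iff it overlaps the thresholded marker mask and
    does not overlap the capillary mask.
    """
    if marker not in ("edu", "phh3"):
        raise ValueError(f"marker must be 'edu' or 'phh3', got {marker!r}")
    ps = stack.pixel_size
    cm_mask = _recipe_mask(stack["mlc2v"], 50, 1, "default_isodata", ps)
    cap_channel = stack["isolectin"]
    if _is_constant(cap_channel):
        cap = np.zeros(cap_channel.shape, dtype=bool)
    else:
        cap = _recipe_mask(cap_channel, 5, 20, "default_isodata", ps).data
    region = cm_mask.data & ~cap
    _, labels = count_nuclei(stack["hoechst"], "default_isodata", ps)
    marker_mask = _marker_mask(stack[marker], "yen", ps)
    kept = _centroid_in(labels, region)
    positive = 0
    for lbl in kept:
        comp = labels == lbl
        if marker_mask[comp].any() and not cap[comp].any():
            positive += 1
    total = len(kept)
    return CountResult(
        total_nuclei=total,
        positive_nuclei=positive,
        fraction_percent=100.0 * positive / total if total else 0.0,
        roi_area_um2=float(region.sum()) * ps**2,
        provenance={"recipe": "cm_proliferation", "marker": marker},
    )


def count_arteries(
    stack: ChannelStack,
    min_diameter_um: float = 10.0,
    max_solidity: float = 0.85,
    min_elongation: float = 2.5,
) -> tuple[int, list[VesselRecord], float]:
    """Count muscularized arteries in the scar area.

    α-SMA+ components inside the WGA+ scar ROI that look like vessel
    cross-sections (ring-like, low solidity, or elongated tubes) are
    measured by their maximum Feret diameter; vessels narrower than
    ``min_diameter_um`` are excluded to avoid α-SMA+ mesenchyme. Returns
    ``(count, records, count per scar mm^2)``; records include excluded
    and out-of-scar vessels for audit.
    """
    ps = stack.pixel_size
    roi = scar_roi(stack["wga"], ps)
    asma_mask = _recipe_mask(stack["asma"], 50, 1, "default_isodata", ps)
    labels, _ = ndi.label(asma_mask.data, structure=np.ones((3, 3)))
    records: list[VesselRecord] = []
    count = 0
    for prop in regionprops(labels):
        area = prop.area
        hull_solidity = prop.solidity
        elong = (
            prop.axis_major_length / prop.axis_minor_length
            if prop.axis_minor_length > 0
            else np.inf
        )
        ring_like = hull_solidity <= max_solidity or elong >= min_elongation
        if not ring_like or area < 4:
            continue
        diameter = prop.feret_diameter_max * ps
        cy, cx = (int(round(c)) for c in prop.centroid)
        inside = bool(roi.data[cy, cx])
        records.append(VesselRecord((cy, cx), diameter, inside))
        if inside and diameter >= min_diameter_um:
            count += 1
    scar_mm2 = roi.area_um2 / 1e6
    density = count / scar_mm2 if scar_mm2 > 0 else float("nan")
    return count, records, density


def coverage_fraction(
    channel: np.ndarray,
    roi: BinaryMask,
    method: str = "moments",
    pixel_size: float = 1.0,
) -> float:
    """Stained area inside the ROI as a percentage of ROI area:
    rolling-ball(50) -> threshold(method). Blank channels cover 0%."""
    if roi.data.sum() == 0:
        raise ValueError("empty ROI")
    if _is_constant(channel):
        return 0.0
    img = rolling_ball_subtract(np.asarray(channel, dtype=np.float64), 50)
    mask, _ = auto_threshold(img, method, pixel_size=pixel_size)
    return 100.0 * float((mask.data & roi.data).sum()) / float(roi.data.sum())


def cm_surface_area(width_um: float, length_um: float) -> float:
    """Cardiomyocyte surface area as width x length (µm^2)."""
    if width_um <= 0 or length_um <= 0:
        raise ValueError("width and length must be > 0")
    return width_um * length_um
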