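"""Synthetic multichannel fluorescence stacks with exact count truth.

Geometry is chosen so that the counting recipes genuinely recover the
planted truth under their rolling-ball/median/threshold chains:

* stain *regions* (WGA scar band, PDGFRβ coverage band) are solid bands
  narrower than the rolling ball, so background subtraction preserves
  them;
* the cardiomyocyte (MLC-2v) region is a dense tube pack (tube width 8,
  gap 2) that survives the radius-50 ball, plus a disk at every CM
  nucleus so nuclear centroids always fall on the segment;
* the capillary (isolectin B4) region is a coarser tube pack (width 8,
  gap 7) whose elements pass the radius-5 ball while the pack is locally
  dense enough (>50%) that the radius-20 median closes it into a solid
  strip; capillary nuclei sit well inside the strip.

Nuclei are non-overlapping disks; noiseless mode gives exact counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage import draw as skdraw

from ..cells import ChannelStack

__all__ = ["MultichannelSpec", "VesselSpec", "gen_multichannel"]


@dataclass(frozen=True)
class VesselSpec:
    diameter_um: float
    inside_scar: bool = True
    wall_um: float = 2.0


@dataclass(frozen=True)
class MultichannelSpec:
    image_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size: float = 1.0  # µm / px
    n_nuclei: int = 100
    nucleus_radius: int = 4  # px
    marker_fractions: Mapping[str, float] = field(default_factory=dict)
    scar_band_px: int | None = None  # WGA+ band width in columns (solid)
    scar_band_offset: int = 40  # left edge of the band (clear of the border)
    render_cm_channels: bool = False  # mlc2v + isolectin geometry
    n_capillary_nuclei: int = 0
    capillary_marker_fractions: Mapping[str, float] = field(default_factory=dict)
    vessels: tuple[VesselSpec, ...] = ()
    coverage_fractions: Mapping[str, float] = field(default_factory=dict)
    border_nucleus: bool = False
    seed: int = 0

    def validate(self) -> None:
        for d in (self.marker_fractions, self.capillary_marker_fractions,
                  self.coverage_fractions):
            for name, f in d.items():
                if not (0 <= f <= 1):
                    raise ValueError(f"fraction for {name!r} must be in [0, 1], got {f}")
        if self.n_nuclei < 0 or self.n_capillary_nuclei < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.n_capillary_nuclei > 0 and not self.render_cm_channels:
            raise ValueError("capillary nuclei require render_cm_channels=True")
        if self.scar_band_px is not None and self.scar_band_px > 95:
            # a solid band wider than the radius-50 rolling ball is treated
            # as background by the recipes and would vanish
            raise ValueError("scar_band_px must stay below the rolling-ball "
                             "diameter (<= 95 px)")


# layout constants (px) for the CM/capillary geometry; the pack starts
# clear of the image border so rolling-ball edge handling cannot bite
_CM_LO, _CM_HI = 40, 240  # mlc2v tube pack columns
_CAP_LO, _CAP_HI = 160, 240  # capillary pack columns (inside the CM band)
_CM_NUC_COLS = (52, 148)  # CM nuclei centroid column range
_CAP_NUC_COLS = (180, 220)  # capillary nuclei, well inside the closed strip


def _place_nuclei(
    rng: np.random.Generator,
    n: int,
    row_range: tuple[int, int],
    col_range: tuple[int, int],
    min_dist: float,
    existing: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    all_pts = list(existing)
    capacity = max(
        1,
        ((row_range[1] - row_range[0]) // int(min_dist))
        * ((col_range[1] - col_range[0]) // int(min_dist) + 1),
    )
    if n > capacity:
        raise ValueError(
            f"cannot fit {n} non-overlapping nuclei in the region (capacity ~{capacity})"
        )
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200_000:
            raise ValueError(
                f"cannot fit {n} non-overlapping nuclei at the stated density"
            )
        r = int(rng.integers(row_range[0], row_range[1]))
        c = int(rng.integers(col_range[0], col_range[1]))
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist**2 for pr, pc in all_pts):
            placed.append((r, c))
            all_pts.append((r, c))
    return placed


def _draw_disks(img: np.ndarray, centers: list[tuple[int, int]], radius: int, value: int) -> None:
    for r, c in centers:
        rr, cc = skdraw.disk((r, c), radius, shape=img.shape)
        img[rr, cc] = value


def _tube_pack(shape: tuple[int, int], col_lo: int, col_hi: int, tube: int, gap: int,
               value: int) -> np.ndarray:
    """Horizontal tubes of height ``tube`` px separated by ``gap`` px,
    restricted to a column band."""
    img = np.zeros(shape, dtype=np.uint8)
    period = tube + gap
    rows = np.arange(shape[0])
    on = (rows % period) < tube
    img[np.ix_(on, np.arange(col_lo, col_hi))] = value
    return img


def gen_multichannel(spec: MultichannelSpec) -> tuple[ChannelStack, dict]:
    """Render the stack and return ``(stack, truth)``.

    Truth holds exact planted counts: total nuclei, per-channel positive
    counts for the primary and capillary populations, band fractions,
    vessel diameters and coverage fractions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    h, w = shape
    r_nuc = spec.nucleus_radius
    margin = r_nuc + 4
    min_dist = 2 * r_nuc + 4

    channels: dict[str, np.ndarray] = {}
    truth: dict = {}

    # primary nucleus region
    if spec.render_cm_channels:
        col_range = _CM_NUC_COLS
    elif spec.scar_band_px is not None:
        col_range = (
            spec.scar_band_offset + margin,
            spec.scar_band_offset + spec.scar_band_px - margin,
        )
    else:
        col_range = (margin, w - margin)
    primary = _place_nuclei(rng, spec.n_nuclei, (margin, h - margin), col_range,
                            min_dist, [])
    capillary: list[tuple[int, int]] = []
    if spec.n_capillary_nuclei:
        # stay clear of the border: the wide-median capillary mask
        # shrinks by roughly its radius at the image edges
        cap_margin = max(margin, 24)
        capillary = _place_nuclei(
            rng,
            spec.n_capillary_nuclei,
            (cap_margin, h - cap_margin),
            (_CAP_NUC_COLS[0], _CAP_NUC_COLS[1]),
            min_dist,
            primary,
        )

    hoechst = np.zeros(shape, dtype=np.uint8)
    _draw_disks(hoechst, primary, r_nuc, 200)
    _draw_disks(hoechst, capillary, r_nuc, 200)
    if spec.border_nucleus:
        _draw_disks(hoechst, [(0, w // 2)], r_nuc, 200)
    channels["hoechst"] = hoechst
    truth["n_nuclei"] = spec.n_nuclei
    truth["n_capillary_nuclei"] = spec.n_capillary_nuclei

    # marker channels: exact positive counts by construction
    truth["marker_positive"] = {}
    truth["capillary_marker_positive"] = {}
    marker_names = set(spec.marker_fractions) | set(spec.capillary_marker_fractions)
    for name in sorted(marker_names):
        img = np.zeros(shape, dtype=np.uint8)
        k = int(round(spec.marker_fractions.get(name, 0.0) * len(primary)))
        if k:
            chosen = [primary[i] for i in rng.choice(len(primary), k, replace=False)]
            _draw_disks(img, chosen, r_nuc, 200)
        truth["marker_positive"][name] = k
        kc = int(
            round(spec.capillary_marker_fractions.get(name, 0.0) * len(capillary))
        )
        if kc:
            chosen = [capillary[i] for i in rng.choice(len(capillary), kc, replace=False)]
            _draw_disks(img, chosen, r_nuc, 200)
        truth["capillary_marker_positive"][name] = kc
        channels[name] = img

    if spec.scar_band_px is not None:
        wga = np.zeros(shape, dtype=np.uint8)
        off = spec.scar_band_offset
        wga[:, off : off + spec.scar_band_px] = 170
        channels["wga"] = wga
        truth["scar_band_fraction"] = spec.scar_band_px / w
        truth["scar_area_um2"] = spec.scar_band_px * h * spec.pixel_size**2

    if spec.render_cm_channels:
        mlc2v = _tube_pack(shape, _CM_LO, _CM_HI, tube=8, gap=2, value=150)
        _draw_disks(mlc2v, primary, r_nuc + 2, 160)
        channels["mlc2v"] = mlc2v
        isolectin = _tube_pack(shape, _CAP_LO, _CAP_HI, tube=8, gap=7, value=180)
        _draw_disks(isolectin, capillary, r_nuc + 1, 180)
        channels["isolectin"] = isolectin

    if spec.vessels:
        if spec.scar_band_px is None:
            raise ValueError("vessels require scar_band_px (the WGA+ area)")
        asma = np.zeros(shape, dtype=np.uint8)
        n_v = len(spec.vessels)
        rows = np.linspace(h * 0.15, h * 0.85, n_v).astype(int)
        diam_truth = []
        for vessel, row in zip(spec.vessels, rows):
            r_out = max(2, int(round(vessel.diameter_um / 2.0 / spec.pixel_size)))
            wall = max(2, int(round(vessel.wall_um / spec.pixel_size)))
            band_end = spec.scar_band_offset + spec.scar_band_px
            col = (
                spec.scar_band_offset + spec.scar_band_px // 2
                if vessel.inside_scar
                else min(w - r_out - 4, band_end + (w - band_end) // 2)
            )
            rr, cc = skdraw.disk((row, col), r_out, shape=shape)
            asma[rr, cc] = 190
            inner = max(1, r_out - wall)
            rr, cc = skdraw.disk((row, col), inner, shape=shape)
            asma[rr, cc] = 0
            diam_truth.append((vessel.diameter_um, vessel.inside_scar))
        channels["asma"] = asma
        truth["vessel_diameters_um"] = tuple(diam_truth)

    for name, frac in spec.coverage_fractions.items():
        if spec.scar_band_px is None:
            raise ValueError("coverage_fractions require scar_band_px")
        img = np.zeros(shape, dtype=np.uint8)
        width = int(round(frac * spec.scar_band_px))
        img[:, spec.scar_band_offset : spec.scar_band_offset + width] = 160
        channels[name] = img
        truth.setdefault("coverage_fraction", {})[name] = width / spec.scar_band_px

    return ChannelStack(channels, spec.pixel_size), truth
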