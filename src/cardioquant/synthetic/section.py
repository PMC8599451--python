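"""Synthetic histological section images with known color composition.

Sections are rendered as a tissue disk on a desaturated background, with
pixel colors constructed directly in 8-bit HSB space (the convention of
every gate in the morphometry stage) and converted to RGB. Hue jitter is
uniform and clipped so that scar pixels stay inside the scar hue gate
(140-200) and tissue pixels inside the tissue-only band (60-139); a
2-unit guard margin absorbs the 8-bit RGB round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..imageops import BinaryMask, SectionImage, hsb255_to_rgb

__all__ = [
    "SectionSimSpec",
    "gen_section",
    "gen_evans_blue_section",
    "gen_birefringence_section",
]

_GUARD = 2  # hue guard margin against 8-bit RGB round-trip error


@dataclass(frozen=True)
class SectionSimSpec:
    image_size: int = 512  # px (square)
    pixel_size: float = 5.0  # µm / px
    scar_fraction_target: float = 0.3  # fraction of tissue area
    scar_hue: int = 170  # 0-255; must lie in the scar gate 140-200
    tissue_hue: int = 100  # 0-255; must lie in 60-139 (tissue-only band)
    hue_jitter: int = 5  # uniform +/- jitter, clipped to the band
    disk_radius: int | None = None  # px; default 40% of image size
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.scar_fraction_target <= 1):
            raise ValueError(
                f"scar_fraction_target must be in [0, 1], got {self.scar_fraction_target}"
            )
        if not (140 <= self.scar_hue <= 200):
            raise ValueError(f"scar_hue must lie in [140, 200], got {self.scar_hue}")
        if not (60 <= self.tissue_hue <= 139):
            raise ValueError(f"tissue_hue must lie in [60, 139], got {self.tissue_hue}")
        if self.hue_jitter < 0:
            raise ValueError("hue_jitter must be >= 0")

    @property
    def radius(self) -> int:
        return self.disk_radius if self.disk_radius is not None else int(0.4 * self.image_size)


def _disk_mask(size: int, radius: int) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def _render_hsb(
    size: int,
    regions: list[tuple[np.ndarray, int, tuple[int, int], int, int]],
    rng: np.random.Generator,
    jitter: int,
    background_hsb: tuple[int, int, int] = (0, 0, 230),
) -> np.ndarray:
    """Render regions given as (mask, hue_center, hue_band, sat, bright)."""
    h = np.full((size, size), background_hsb[0], dtype=np.int32)
    s = np.full((size, size), background_hsb[1], dtype=np.int32)
    b = np.full((size, size), background_hsb[2], dtype=np.int32)
    for mask, hue, (lo, hi), sat, bright in regions:
        n = int(mask.sum())
        hues = hue + (rng.integers(-jitter, jitter + 1, size=n) if jitter else 0)
        h[mask] = np.clip(hues, lo + _GUARD, hi - _GUARD)
        s[mask] = sat
        b[mask] = bright
    return hsb255_to_rgb(np.stack([h, s, b], axis=-1).astype(np.uint8))


def gen_section(spec: SectionSimSpec) -> tuple[SectionImage, float, float]:
    """Trichrome-like section: scar wedge inside a tissue disk.

    Returns ``(image, true_scar_fraction, true_tissue_area_um2)``. The
    scar occupies a contiguous angular wedge whose pixel count is exactly
    ``round(target * n_tissue_pixels)``, so the rendered fraction matches
    the target to within one pixel.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    tissue = _disk_mask(size, spec.radius)
    n_tissue = int(tissue.sum())
    n_scar = int(round(spec.scar_fraction_target * n_tissue))

    yy, xx = np.nonzero(tissue)
    c = (size - 1) / 2.0
    angles = np.arctan2(yy - c, xx - c)
    order = np.argsort(angles, kind="stable")
    scar = np.zeros_like(tissue)
    scar[yy[order[:n_scar]], xx[order[:n_scar]]] = True

    rgb = _render_hsb(
        size,
        [
            (tissue & ~scar, spec.tissue_hue, (60, 139), 180, 200),
            (scar, spec.scar_hue, (140, 200), 180, 200),
        ],
        rng,
        spec.hue_jitter,
    )
    true_fraction = n_scar / n_tissue
    true_area = n_tissue * spec.pixel_size**2
    return SectionImage(rgb, spec.pixel_size), true_fraction, true_area


def gen_evans_blue_section(
    image_size: int = 512,
    pixel_size: float = 5.0,
    unstained_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[SectionImage, float]:
    """Dye-perfusion section: perfused tissue carries the dye hue
    (140-200 band), the ischemic dye-excluded wedge a red hue (201-255
    band). Returns ``(image, true_unstained_fraction)``."""
    if not (0 <= unstained_fraction <= 1):
        raise ValueError("unstained_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tissue = _disk_mask(image_size, int(0.4 * image_size))
    n_tissue = int(tissue.sum())
    n_unstained = int(round(unstained_fraction * n_tissue))
    yy, xx = np.nonzero(tissue)
    c = (image_size - 1) / 2.0
    order = np.argsort(np.arctan2(yy - c, xx - c), kind="stable")
    unstained = np.zeros_like(tissue)
    unstained[yy[order[:n_unstained]], xx[order[:n_unstained]]] = True

    rgb = _render_hsb(
        image_size,
        [
            (tissue & ~unstained, 170, (140, 200), 190, 180),  # dye (blue)
            (unstained, 235, (201, 255), 150, 210),  # pale ischemic tissue
        ],
        rng,
        jitter=4,
    )
    return SectionImage(rgb, pixel_size), n_unstained / n_tissue


def gen_birefringence_section(
    image_size: int = 512,
    pixel_size: float = 2.0,
    fractions: tuple[float, float, float, float] = (0.5, 0.3, 0.15, 0.05),
    seed: int = 0,
) -> tuple[SectionImage, BinaryMask, dict[str, float]]:
    """Polarized-light style image with a known red/orange/yellow/green
    hue composition inside a disk-shaped scar ROI.

    ``fractions`` are the (red, orange, yellow, green) shares of the
    birefringent signal; they must sum to 1. Pixels are assigned to bins
    by exact counts, rendered at the center hue of each gate on a black
    (non-birefringent) background. Returns ``(image, roi, truth)`` with
    truth in percent.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    roi = _disk_mask(image_size, int(0.35 * image_size))
    n = int(roi.sum())
    counts = [int(round(f * n)) for f in fractions]
    counts[-1] = n - sum(counts[:-1])

    # center hues of the four gates: red 1-13, orange 14-25, yellow 26-52, green 53-110
    centers = {"red": 7, "orange": 20, "yellow": 39, "green": 82}
    bands = {"red": (1, 13), "orange": (14, 25), "yellow": (26, 52), "green": (53, 110)}
    yy, xx = np.nonzero(roi)
    perm = rng.permutation(n)
    regions = []
    start = 0
    for (name, hue), cnt in zip(centers.items(), counts):
        sel = np.zeros_like(roi)
        idx = perm[start : start + cnt]
        sel[yy[idx], xx[idx]] = True
        start += cnt
        regions.append((sel, hue, bands[name], 200, 180))
    rgb = _render_hsb(image_size, regions, rng, jitter=2, background_hsb=(0, 0, 0))
    truth = {name: 100.0 * cnt / n for name, cnt in zip(centers, counts)}
    return (
        SectionImage(rgb, pixel_size),
        BinaryMask(roi, pixel_size, {"op": "synthetic_roi"}),
        truth,
    )
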