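"""Echocardiographic output metrics from M-mode morphometry.

Fractional shortening (FS) and ejection fraction (EF) are computed from
left-ventricular internal diameters at end-diastole (LVID;d) and
end-systole (LVID;s):

    FS (%) = (LVID;d - LVID;s) / LVID;d x 100
    EF (%) = (LVID;d^3 - LVID;s^3) / LVID;d^3 x 100

The cubic EF treats the ventricle as a shape whose volume scales with the
cube of its internal diameter, so EF >= FS always holds for
0 <= LVID;s <= LVID;d. Replicate M-mode measurements (five per animal by
convention) are averaged parameter-wise *before* the formulas are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

__all__ = [
    "MModeMeasurement",
    "EchoSummary",
    "fractional_shortening",
    "ejection_fraction",
    "summarize_echo",
]

_PARAMS = ("LVID_d", "LVID_s", "LVFW_d", "LVFW_s", "IVS_d", "IVS_s")


@dataclass(frozen=True)
class MModeMeasurement:
    """One M-mode replicate: internal diameters, free-wall and septal
    thicknesses (mm) at end-diastole (_d) and end-systole (_s)."""

    LVID_d: float
    LVID_s: float
    LVFW_d: float = 0.0
    LVFW_s: float = 0.0
    IVS_d: float = 0.0
    IVS_s: float = 0.0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "replicate_id":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class EchoSummary:
    EF: float  # %
    FS: float  # %
    averaged: dict  # parameter name -> mean (mm)
    n_replicates: int
    quality_flags: tuple[str, ...] = ()


def fractional_shortening(LVID_d: float, LVID_s: float) -> float:
    """FS (%) = ((LVID;d - LVID;s) / LVID;d) x 100."""
    if LVID_d <= 0:
        raise ValueError(f"LVID_d must be > 0, got {LVID_d}")
    return (LVID_d - LVID_s) / LVID_d * 100.0


def ejection_fraction(LVID_d: float, LVID_s: float) -> float:
    """EF (%) = ((LVID;d^3 - LVID;s^3) / LVID;d^3) x 100."""
    if LVID_d <= 0:
        raise ValueError(f"LVID_d must be > 0, got {LVID_d}")
    return (LVID_d**3 - LVID_s**3) / LVID_d**3 * 100.0


def summarize_echo(measurements: list[MModeMeasurement]) -> EchoSummary:
    """Average replicate parameters, then compute EF and FS from the means.

    Five replicates are the expected convention; fewer (or more) trigger a
    warning but are averaged all the same. LVID;s exceeding LVID;d after
    averaging yields negative EF/FS and a quality flag rather than an
    error, since dyskinetic ventricles can genuinely produce it.
    """
    if not measurements:
        raise ValueError("summarize_echo requires at least one measurement")
    if len(measurements) != 5:
        warnings.warn(
            f"expected 5 M-mode replicates, got {len(measurements)}", stacklevel=2
        )
    averaged = {
        p: sum(getattr(m, p) for m in measurements) / len(measurements) for p in _PARAMS
    }
    flags: list[str] = []
    if averaged["LVID_s"] > averaged["LVID_d"]:
        flags.append("LVID_s > LVID_d")
    return EchoSummary(
        EF=ejection_fraction(averaged["LVID_d"], averaged["LVID_s"]),
        FS=fractional_shortening(averaged["LVID_d"], averaged["LVID_s"]),
        averaged=averaged,
        n_replicates=len(measurements),
        quality_flags=tuple(flags),
    )
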