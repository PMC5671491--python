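"""TEX86 temperature calibration and ring-index screening.

Two quality screens guard TEX86-based temperature estimates:

1. The RI-TEX86 *calibration zone*: across global core-top sediments the
   ring index tracks TEX86 along the parabola
   ``RI = 3.32 * TEX86**2 - 0.77 * TEX86 + 1.59`` with a ±2σ envelope of
   about 0.3 ring units.  A sample whose measured ring index departs from
   the parabola by more than the half-width (``delta_ri``) carries a GDGT
   pool whose ring distribution is not governed by temperature alone.

2. Threshold flags from the screening literature: BIT > 0.2 (terrestrial
   input), GDGT-2/Cren > 0.4, Methane Index > 0.5 (methanotrophy),
   GDGT-0/Cren > 2, %GDGT-2 > 45.

Flags are advisory: the pipeline reports them and never silently drops
flagged samples.  A flag whose input index is undefined is *indeterminate*
(``None``), distinct from both True and False.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .indices import IndexSet

__all__ = [
    "CalibrationParams",
    "ScreenThresholds",
    "ScreenResult",
    "tex86_temperature",
    "predicted_ri",
    "delta_ri",
    "qc_flags",
    "screen_index_set",
]


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the TEX86 temperature and RI-TEX86 calibrations.

    ``slope``/``intercept`` define SST = slope * log10(TEX86) + intercept
    (°C); ``ri_a``, ``ri_b``, ``ri_c`` the core-top RI(TEX86) parabola;
    ``zone_halfwidth`` the ±2σ calibration-zone envelope in ring units.
    ``log_base`` is configurable so natural-log calibration variants can
    be tested.
    """

    slope: float = 68.4
    intercept: float = 38.6
    ri_a: float = 3.32
    ri_b: float = -0.77
    ri_c: float = 1.59
    zone_halfwidth: float = 0.3
    log_base: float = 10.0

    def inverse_temperature(self, temp_c: float) -> float:
        """TEX86 value whose calibrated temperature is ``temp_c``."""
        return self.log_base ** ((temp_c - self.intercept) / self.slope)


@dataclass(frozen=True)
class ScreenThresholds:
    """Strict (>) thresholds for the advisory QC flags."""

    bit: float = 0.2
    ratio_2_cren: float = 0.4
    methane_index: float = 0.5
    ratio_0_cren: float = 2.0
    pct_gdgt2: float = 45.0


@dataclass(frozen=True)
class ScreenResult:
    """Calibration-zone screen and QC flags for one index set.

    ``flags`` values are True/False, or None when the underlying index is
    undefined.  ``in_calibration_zone`` is the negation of the
    ``ri_deviation`` flag (None when TEX86 or the ring index is undefined).
    """

    tex86_temp: float = math.nan
    ri_predicted: float = math.nan
    delta_ri: float = math.nan
    in_calibration_zone: bool | None = None
    flags: dict = field(default_factory=dict)


def tex86_temperature(t: float, cal: CalibrationParams = CalibrationParams()) -> float:
    """Calibrated (sea-surface) temperature in °C for a TEX86 value.

    Undefined (NaN) for t <= 0 or t undefined.
    """
    if math.isnan(t) or t <= 0:
        return math.nan
    return cal.slope * (math.log(t) / math.log(cal.log_base)) + cal.intercept


def predicted_ri(t: float, cal: CalibrationParams = CalibrationParams()) -> float:
    """Core-top calibration ring index expected at a given TEX86 value."""
    if math.isnan(t):
        return math.nan
    return cal.ri_a * t * t + cal.ri_b * t + cal.ri_c


def delta_ri(
    ri_measured: float,
    t: float,
    cal: CalibrationParams = CalibrationParams(),
) -> tuple[float, bool | None]:
    """Offset of a measured ring index from the calibration parabola.

    Returns ``(measured - predicted, |offset| <= zone_halfwidth)``; both
    are undefined (NaN, None) when either input is undefined.
    """
    if math.isnan(ri_measured) or math.isnan(t):
        return math.nan, None
    d = ri_measured - predicted_ri(t, cal)
    return d, abs(d) <= cal.zone_halfwidth


def qc_flags(
    ix: IndexSet,
    thresholds: ScreenThresholds = ScreenThresholds(),
    *,
    ri_deviation: bool | None = None,
) -> dict:
    """Advisory QC flags; each is True iff its strict inequality holds.

    A flag is None (indeterminate) when its index is undefined.
    ``ri_deviation`` is injected from the calibration-zone test.
    """

    def gt(value: float, threshold: float) -> bool | None:
        if math.isnan(value):
            return None
        return value > threshold

    return {
        "bit_gt_0_2": gt(ix.bit, thresholds.bit),
        "g2_cren_gt_0_4": gt(ix.ratio_2_cren, thresholds.ratio_2_cren),
        "mi_gt_0_5": gt(ix.methane_index, thresholds.methane_index),
        "g0_cren_gt_2": gt(ix.ratio_0_cren, thresholds.ratio_0_cren),
        "pct_g2_gt_45": gt(ix.pct_gdgt2, thresholds.pct_gdgt2),
        "ri_deviation": ri_deviation,
    }


def screen_index_set(
    ix: IndexSet,
    cal: CalibrationParams = CalibrationParams(),
    thresholds: ScreenThresholds = ScreenThresholds(),
    *,
    ri_variant: str = "ri1",
) -> ScreenResult:
    """Full screen of one index set: temperature, ΔRI and QC flags.

    ``ri_variant`` selects which measured ring index enters the zone test;
    the calibration parabola was fitted with the crenarchaeol-weighted
    variant, so ``"ri1"`` is the default.  (The crenarchaeol-free
    ``"ri2"`` sits on a different scale and is not zone-tested in normal
    use.)
    """
    if ri_variant not in ("ri1", "ri2"):
        raise ValueError(f"ri_variant must be 'ri1' or 'ri2', got {ri_variant!r}")
    ri_measured = getattr(ix, ri_variant)
    d, in_zone = delta_ri(ri_measured, ix.tex86, cal)
    flags = qc_flags(
        ix, thresholds, ri_deviation=None if in_zone is None else not in_zone
    )
    return ScreenResult(
        tex86_temp=tex86_temperature(ix.tex86, cal),
        ri_predicted=predicted_ri(ix.tex86, cal),
        delta_ri=d,
        in_calibration_zone=in_zone,
        flags=flags,
    )
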