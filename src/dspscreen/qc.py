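"""Plate normalization and robust Z' quality control.

Raw luminescence counts are converted to percent inhibition against the
per-plate control means,

    inhibition = 100 * (count - mean_DMSO) / (mean_benzethonium - mean_DMSO),

so a DMSO-level well reads 0% and a benzethonium-level well 100%.  Values
below 0 (growth stimulation) and above 100 are kept as-is; downstream
fitting tolerates them.

Plate quality is judged by the robust Z-prime, computed from control
medians and robust dispersions rather than means/SDs so single outlier
wells cannot sink a plate:

    Z' = 1 - 3 * (mad_pos + mad_neg) / |median_neg - median_pos|

The dispersion convention is configurable; the default is the median
absolute deviation scaled by 1.4826 (consistent with sigma under
normality).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

from .errors import QCError
from .model import PlateLayout, RawPlate, WellAddress, WellRole

#: scaling that makes the median absolute deviation consistent with the
#: standard deviation of a normal distribution
MAD_NORMAL_SCALE = 1.4826

DEFAULT_ZPRIME_THRESHOLD = 0.5


class MadConvention(str, Enum):
    SCALED_MEDIAN_AD = "scaled_median_ad"  # 1.4826 * median(|x - median|)
    MEDIAN_AD = "median_ad"                # median(|x - median|)
    MEAN_AD = "mean_ad"                    # mean(|x - mean|)


def robust_dispersion(values: np.ndarray, convention: MadConvention) -> float:
    values = np.asarray(values, dtype=float)
    if convention is MadConvention.MEAN_AD:
        return float(np.mean(np.abs(values - values.mean())))
    mad = float(np.median(np.abs(values - np.median(values))))
    if convention is MadConvention.SCALED_MEDIAN_AD:
        mad *= MAD_NORMAL_SCALE
    return mad


@dataclass(frozen=True)
class ControlStats:
    """Per-plate summary of the DMSO / benzethonium / staurosporine wells."""

    mean_neg: float
    mean_pos: float
    median_neg: float
    median_pos: float
    mad_neg: float
    mad_pos: float
    n_neg: int
    n_pos: int
    n_mid: int
    median_mid: float | None
    mad_convention: MadConvention = MadConvention.SCALED_MEDIAN_AD


@dataclass(frozen=True)
class PlateQC:
    zprime: float
    qc_class: str  # "pass" | "fail"
    threshold_used: float

    @property
    def passed(self) -> bool:
        return self.qc_class == "pass"


@dataclass(frozen=True)
class NormalizedPlate:
    plate_id: str
    inhibition: Mapping[WellAddress, float]
    stats: ControlStats
    qc: PlateQC
    layout_ref: str


def control_stats(
    plate: RawPlate,
    layout: PlateLayout,
    mad_convention: MadConvention = MadConvention.SCALED_MEDIAN_AD,
) -> ControlStats:
    """Means, medians and robust dispersions over the plate's control wells."""
    plate.check_against_layout(layout)

    def _counts(role: WellRole) -> np.ndarray:
        return np.array(
            [plate.counts[a.well] for a in layout.wells_by_role(role) if a.well in plate.counts],
            dtype=float,
        )

    neg = _counts(WellRole.NEG_CONTROL)
    pos = _counts(WellRole.POS_CONTROL)
    mid = _counts(WellRole.MID_CONTROL)
    if neg.size < 2 or pos.size < 2:
        raise QCError(
            f"plate {plate.plate_id}: insufficient controls "
            f"(neg={neg.size}, pos={pos.size}; need >= 2 of each)"
        )
    return ControlStats(
        mean_neg=float(neg.mean()),
        mean_pos=float(pos.mean()),
        median_neg=float(np.median(neg)),
        median_pos=float(np.median(pos)),
        mad_neg=robust_dispersion(neg, mad_convention),
        mad_pos=robust_dispersion(pos, mad_convention),
        n_neg=int(neg.size),
        n_pos=int(pos.size),
        n_mid=int(mid.size),
        median_mid=float(np.median(mid)) if mid.size else None,
        mad_convention=mad_convention,
    )


def percent_inhibition(count: float, stats: ControlStats) -> float:
    """Percent inhibition of metabolic activity for one raw count.

    Not clipped: counts above the DMSO mean give negative inhibition,
    counts below the benzethonium mean exceed 100%.
    """
    denom = stats.mean_pos - stats.mean_neg
    if denom == 0:
        raise QCError("no control separation (mean_pos == mean_neg)")
    return 100.0 * (count - stats.mean_neg) / denom


def robust_zprime(stats: ControlStats) -> float:
    """Robust Z-prime from control medians and robust dispersions (<= 1)."""
    sep = abs(stats.median_neg - stats.median_pos)
    if sep == 0:
        raise QCError("no control separation (identical control medians)")
    return 1.0 - 3.0 * (stats.mad_pos + stats.mad_neg) / sep


def normalize_plate(
    plate: RawPlate,
    layout: PlateLayout,
    qc_threshold: float = DEFAULT_ZPRIME_THRESHOLD,
    mad_convention: MadConvention = MadConvention.SCALED_MEDIAN_AD,
) -> NormalizedPlate:
    """Normalize every well of a plate and attach its QC verdict."""
    stats = control_stats(plate, layout, mad_convention)
    zp = robust_zprime(stats)
    qc = PlateQC(
        zprime=zp,
        qc_class="pass" if zp >= qc_threshold else "fail",
        threshold_used=qc_threshold,
    )
    inhibition = {
        well: percent_inhibition(count, stats) for well, count in plate.counts.items()
    }
    return NormalizedPlate(
        plate_id=plate.plate_id,
        inhibition=inhibition,
        stats=stats,
        qc=qc,
        layout_ref=plate.layout_ref,
    )


def classify_screen(plate_qcs: list[PlateQC], n_expected: int = 3) -> str:
    """Screen type from per-plate QC: all three plates passing makes a full
    screen, 1-2 passing a partial screen, none a failed screen."""
    if not plate_qcs:
        raise QCError("cannot classify a screen with no plate QC results")
    n_pass = sum(q.passed for q in plate_qcs)
    if n_pass == n_expected:
        return "full"
    if n_pass >= 1:
        return "partial"
    return "failed"
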