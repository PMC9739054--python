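"""Morpho-physiological index formulas.

Excised-leaf water loss, relative water content, chlorophyll fluorescence,
relative cell-membrane injury, flag-leaf senescence rate, growing-degree-day
phyllochron intervals, early vigour, harvest index and spike fertility.
All inputs are per-sample scalars; samples that violate the expected
monotone orderings raise a degenerate-sample error on zero/inverted
denominators and are otherwise flagged by the caller, never silently
clamped.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSampleError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LeafWeightSeries:
    """Excised-leaf weights: fresh at 0/4/8 h and oven-dry, grams."""

    FW0: float
    FW4: float
    FW8: float
    DW: float


@dataclass(frozen=True)
class RWCSample:
    """Fresh, turgid (12 h soak) and oven-dry leaf weights, grams."""

    FW: float
    TW: float
    DW: float


@dataclass(frozen=True)
class FluorescenceSample:
    """Dark-adapted minimal (Fo) and maximal (Fm) fluorescence."""

    Fo: float
    Fm: float


@dataclass(frozen=True)
class ConductivitySample:
    """Conductance before/after autoclave for control (C) and heat-treated (T) discs."""

    C1: float
    C2: float
    T1: float
    T2: float


@dataclass(frozen=True)
class SenescenceSeries:
    """SPAD after stress (SPAD_a), at maturity (SPAD_m) and the day span."""

    SPAD_a: float
    SPAD_m: float
    days_anthesis10_to_maturity: float


@dataclass(frozen=True)
class EarlyVigourRecord:
    leaf_areas: tuple[float, float, float]
    phyllochron_intervals: tuple[float, float, float]
    vigour_index: float


def elwl(series: LeafWeightSeries) -> dict[str, float]:
    """Excised-leaf water loss, % of initial water content per interval.

    elwl_0_4 = 100*(FW0-FW4)/(FW0-DW), elwl_4_8 = 100*(FW4-FW8)/(FW4-DW),
    elwl_0_8 = 100*(FW0-FW8)/(FW0-DW).
    """
    d04 = series.FW0 - series.DW
    d48 = series.FW4 - series.DW
    if d04 <= 0 or d48 <= 0:
        raise DegenerateSampleError(
            f"non-positive water content: FW0-DW={d04:.4g}, FW4-DW={d48:.4g}"
        )
    return {
        "elwl_0_4": 100.0 * (series.FW0 - series.FW4) / d04,
        "elwl_4_8": 100.0 * (series.FW4 - series.FW8) / d48,
        "elwl_0_8": 100.0 * (series.FW0 - series.FW8) / d04,
    }


def rwc(sample: RWCSample) -> float:
    """Relative water content, 100*(FW-DW)/(TW-DW)."""
    denom = sample.TW - sample.DW
    if denom <= 0:
        raise DegenerateSampleError(f"turgid weight must exceed dry weight (TW-DW={denom:.4g})")
    return 100.0 * (sample.FW - sample.DW) / denom


def fv_fm(sample: FluorescenceSample) -> float:
    """Maximum PSII quantum yield, (Fm-Fo)/Fm."""
    if sample.Fm <= 0:
        raise DegenerateSampleError("Fm must be positive")
    value = (sample.Fm - sample.Fo) / sample.Fm
    if sample.Fm <= sample.Fo:
        logger.warning("Fv/Fm out of range: Fo %.4g >= Fm %.4g", sample.Fo, sample.Fm)
    return value


def rci(sample: ConductivitySample) -> float:
    """Relative cell-membrane injury, 100*(1 - (1-T1/T2)/(1-C1/C2)).

    The control ratio C1/C2 measures background leakage; a heat-injured
    sample leaks more before autoclaving, raising T1/T2 toward 1.
    """
    if sample.C2 <= 0 or sample.T2 <= 0:
        raise DegenerateSampleError("post-autoclave conductances must be positive")
    c_ratio = sample.C1 / sample.C2
    if c_ratio >= 1:
        raise DegenerateSampleError(
            f"control ratio C1/C2={c_ratio:.4g} >= 1: injury formula undefined"
        )
    t_ratio = sample.T1 / sample.T2
    return 100.0 * (1.0 - (1.0 - t_ratio) / (1.0 - c_ratio))


def flsm(series: SenescenceSeries) -> float:
    """Flag-leaf senescence rate, % relative greenness lost per day."""
    if series.SPAD_a <= 0:
        raise DegenerateSampleError("SPAD after stress must be positive")
    if series.days_anthesis10_to_maturity <= 0:
        raise DegenerateSampleError("day span must be positive")
    return (
        100.0 * (1.0 - series.SPAD_m / series.SPAD_a)
        / series.days_anthesis10_to_maturity
    )


def daily_gdd(t_min: np.ndarray, t_max: np.ndarray, base_temp: float = 0.0) -> np.ndarray:
    """Daily growing degree days, max(0, (t_max+t_min)/2 - base)."""
    t_min = np.asarray(t_min, dtype=float)
    t_max = np.asarray(t_max, dtype=float)
    if np.any(t_max < t_min):
        raise ParameterError("t_max below t_min in temperature series")
    return np.maximum(0.0, (t_max + t_min) / 2.0 - base_temp)


def gdd_and_phyllochron(
    t_min: Sequence[float],
    t_max: Sequence[float],
    leaf_emergence_days: Sequence[int],
    base_temp: float = 0.0,
) -> tuple[float, ...]:
    """Sowing-anchored phyllochron intervals in degC-day.

    Interval i is the cumulative GDD from sowing (day index 0) through the
    emergence day of leaf i.  Temperatures are daily min/max series indexed
    from the day of sowing.
    """
    gdd = daily_gdd(t_min, t_max, base_temp)
    cum = np.cumsum(gdd)
    out = []
    for day in leaf_emergence_days:
        if not 0 <= day < cum.size:
            raise ParameterError(
                f"emergence day {day} outside the temperature series (0..{cum.size - 1})"
            )
        out.append(float(cum[day]))
    return tuple(out)


def early_vigour(
    areas: Sequence[float], intervals: Sequence[float]
) -> EarlyVigourRecord:
    """Early vigour: first three leaf areas per unit thermal time.

    The composite index divides the summed area of leaves 1-3 by the
    thermal time to third-leaf emergence (cm^2 per degC-day); components
    are stored so any alternative composite can be recomputed.
    """
    areas = tuple(float(a) for a in areas)
    intervals = tuple(float(v) for v in intervals)
    if len(areas) != 3 or len(intervals) != 3:
        raise ParameterError("early vigour needs three leaf areas and three intervals")
    if any(a <= 0 for a in areas):
        raise DegenerateSampleError("leaf areas must be positive")
    if any(v <= 0 for v in intervals):
        raise DegenerateSampleError("phyllochron intervals must be positive")
    return EarlyVigourRecord(
        leaf_areas=areas,
        phyllochron_intervals=intervals,
        vigour_index=sum(areas) / intervals[2],
    )


def derived_traits(gy: float, agdm: float, grains: float, spikelets: float) -> dict[str, float]:
    """Harvest index (% of above-ground dry matter) and spike fertility.

    Spike fertility is grains per spikelet reported on a x100 scale (the
    screening tables print values like 81.21 grains per 100 spikelets).
    """
    if agdm <= 0:
        raise DegenerateSampleError("above-ground dry matter must be positive")
    if spikelets <= 0:
        raise DegenerateSampleError("spikelet count must be positive")
    return {"HI": 100.0 * gy / agdm, "SF": 100.0 * grains / spikelets}
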