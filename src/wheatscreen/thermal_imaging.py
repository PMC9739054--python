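"""Canopy thermography: segmentation, reference temperatures, stress indices.

A thermal image is a grid of temperatures in degrees Celsius.  The canopy is
segmented as the cooler of two 1-D temperature clusters (transpiring leaves
sit below the warmer background), empirical wet/dry reference temperatures
are taken as symmetric tail means of the canopy pixel distribution, and the
water-stress indices follow

    CWSI = (T_c - T_wet) / (T_dry - T_wet)
    Ig   = (T_dry - T_c) / (T_c - T_wet)
    CTD  = T_a - T_c

where T_c is the mean canopy temperature and T_a the ambient temperature.
CWSI runs from 0 (fully transpiring) to 1 (fully stressed); Ig is
proportional to stomatal conductance; CTD is positive when the canopy is
cooler than the surrounding air.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .errors import ParameterError, SegmentationError


@dataclass
class ThermalImage:
    """Temperature grid (degC) with ambient temperature and a plant id."""

    pixels: np.ndarray
    ambient_temp: float
    plant_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ParameterError("thermal image must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("thermal image holds non-finite pixels")


@dataclass
class CanopyMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_canopy(self) -> int:
        return int(self.mask.sum())


@dataclass
class ReferenceTemps:
    """Empirical wet/dry references; ``flat`` marks a constant canopy."""

    t_wet: float
    t_dry: float
    flat: bool = False


@dataclass
class WaterStressSummary:
    """Per-plant water-stress indices; undefined fields are None + flagged."""

    plant_id: str
    t_c: float
    t_wet: float
    t_dry: float
    t_a: float
    cwsi: Optional[float]
    ig: Optional[float]
    ctd: float
    flags: list[str] = field(default_factory=list)


# -- index formulas (scalar, reusable on printed table values) -------------

def cwsi(t_c: float, t_wet: float, t_dry: float) -> float:
    """Crop water stress index, (T_c - T_wet)/(T_dry - T_wet)."""
    denom = t_dry - t_wet
    if denom == 0:
        raise ParameterError("CWSI undefined: T_dry equals T_wet")
    return (t_c - t_wet) / denom


def ig(t_c: float, t_wet: float, t_dry: float) -> float:
    """Infrared conductance index, (T_dry - T_c)/(T_c - T_wet)."""
    denom = t_c - t_wet
    if denom == 0:
        raise ParameterError("Ig undefined: T_c equals T_wet")
    return (t_dry - t_c) / denom


def ctd(t_a: float, t_c: float) -> float:
    """Canopy temperature depression, T_a - T_c."""
    return t_a - t_c


# -- segmentation ----------------------------------------------------------

def segment_canopy(
    img: ThermalImage,
    mode: str = "temperature_gap",
    provided_mask: np.ndarray | None = None,
    min_pixels: int = 25,
    gap_factor: float = 4.0,
    seed: int = 0,
) -> CanopyMask:
    """Segment canopy pixels.

    ``provided_mask`` passes an external mask through (shape-checked).
    ``temperature_gap`` splits the pixel temperatures into two 1-D clusters
    (two-means) and assigns the cooler cluster to the canopy; the split must
    be bimodal, i.e. the between-centre gap must exceed ``gap_factor`` times
    the pooled within-cluster standard deviation, otherwise segmentation
    fails rather than returning an arbitrary cut of a unimodal histogram.
    The default factor of 4 rejects single-mode pixel distributions (a lone
    Gaussian mode splits with a ratio near 2.6, a uniform one near 3.5)
    while a leaf-to-background temperature gap of a few degC clears it.
    """
    if mode == "provided_mask":
        if provided_mask is None:
            raise ParameterError("provided_mask mode needs a mask")
        mask = np.asarray(provided_mask, dtype=bool)
        if mask.shape != img.pixels.shape:
            raise ParameterError(
                f"mask shape {mask.shape} differs from image {img.pixels.shape}"
            )
        out = CanopyMask(mask)
        if out.n_canopy < min_pixels:
            raise SegmentationError(
                f"canopy holds {out.n_canopy} pixels, below minimum {min_pixels}"
            )
        return out
    if mode != "temperature_gap":
        raise ParameterError(f"unknown segmentation mode {mode!r}")

    values = img.pixels.ravel()
    if np.ptp(values) == 0:
        raise SegmentationError("uniform image: no temperature gap to segment on")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    labels = km.labels_
    cool = int(np.argmin(centers))
    gap = abs(centers[0] - centers[1])
    within = [values[labels == k] for k in (0, 1)]
    pooled_var = sum(v.size * v.var() for v in within) / values.size
    pooled_sd = math.sqrt(pooled_var)
    if pooled_sd > 0 and gap < gap_factor * pooled_sd:
        raise SegmentationError(
            f"pixel histogram not bimodal: centre gap {gap:.3g} degC below "
            f"{gap_factor} x pooled within-cluster sd {pooled_sd:.3g}"
        )
    mask = (labels == cool).reshape(img.pixels.shape)
    out = CanopyMask(mask)
    if out.n_canopy < min_pixels:
        raise SegmentationError(
            f"canopy holds {out.n_canopy} pixels, below minimum {min_pixels}"
        )
    return out


# -- reference temperatures ------------------------------------------------

def reference_temperatures(
    img: ThermalImage, mask: CanopyMask, tail: float = 0.05
) -> ReferenceTemps:
    """Wet/dry references as means of the coolest/hottest ceil(tail*n) pixels."""
    if not 0.0 < tail < 0.5:
        raise ParameterError("tail fraction must lie in (0, 0.5)")
    canopy = np.sort(img.pixels[mask.mask].ravel())
    n = canopy.size
    m = math.ceil(tail * n)
    if m < 1 or n == 0:
        raise ParameterError("canopy too small for the requested tail fraction")
    t_wet = float(canopy[:m].mean())
    t_dry = float(canopy[-m:].mean())
    return ReferenceTemps(t_wet=t_wet, t_dry=t_dry, flat=(t_wet == t_dry))


# -- summary ---------------------------------------------------------------

def water_stress_summary(
    img: ThermalImage,
    mask: CanopyMask,
    refs: ReferenceTemps,
    t_a: float | None = None,
) -> WaterStressSummary:
    """Mean canopy temperature plus CWSI, Ig and CTD.

    Values are never clipped: a T_c outside [T_wet, T_dry] (possible with
    externally supplied references) yields out-of-range values plus a flag,
    and undefined ratios come back as None with a flag.
    """
    t_a = img.ambient_temp if t_a is None else float(t_a)
    t_c = float(img.pixels[mask.mask].mean())
    flags: list[str] = []
    if refs.flat or refs.t_dry <= refs.t_wet:
        flags.append("flat_canopy" if refs.flat else "inverted_references")
        cwsi_val: Optional[float] = None
    else:
        cwsi_val = cwsi(t_c, refs.t_wet, refs.t_dry)
        if not 0.0 <= cwsi_val <= 1.0:
            flags.append("tc_outside_references")
    if t_c == refs.t_wet or refs.t_dry <= refs.t_wet:
        ig_val: Optional[float] = None
        if "flat_canopy" not in flags and "inverted_references" not in flags:
            flags.append("ig_undefined")
    else:
        ig_val = ig(t_c, refs.t_wet, refs.t_dry)
    return WaterStressSummary(
        plant_id=img.plant_id,
        t_c=t_c,
        t_wet=refs.t_wet,
        t_dry=refs.t_dry,
        t_a=t_a,
        cwsi=cwsi_val,
        ig=ig_val,
        ctd=ctd(t_a, t_c),
        flags=flags,
    )


def analyze_image(
    img: ThermalImage,
    tail: float = 0.05,
    mode: str = "temperature_gap",
    provided_mask: np.ndarray | None = None,
    min_pixels: int = 25,
    seed: int = 0,
) -> WaterStressSummary:
    """Segment, derive references and summarize in one call."""
    mask = segment_canopy(
        img, mode=mode, provided_mask=provided_mask, min_pixels=min_pixels, seed=seed
    )
    refs = reference_temperatures(img, mask, tail=tail)
    return water_stress_summary(img, mask, refs)
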