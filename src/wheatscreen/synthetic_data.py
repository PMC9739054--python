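"""Synthetic trials, canopy thermal images and senescence series.

Everything downstream is tested as estimate-versus-truth, so every
generator returns its ground truth next to the simulated data.  The default
trial emulates the screening study's design: 46 genotypes of which 5 checks
are replicated in each of 4 blocks and 41 tests appear once each, with
additive block and genotype effects plus Gaussian error,

    y_ij = mu + g_i + b_j + e_ij,   e_ij ~ N(0, sigma_e^2).

Default trait means and effect variances are back-derived from the study's
printed genotypic variances and coefficients of variation
(mean = 100 * sqrt(GV) / GCV), so the simulated trial sits at the same
signal-to-noise operating point as the real one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_formats import FieldBook
from .thermal_imaging import ThermalImage

DEFAULT_CHECKS = ("KUKRI", "DRYSDALE", "RAC875", "EXCALIBUR", "AXE")


@dataclass
class TraitSim:
    """One trait's generative parameters.

    Either pass explicit per-genotype effects or let them be drawn as
    N(0, genotype_effect_sd^2), centred to mean zero.
    """

    mean: float
    error_sd: float
    genotype_effect_sd: float = 1.0
    genotype_effects: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.error_sd < 0:
            raise ParameterError("error_sd must be >= 0")
        if self.genotype_effect_sd < 0:
            raise ParameterError("genotype_effect_sd must be >= 0")


@dataclass
class SimulationSpec:
    n_blocks: int = 4
    checks: Sequence[str] = DEFAULT_CHECKS
    n_tests: int = 41
    traits: dict[str, TraitSim] = field(default_factory=dict)
    block_effects: Sequence[float] | None = None
    treatment_label: str = "DS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2 or len(self.checks) < 2:
            raise ParameterError("need >=2 blocks and >=2 checks")
        if self.n_tests < 1:
            raise ParameterError("need >=1 test genotype")
        if self.block_effects is not None:
            eff = np.asarray(self.block_effects, dtype=float)
            if eff.size != self.n_blocks:
                raise ParameterError("block_effects length must equal n_blocks")
            if abs(eff.sum()) > 1e-8 * max(1.0, np.abs(eff).max()):
                raise ParameterError("block_effects must sum to zero")
        if not self.traits:
            self.traits = study_default_traits()


def study_default_traits() -> dict[str, TraitSim]:
    """Drought-screening operating point from the study's printed summary.

    Effect sds are sqrt(GV), error sds sqrt(EV), means 100*sqrt(GV)/GCV.
    """
    rows = {
        # trait: (GV, EV, GCV %)
        "GY": (1.52, 0.02, 31.02),
        "SPS": (14.71, 1.43, 14.39),
        "GPS": (39.37, 0.54, 41.31),
        "HI": (52.29, 12.01, 25.48),
        "PHT": (148.03, 0.29, 24.10),
        "D50A": (57.81, 0.53, 14.34),
        "SF": (378.90, 2.95, 34.60),
    }
    return {
        name: TraitSim(
            mean=100.0 * math.sqrt(gv) / gcv,
            error_sd=math.sqrt(ev),
            genotype_effect_sd=math.sqrt(gv),
        )
        for name, (gv, ev, gcv) in rows.items()
    }


def _assign_tests_to_blocks(test_ids: Sequence[str], n_blocks: int) -> dict[str, int]:
    """Round-robin assignment in id order (position never enters the model)."""
    return {g: i % n_blocks for i, g in enumerate(test_ids)}


def simulate_fieldbook(spec: SimulationSpec) -> tuple[FieldBook, pd.DataFrame, pd.DataFrame]:
    """Simulate an augmented trial.

    Returns (field book, genotype-truth table, block-truth table).  The
    genotype truth holds the true effect and true value (mean + effect) per
    genotype and trait; the block truth holds the true block effects.
    """
    rng = np.random.default_rng(spec.seed)
    checks = [str(c) for c in spec.checks]
    tests = [f"T{i + 1:02d}" for i in range(spec.n_tests)]
    blocks = [f"B{j + 1}" for j in range(spec.n_blocks)]
    if spec.block_effects is not None:
        block_eff = np.asarray(spec.block_effects, dtype=float)
    else:
        block_eff = rng.normal(0.0, 1.0, size=spec.n_blocks)
        block_eff -= block_eff.mean()
    assignment = _assign_tests_to_blocks(tests, spec.n_blocks)

    geno_truth_rows = []
    effects_by_trait: dict[str, dict[str, float]] = {}
    for trait, sim in spec.traits.items():
        if sim.genotype_effects is not None:
            eff = {g: float(sim.genotype_effects.get(g, 0.0)) for g in checks + tests}
        else:
            draws = rng.normal(0.0, sim.genotype_effect_sd, size=len(checks) + len(tests))
            draws -= draws.mean()
            eff = dict(zip(checks + tests, draws))
        effects_by_trait[trait] = eff
        for g in checks + tests:
            geno_truth_rows.append(
                {"trait": trait, "genotype": g, "effect": eff[g],
                 "true_value": sim.mean + eff[g]}
            )

    records = []
    for j, blk in enumerate(blocks):
        for g in checks:
            records.append({"genotype": g, "block": blk, "is_check": True})
    for g in tests:
        records.append({"genotype": g, "block": blocks[assignment[g]], "is_check": False})
    df = pd.DataFrame(records)
    df["treatment"] = spec.treatment_label

    for trait, sim in spec.traits.items():
        eff = effects_by_trait[trait]
        bidx = df["block"].map({b: i for i, b in enumerate(blocks)}).to_numpy()
        noise = rng.normal(0.0, sim.error_sd, size=len(df)) if sim.error_sd > 0 else 0.0
        df[trait] = (
            sim.mean
            + df["genotype"].map(eff).to_numpy()
            + block_eff[bidx]
            + noise
        )

    fb = FieldBook(df)
    geno_truth = pd.DataFrame(geno_truth_rows)
    block_truth = pd.DataFrame({"block": blocks, "effect": block_eff})
    return fb, geno_truth, block_truth


# -- thermal images --------------------------------------------------------

@dataclass
class ThermalSimSpec:
    grid_shape: tuple[int, int] = (60, 80)
    canopy_fraction: float = 0.35
    canopy_temp_mean: float = 24.0
    canopy_temp_sd: float = 0.3
    background_offset: float = 5.0
    background_jitter_sd: float = 0.1
    ambient_temp: float = 25.0
    plant_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        if r < 1 or c < 1:
            raise ParameterError("grid_shape must be positive")
        if not 0.0 < self.canopy_fraction < 1.0:
            raise ParameterError("canopy_fraction must lie in (0, 1)")
        if self.canopy_temp_sd < 0 or self.background_jitter_sd < 0:
            raise ParameterError("temperature sds must be >= 0")


def _ellipse_mask(shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Centred ellipse covering approximately ``fraction`` of the grid."""
    r, c = shape
    yy, xx = np.mgrid[0:r, 0:c]
    cy, cx = (r - 1) / 2.0, (c - 1) / 2.0
    # ellipse area pi*a*b = fraction*r*c with a/b = r/c
    scale = math.sqrt(fraction * r * c / (math.pi * (r / 2.0) * (c / 2.0)))
    a, b = scale * r / 2.0, scale * c / 2.0
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def simulate_thermal_image(
    spec: ThermalSimSpec,
) -> tuple[ThermalImage, np.ndarray, dict[str, float]]:
    """Simulate a canopy-over-background thermal image.

    Canopy pixels ~ N(canopy_temp_mean, canopy_temp_sd^2); background
    pixels sit at canopy_temp_mean + background_offset with a small jitter.
    Returns (image, ground-truth mask, truth dict with the canopy mean and
    the realized mean canopy temperature T_c).
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipse_mask(spec.grid_shape, spec.canopy_fraction)
    pixels = np.empty(spec.grid_shape, dtype=float)
    n_canopy = int(mask.sum())
    canopy_vals = spec.canopy_temp_mean + (
        rng.normal(0.0, spec.canopy_temp_sd, size=n_canopy)
        if spec.canopy_temp_sd > 0
        else np.zeros(n_canopy)
    )
    bg_mean = spec.canopy_temp_mean + spec.background_offset
    n_bg = pixels.size - n_canopy
    bg_vals = bg_mean + (
        rng.normal(0.0, spec.background_jitter_sd, size=n_bg)
        if spec.background_jitter_sd > 0
        else np.zeros(n_bg)
    )
    pixels[mask] = canopy_vals
    pixels[~mask] = bg_vals
    img = ThermalImage(pixels=pixels, ambient_temp=spec.ambient_temp, plant_id=spec.plant_id)
    truth = {
        "canopy_temp_mean": spec.canopy_temp_mean,
        "realized_t_c": float(canopy_vals.mean()),
        "n_canopy": float(n_canopy),
    }
    return img, mask, truth


# -- senescence series -----------------------------------------------------

def simulate_senescence_series(
    initial_spad: float,
    daily_loss_rate: float,
    n_weeks: int = 6,
    days_to_maturity: int = 42,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Weekly SPAD readings declining linearly in relative greenness.

    SPAD(d) = SPAD_0 * (1 - r*d/100) with r in %/day, sampled weekly for
    ``n_weeks`` and at maturity (day ``days_to_maturity``), plus optional
    Gaussian reading noise.  The truth dict records the senescence rate r
    and the noise-free maturity reading, so the endpoint rate estimator can
    be checked as an exact inverse at zero noise.
    """
    if initial_spad <= 0:
        raise ParameterError("initial_spad must be positive")
    if daily_loss_rate < 0 or noise_sd < 0:
        raise ParameterError("rates and noise must be non-negative")
    if n_weeks < 1 or days_to_maturity <= 0:
        raise ParameterError("n_weeks and days_to_maturity must be positive")
    rng = np.random.default_rng(seed)
    days = [7 * w for w in range(n_weeks)]
    if days_to_maturity not in days:
        days.append(days_to_maturity)
    days = sorted(d for d in days if d <= days_to_maturity)
    clean = [initial_spad * (1.0 - daily_loss_rate * d / 100.0) for d in days]
    noisy = [v + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0) for v in clean]
    table = pd.DataFrame({"day": days, "spad": noisy, "spad_clean": clean})
    truth = {
        "flsm": daily_loss_rate,
        "spad_at_maturity": initial_spad * (1.0 - daily_loss_rate * days_to_maturity / 100.0),
        "days_to_maturity": float(days_to_maturity),
    }
    return table, truth
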