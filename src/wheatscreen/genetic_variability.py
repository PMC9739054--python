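"""Variance components, coefficients of variation, heritability and genetic advance.

From the augmented analysis: the environmental variance EV is the residual
mean square; the phenotypic variance PV is the sample variance of the
adjusted genotype means; the genotypic variance GV is PV minus EV,
truncated at zero, so PV = GV + EV by construction.  (An alternative
estimator, adjusted-genotypes mean square minus EV, is available behind a
flag but is upward-biased in this design because checks enter the genotype
sum of squares with b replicates.)  Derived screening statistics:

    XCV  = 100 * sqrt(XV) / mean            for X in {G, P, E}
    h^2  = GV / PV                          (broad sense)
    GA   = k * sqrt(PV) * h^2               (gain at selection intensity k)
    GAM  = 100 * GA / mean

with k = 2.063, the standardized selection differential at 5% selection.
CV and GAM categories: low below 10%, medium from 10 to below 20%, high
from 20% up (boundary values go to the higher category).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .augmented_design import AdjustedMeans, AnovaTable, adjust_means, anova
from .errors import AnalysisError, ParameterError
from .io_formats import FieldBook, RunConfig

logger = logging.getLogger(__name__)

DEFAULT_SELECTION_INTENSITY = 2.063


@dataclass
class VarianceComponents:
    PV: float
    GV: float
    EV: float
    gv_truncated: bool = False


def variance_components(
    anova_result: AnovaTable,
    adjusted: AdjustedMeans | None = None,
    estimator: str = "adjusted_means",
) -> VarianceComponents:
    """PV/GV/EV estimates; EV is the residual MS under either estimator.

    ``adjusted_means`` (default): GV = sample variance of the adjusted
    genotype means minus EV; nearly unbiased for the genotype-effect
    variance in this design.  ``mean_square``: GV = adjusted-Genotypes MS
    minus EV; inflated because checks carry b replicates into the genotype
    sum of squares, but kept for comparison.  Negative GV is a known
    small-sample artifact, logged and truncated at zero.
    """
    ev = anova_result.mse
    if estimator == "mean_square":
        gv_raw = float(anova_result.row("Genotypes")["MS"]) - ev
    elif estimator == "adjusted_means":
        if adjusted is None:
            raise ParameterError("adjusted_means estimator needs the adjusted means")
        gv_raw = float(adjusted.table["adjusted_mean"].var(ddof=1)) - ev
    else:
        raise ParameterError(f"unknown GV estimator {estimator!r}")
    truncated = gv_raw < 0
    if truncated:
        logger.warning(
            "trait %s: negative genotypic variance %.4g truncated to 0",
            anova_result.trait, gv_raw,
        )
    gv = max(gv_raw, 0.0)
    return VarianceComponents(PV=gv + ev, GV=gv, EV=ev, gv_truncated=truncated)


def categorize_cv(value: float, bounds: tuple[float, float] = (10.0, 20.0)) -> str:
    """low / medium / high, boundaries assigned upward (10 -> medium, 20 -> high)."""
    lo, hi = bounds
    if value < lo:
        return "low"
    if value < hi:
        return "medium"
    return "high"


def coefficients_of_variation(
    components: VarianceComponents,
    mean: float,
    bounds: tuple[float, float] = (10.0, 20.0),
) -> dict[str, float | str]:
    if mean <= 0:
        raise AnalysisError(f"coefficients of variation undefined for mean {mean}")
    out: dict[str, float | str] = {}
    for name, var in (("GCV", components.GV), ("PCV", components.PV), ("ECV", components.EV)):
        out[name] = 100.0 * math.sqrt(var) / mean
    out["gcv_category"] = categorize_cv(float(out["GCV"]), bounds)
    out["pcv_category"] = categorize_cv(float(out["PCV"]), bounds)
    return out


def genetic_advance(
    components: VarianceComponents,
    mean: float,
    k: float = DEFAULT_SELECTION_INTENSITY,
    bounds: tuple[float, float] = (10.0, 20.0),
) -> dict[str, float | str]:
    """Heritability, expected gain and gain as percent of the trait mean."""
    if mean <= 0:
        raise AnalysisError(f"genetic advance undefined for mean {mean}")
    if components.PV == 0:
        logger.warning("PV is zero; genetic advance set to 0")
        return {"h2": 0.0, "GA": 0.0, "GAM": 0.0, "gam_category": "low"}
    h2 = components.GV / components.PV
    ga = k * math.sqrt(components.PV) * h2
    gam = 100.0 * ga / mean
    return {"h2": h2, "GA": ga, "GAM": gam, "gam_category": categorize_cv(gam, bounds)}


def variability_report(
    fb: FieldBook,
    traits: list[str] | None = None,
    config: RunConfig | None = None,
    estimator: str = "adjusted_means",
) -> pd.DataFrame:
    """Per-trait variability table (one row per trait, Table-style columns).

    The trait mean used for the CVs and GAM is the mean of adjusted means
    over all genotypes, checks counted once.
    """
    config = config or RunConfig()
    traits = traits or fb.trait_names
    rows = []
    for trait in traits:
        an = anova(fb, trait)
        adj = adjust_means(fb, trait)
        comp = variance_components(an, adj, estimator=estimator)
        mean = float(adj.table["adjusted_mean"].mean())
        cvs = coefficients_of_variation(comp, mean, config.cv_category_bounds)
        ga = genetic_advance(comp, mean, config.selection_intensity_k, config.cv_category_bounds)
        rows.append(
            {
                "trait": trait,
                "mean": mean,
                "PV": comp.PV,
                "GV": comp.GV,
                "EV": comp.EV,
                "GCV": cvs["GCV"],
                "gcv_category": cvs["gcv_category"],
                "PCV": cvs["PCV"],
                "pcv_category": cvs["pcv_category"],
                "ECV": cvs["ECV"],
                "h2": ga["h2"],
                "GA": ga["GA"],
                "GAM": ga["GAM"],
                "gam_category": ga["gam_category"],
            }
        )
    return pd.DataFrame(rows)
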