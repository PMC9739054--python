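"""Augmented randomized complete block design analysis.

In an augmented RCBD, c check genotypes are replicated once in each of b
blocks while t test genotypes appear exactly once.  The replicated checks
estimate the block effects and the residual error; each test observation is
then corrected by its block's estimated effect.  The ANOVA partitions the
N - 1 = b*c + t - 1 total degrees of freedom as

    Block                      b - 1        (ignoring treatments)
    Genotypes (adjusted)       c + t - 1    (eliminating blocks)
      Check                    c - 1
      Test and Test-vs-Check   t
    Residual                   (b - 1)(c - 1)

The residual comes from the check-only two-way layout; because every test
genotype is fit exactly by its own effect, the full least-squares residual
coincides with it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, DesignViolationError, IncompleteDesignError, ParameterError
from .io_formats import FieldBook


@dataclass
class AdjustedMeans:
    """Per-genotype adjusted means for one trait.

    ``table`` has columns genotype, source ("check"/"test"), raw_mean,
    block_adjustment, adjusted_mean.  Check adjusted means are plain means
    over blocks (adjustment 0); test adjusted means subtract the block
    effect of the block they sat in.
    """

    trait: str
    table: pd.DataFrame
    block_effects: dict[str, float]

    def value(self, genotype: str) -> float:
        row = self.table.loc[self.table["genotype"] == genotype]
        if row.empty:
            raise ParameterError(f"no adjusted mean for genotype {genotype!r}")
        return float(row["adjusted_mean"].iloc[0])

    @property
    def series(self) -> pd.Series:
        return self.table.set_index("genotype")["adjusted_mean"]


@dataclass
class AnovaTable:
    """Five-source augmented ANOVA; the check/test split is kept verbose."""

    trait: str
    rows: pd.DataFrame  # columns: source, df, SS, MS, F, p
    n_blocks: int
    n_checks: int
    n_tests: int
    verbose: dict[str, float] = field(default_factory=dict)

    def row(self, source: str) -> pd.Series:
        hit = self.rows.loc[self.rows["source"] == source]
        if hit.empty:
            raise ParameterError(f"no ANOVA source {source!r}")
        return hit.iloc[0]

    @property
    def mse(self) -> float:
        return float(self.row("Residuals")["MS"])

    @property
    def residual_df(self) -> int:
        return int(self.row("Residuals")["df"])

    @property
    def df_column(self) -> tuple[int, ...]:
        return tuple(int(d) for d in self.rows["df"])


@dataclass
class ComparisonErrors:
    """Standard errors and critical differences for the four comparison classes."""

    mse: float
    se_check_vs_check: float
    se_test_same_block: float
    se_test_diff_block: float
    se_test_vs_check: float
    cd_check_vs_check: float
    cd_test_same_block: float
    cd_test_diff_block: float
    cd_test_vs_check: float
    alpha: float


# -- block effects and adjusted means --------------------------------------

def _check_table(fb: FieldBook, trait: str) -> pd.DataFrame:
    """Check observations as a complete checks x blocks table."""
    df = fb.subset_trait(trait)
    chk = df[df["is_check"]]
    blocks = sorted(df["block"].unique())
    checks = sorted(chk["genotype"].unique())
    if len(blocks) < 2 or len(checks) < 2:
        raise DesignViolationError(
            f"trait {trait!r}: need >=2 blocks and >=2 checks with data, "
            f"got {len(blocks)} and {len(checks)}"
        )
    wide = chk.pivot_table(index="genotype", columns="block", values="value", aggfunc="mean")
    wide = wide.reindex(index=checks, columns=blocks)
    if wide.isna().any().any():
        g = wide.isna().stack()
        g = g[g].index[0]
        raise IncompleteDesignError(
            f"trait {trait!r}: check {g[0]!r} has no value in block {g[1]!r}"
        )
    return wide


def estimate_block_effects(fb: FieldBook, trait: str) -> dict[str, float]:
    """Block effect = mean of that block's checks minus the grand check mean."""
    wide = _check_table(fb, trait)
    grand = float(wide.to_numpy().mean())
    return {b: float(wide[b].mean() - grand) for b in wide.columns}


def adjust_means(fb: FieldBook, trait: str) -> AdjustedMeans:
    """Adjusted means: checks averaged over blocks, tests block-corrected."""
    effects = estimate_block_effects(fb, trait)
    df = fb.subset_trait(trait)
    rows = []
    chk = df[df["is_check"]].groupby("genotype", observed=True)["value"].mean()
    for g, raw in chk.items():
        rows.append(
            {"genotype": g, "source": "check", "raw_mean": float(raw),
             "block_adjustment": 0.0, "adjusted_mean": float(raw)}
        )
    for _, r in df[~df["is_check"]].iterrows():
        eff = effects[str(r["block"])]
        rows.append(
            {"genotype": str(r["genotype"]), "source": "test",
             "raw_mean": float(r["value"]), "block_adjustment": -eff,
             "adjusted_mean": float(r["value"]) - eff}
        )
    table = pd.DataFrame(rows).sort_values(["source", "genotype"]).reset_index(drop=True)
    return AdjustedMeans(trait=trait, table=table, block_effects=effects)


# -- ANOVA -----------------------------------------------------------------

def anova(fb: FieldBook, trait: str) -> AnovaTable:
    """Augmented-RCBD ANOVA for one trait.

    Block SS ignores treatments; the adjusted Genotypes SS eliminates
    blocks (difference between total SS, block-ignoring SS and the full
    least-squares residual); the residual is the check-only two-way
    interaction SS on (b-1)(c-1) df.  F tests use the residual mean square.
    """
    wide = _check_table(fb, trait)  # validates design
    df = fb.subset_trait(trait)
    y = df["value"].to_numpy(dtype=float)
    n = y.size
    blocks = sorted(df["block"].unique())
    checks = list(wide.index)
    tests = sorted(df.loc[~df["is_check"], "genotype"].unique())
    b, c, t = len(blocks), len(checks), len(tests)

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    # Block SS ignoring treatments
    ss_block_ign = float(
        df.groupby("block", observed=True)["value"]
        .apply(lambda v: len(v) * (v.mean() - grand) ** 2)
        .sum()
    )

    # Residual: check-only two-way interaction SS
    arr = wide.to_numpy(dtype=float)
    gmean = arr.mean()
    resid = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True) + gmean
    ss_resid = float((resid ** 2).sum())
    # snap float dust to an exact zero so noise-free data gives F = inf
    if ss_resid <= 1e-12 * max(ss_total, 1.0):
        ss_resid = 0.0
    df_resid = (b - 1) * (c - 1)

    # Genotypes eliminating blocks = total - block(ignoring) - residual
    ss_geno = ss_total - ss_block_ign - ss_resid
    # Check SS (orthogonal to blocks in the complete check layout)
    ss_check = float(b * ((arr.mean(axis=1) - gmean) ** 2).sum())
    ss_test_tvc = ss_geno - ss_check

    # verbose dual convention + test/test-vs-check split from adjusted values
    block_means = {bl: float(wide[bl].mean()) for bl in wide.columns}
    grand_chk = gmean
    adj = adjust_means(fb, trait)
    test_adj = adj.table.loc[adj.table["source"] == "test", "adjusted_mean"].to_numpy()
    ss_test_among = float(((test_adj - test_adj.mean()) ** 2).sum())
    ss_block_elim = ss_total - ss_resid - _ss_genotype_ignoring(df, grand)
    verbose = {
        "ss_block_eliminating": ss_block_elim,
        "ss_genotype_ignoring": _ss_genotype_ignoring(df, grand),
        "ss_test_among_adjusted": ss_test_among,
        "ss_test_vs_check": ss_test_tvc - ss_test_among,
        "block_check_means": block_means,
        "grand_check_mean": grand_chk,
    }

    sources = [
        ("Block", b - 1, ss_block_ign),
        ("Genotypes", c + t - 1, ss_geno),
        ("Check", c - 1, ss_check),
        ("Test and Test vs. Check", t, ss_test_tvc),
        ("Residuals", df_resid, ss_resid),
    ]
    if df_resid < 1:
        raise DesignViolationError("no residual degrees of freedom")
    mse = ss_resid / df_resid
    rows = []
    for name, dfree, ss in sources:
        ms = ss / dfree if dfree > 0 else math.nan
        if name == "Residuals" or dfree == 0:
            F = p = math.nan
        elif mse == 0:
            F, p = math.inf if ms > 0 else math.nan, 0.0 if ms > 0 else math.nan
        else:
            F = ms / mse
            p = float(stats.f.sf(F, dfree, df_resid))
        rows.append({"source": name, "df": dfree, "SS": ss, "MS": ms, "F": F, "p": p})
    return AnovaTable(
        trait=trait,
        rows=pd.DataFrame(rows),
        n_blocks=b,
        n_checks=c,
        n_tests=t,
        verbose=verbose,
    )


def _ss_genotype_ignoring(df: pd.DataFrame, grand: float) -> float:
    return float(
        df.groupby("genotype", observed=True)["value"]
        .apply(lambda v: len(v) * (v.mean() - grand) ** 2)
        .sum()
    )


# -- comparison standard errors --------------------------------------------

def comparison_errors(
    anova_result: AnovaTable,
    b: int | None = None,
    c: int | None = None,
    alpha: float = 0.05,
) -> ComparisonErrors:
    """SEs and critical differences for the four augmented-design contrasts."""
    b = anova_result.n_blocks if b is None else b
    c = anova_result.n_checks if c is None else c
    mse = anova_result.mse
    dfree = anova_result.residual_df
    if dfree < 1:
        raise AnalysisError("comparison errors undefined: zero residual df")
    se_cc = math.sqrt(2 * mse / b)
    se_ts = math.sqrt(2 * mse)
    se_td = math.sqrt(2 * mse * (1 + 1 / c))
    se_tc = math.sqrt(mse * (1 + 1 / b + 1 / c + 1 / (b * c)))
    tq = float(stats.t.ppf(1 - alpha / 2, dfree))
    return ComparisonErrors(
        mse=mse,
        se_check_vs_check=se_cc,
        se_test_same_block=se_ts,
        se_test_diff_block=se_td,
        se_test_vs_check=se_tc,
        cd_check_vs_check=tq * se_cc,
        cd_test_same_block=tq * se_ts,
        cd_test_diff_block=tq * se_td,
        cd_test_vs_check=tq * se_tc,
        alpha=alpha,
    )


def significance_stars(p: float) -> str:
    """Render a p-value the way trial reports print it."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
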