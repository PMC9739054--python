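import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wheatscreen as ws
from wheatscreen.augmented_design import comparison_errors, significance_stars
from wheatscreen.errors import DesignViolationError, IncompleteDesignError


def ls_decomposition(fb):
    """Brute-force sequential least-squares SS oracle.

    Fits mean -> +block dummies -> +genotype dummies with numpy lstsq and
    returns (SS_block_ignoring, SS_genotype_eliminating, SS_residual).
    """
    df = fb.data
    y = df["Y"].to_numpy(dtype=float)
    blocks = pd.get_dummies(df["block"]).to_numpy(dtype=float)
    genos = pd.get_dummies(df["genotype"]).to_numpy(dtype=float)
    ones = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    rss_mean = rss(ones)
    rss_block = rss(np.hstack([ones, blocks]))
    rss_full = rss(np.hstack([ones, blocks, genos]))
    return rss_mean - rss_block, rss_block - rss_full, rss_full


# -- block effects ---------------------------------------------------------

def test_two_block_symmetry(toy_fieldbook):
    eff = ws.estimate_block_effects(toy_fieldbook, "Y")
    assert eff == {"B1": -2.0, "B2": 2.0}


def test_equal_checks_give_zero_effects():
    df = pd.DataFrame(
        {
            "genotype": ["C1", "C2"] * 2,
            "block": ["B1", "B1", "B2", "B2"],
            "is_check": [True] * 4,
            "Y": [7.0] * 4,
        }
    )
    eff = ws.estimate_block_effects(ws.FieldBook(df), "Y")
    assert all(v == 0.0 for v in eff.values())


def test_block_effects_match_least_squares_oracle(default_sim):
    """Check-based effects equal an LS fit of check data on block indicators."""
    _, fb, _, _ = default_sim
    eff = ws.estimate_block_effects(fb, "GY")
    chk = fb.data[fb.data["is_check"]]
    y = chk["GY"].to_numpy(dtype=float)
    B = pd.get_dummies(chk["block"]).to_numpy(dtype=float)
    G = pd.get_dummies(chk["genotype"]).to_numpy(dtype=float)
    X = np.hstack([np.ones((len(y), 1)), B, G])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    block_cols = beta[1 : 1 + B.shape[1]]
    centred = block_cols - block_cols.mean()
    np.testing.assert_allclose(
        [eff[b] for b in sorted(chk["block"].unique())], centred, atol=1e-9
    )
    assert abs(sum(eff.values())) < 1e-9


def test_missing_check_in_block_named():
    df = pd.DataFrame(
        {
            "genotype": ["C1", "C2", "C1"],
            "block": ["B1", "B1", "B2"],
            "is_check": [True] * 3,
            "Y": [1.0, 2.0, 3.0],
        }
    )
    with pytest.raises(IncompleteDesignError, match="C2.*B2"):
        ws.estimate_block_effects(ws.FieldBook(df), "Y")


# -- adjusted means --------------------------------------------------------

def test_adjusted_mean_hand_values(toy_fieldbook):
    adj = ws.adjust_means(toy_fieldbook, "Y")
    # T1 sits in block B1 (effect -2): 20 - (-2) = 22; T2 in B2: 20 - 2 = 18
    assert adj.value("T1") == pytest.approx(22.0)
    assert adj.value("T2") == pytest.approx(18.0)
    # check C1 replicates {10, 14} -> 12
    assert adj.value("C1") == pytest.approx(12.0)
    chk = adj.table[adj.table["source"] == "check"]
    assert (chk["block_adjustment"] == 0.0).all()


def test_noise_free_recovery_of_true_values(noisefree_sim):
    fb, geno_truth, block_truth = noisefree_sim
    adj = ws.adjust_means(fb, "Y")
    eff = ws.estimate_block_effects(fb, "Y")
    for _, row in geno_truth.iterrows():
        assert adj.value(row["genotype"]) == pytest.approx(row["true_value"], abs=1e-10)
    for _, row in block_truth.iterrows():
        assert eff[row["block"]] == pytest.approx(row["effect"], abs=1e-10)


def test_block_shift_invariance(default_sim):
    """Adding a constant to one block shifts its effect, not test adjusted means."""
    _, fb, _, _ = default_sim
    shifted = fb.data.copy()
    shifted.loc[shifted["block"] == "B2", "GY"] += 5.0
    fb2 = ws.FieldBook(shifted)
    eff1 = ws.estimate_block_effects(fb, "GY")
    eff2 = ws.estimate_block_effects(fb2, "GY")
    assert eff2["B2"] - eff1["B2"] == pytest.approx(5.0 * (1 - 1 / 4))
    adj1 = ws.adjust_means(fb, "GY").series
    adj2 = ws.adjust_means(fb2, "GY").series
    tests = ws.adjust_means(fb, "GY").table.query("source == 'test'")["genotype"]
    # every test genotype shifts by the grand-mean share 5/b, so all
    # test-vs-test comparisons are invariant to the block shift
    shifts = (adj2 - adj1).loc[list(tests)]
    np.testing.assert_allclose(shifts, 5.0 / 4, atol=1e-9)


# -- ANOVA -----------------------------------------------------------------

def test_df_column_study_design(default_sim):
    _, fb, _, _ = default_sim
    an = ws.anova(fb, "GY")
    assert an.df_column == (3, 45, 4, 41, 12)
    assert list(an.rows["source"]) == [
        "Block", "Genotypes", "Check", "Test and Test vs. Check", "Residuals",
    ]


def test_df_additivity_random_designs():
    rng = np.random.default_rng(0)
    for case in range(5):
        b = int(rng.integers(2, 6))
        c = int(rng.integers(2, 6))
        t = int(rng.integers(1, 20))
        spec = ws.SimulationSpec(
            n_blocks=b, checks=[f"C{i}" for i in range(c)], n_tests=t,
            traits={"Y": ws.TraitSim(mean=10.0, error_sd=1.0)}, seed=case,
        )
        fb, _, _ = ws.simulate_fieldbook(spec)
        an = ws.anova(fb, "Y")
        N = b * c + t
        assert an.row("Block")["df"] + an.row("Genotypes")["df"] + an.row("Residuals")["df"] == N - 1
        assert an.row("Check")["df"] + an.row("Test and Test vs. Check")["df"] == an.row("Genotypes")["df"]
        for _, r in an.rows.iterrows():
            if r["df"] > 0 and np.isfinite(r["MS"]):
                assert r["MS"] == pytest.approx(r["SS"] / r["df"])


def test_all_equal_observations_zero_ss():
    df = pd.DataFrame(
        {
            "genotype": ["C1", "C2", "C1", "C2", "T1"],
            "block": ["B1", "B1", "B2", "B2", "B1"],
            "is_check": [True, True, True, True, False],
            "Y": [3.0] * 5,
        }
    )
    an = ws.anova(ws.FieldBook(df), "Y")
    assert (an.rows["SS"].abs() < 1e-12).all()


def test_ss_match_brute_force_least_squares():
    """Sequential LS decomposition agrees with the ANOVA on toy designs."""
    for seed in range(6):
        spec = ws.SimulationSpec(
            n_blocks=2, checks=("C1", "C2"), n_tests=2,
            traits={"Y": ws.TraitSim(mean=10.0, error_sd=1.0)}, seed=seed,
        )
        fb, _, _ = ws.simulate_fieldbook(spec)
        ss_block, ss_geno, ss_resid = ls_decomposition(fb)
        an = ws.anova(fb, "Y")
        assert an.row("Block")["SS"] == pytest.approx(ss_block, abs=1e-8)
        assert an.row("Genotypes")["SS"] == pytest.approx(ss_geno, abs=1e-8)
        assert an.row("Residuals")["SS"] == pytest.approx(ss_resid, abs=1e-8)


def test_ss_match_brute_force_study_scale(default_sim):
    _, fb, _, _ = default_sim
    df = fb.data.rename(columns={"GY": "Y"})[["genotype", "block", "is_check", "Y"]]
    fb2 = ws.FieldBook(df)
    ss_block, ss_geno, ss_resid = ls_decomposition(fb2)
    an = ws.anova(fb2, "Y")
    assert an.row("Block")["SS"] == pytest.approx(ss_block, rel=1e-9)
    assert an.row("Genotypes")["SS"] == pytest.approx(ss_geno, rel=1e-9)
    assert an.row("Residuals")["SS"] == pytest.approx(ss_resid, rel=1e-9)


def test_noise_free_f_infinite(noisefree_sim):
    fb, _, _ = noisefree_sim
    an = ws.anova(fb, "Y")
    assert math.isinf(an.row("Genotypes")["F"])
    assert an.row("Genotypes")["p"] == 0.0


def test_null_pvalues_uniform():
    """With zero genotype effects the Genotypes-row p-value is Uniform(0,1)."""
    pvals = []
    seeds = np.random.default_rng(12345).integers(0, 2**31 - 1, size=500)
    for s in seeds:
        spec = ws.SimulationSpec(
            n_blocks=3, checks=("C1", "C2", "C3"), n_tests=6,
            traits={"Y": ws.TraitSim(mean=10.0, error_sd=1.0, genotype_effects={})},
            seed=int(s),
        )
        fb, _, _ = ws.simulate_fieldbook(spec)
        pvals.append(float(ws.anova(fb, "Y").row("Genotypes")["p"]))
    stat = stats.kstest(pvals, "uniform")
    assert stat.pvalue > 0.01


def test_design_too_small_rejected():
    df = pd.DataFrame(
        {
            "genotype": ["C1", "C1", "T1"],
            "block": ["B1", "B2", "B1"],
            "is_check": [True, True, False],
            "Y": [1.0, 2.0, 3.0],
        }
    )
    with pytest.raises(DesignViolationError):
        ws.anova(ws.FieldBook(df), "Y")


# -- comparison errors -----------------------------------------------------

def test_comparison_error_formulas(default_sim):
    _, fb, _, _ = default_sim
    an = ws.anova(fb, "GY")
    ce = comparison_errors(an, alpha=0.05)
    mse, b, c = an.mse, 4, 5
    assert ce.se_check_vs_check == pytest.approx(math.sqrt(2 * mse / b))
    assert ce.se_test_same_block == pytest.approx(math.sqrt(2 * mse))
    assert ce.se_test_diff_block == pytest.approx(math.sqrt(2 * mse * (1 + 1 / c)))
    assert ce.se_test_vs_check == pytest.approx(
        math.sqrt(mse * (1 + 1 / b + 1 / c + 1 / (b * c)))
    )
    assert ce.se_test_diff_block >= ce.se_test_same_block
    # CD widens as alpha shrinks
    ce_wide = comparison_errors(an, alpha=0.32)
    assert ce.cd_test_same_block > ce_wide.cd_test_same_block


def test_comparison_errors_unit_mse_hand_value(default_sim):
    _, fb, _, _ = default_sim
    an = ws.anova(fb, "GY")
    # scale observations so that MSE needs not be unity; use formula directly
    ce = comparison_errors(an)
    assert ce.mse == pytest.approx(an.mse)


def test_significance_stars():
    assert significance_stars(0.003) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.3) == "ns"
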