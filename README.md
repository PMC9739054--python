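# wheatscreen

Screening pipeline for evaluating wheat genotypes under terminal drought
and heat stress. It implements the computational chain used when a large,
mostly unreplicated germplasm panel (46 genotypes: 5 replicated checks ×
4 blocks + 41 tests grown once) is scored for tolerance:

- **Augmented-RCBD analysis** — block effects estimated from replicated
  checks, adjusted genotype means, the five-source ANOVA
  (Block / Genotypes / Check / Test-and-Test-vs-Check / Residuals) and the
  four comparison standard errors.
- **Genetic variability** — variance components (PV = GV + EV),
  genotypic/phenotypic/environmental coefficients of variation with
  low/medium/high categories, broad-sense heritability h² = GV/PV,
  genetic advance GA = k·√PV·h² at selection intensity k = 2.063, and GAM.
- **Physiological indices** — excised-leaf water loss, relative water
  content, Fv/Fm, relative cell-membrane injury, flag-leaf senescence
  rate, growing-degree-day phyllochron and early vigour, harvest index
  and spike fertility.
- **Thermal imaging** — canopy segmentation from temperature grids,
  empirical wet/dry reference temperatures from the canopy pixel tails,
  and CWSI = (T_c−T_wet)/(T_dry−T_wet), Ig = (T_dry−T_c)/(T_c−T_wet),
  CTD = T_a−T_c.
- **Multivariate screening** — standardized genotype-by-trait matrix,
  correlation-matrix PCA (optional varimax), significance-masked Pearson
  correlations, Ward clustering, and a direction-aware composite rank-sum
  classification into top/intermediate/low performers.
- **Synthetic data** — a generator that emulates the trial design and its
  published signal-to-noise operating point with ground truth returned
  alongside, so every estimator is tested as estimate-vs-truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import wheatscreen as ws

# simulate the study design: 4 blocks, 5 checks, 41 tests
fb, truth, blocks = ws.simulate_fieldbook(ws.SimulationSpec(seed=1))

an = ws.anova(fb, "GY")
print(an.df_column)            # (3, 45, 4, 41, 12)
print(round(an.mse, 4))        # 0.0182

rep = ws.variability_report(fb, ["GY"])
print(rep[["trait", "GCV", "gcv_category", "h2", "GA", "GAM"]].round(2))
#   trait    GCV gcv_category    h2    GA    GAM
# 0    GY  27.77         high  0.99  2.27  56.86

# water-stress indices from printed canopy temperatures
print(round(ws.cwsi(t_c=24.13, t_wet=22.98, t_dry=24.97), 2))   # 0.58
```

The df column is the augmented-design partition of the 61 plots; the MSE
comes from the check-only two-way residual on 12 df. GCV ≈ 28% with
h² ≈ 0.99 marks grain yield as highly heritable and highly variable in
this panel, and GAM ≈ 57% says one round of 5% selection is expected to
shift the mean by about 57% of itself. The CWSI of 0.58 places that plant
a bit past midway between its fully transpiring (wet) and fully stressed
(dry) reference temperatures.

The `analysis/` scripts run the same pipeline as a narrative — simulate,
design analysis, variability, physiological indices, thermal indices,
multivariate screening — writing their tables under `results/`. A thin
CLI mirrors the stages: `wheatscreen simulate | anova | adjust |
variability | indices | thermal | multivariate | rank`.

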