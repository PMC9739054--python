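# Methods

## The screening problem

Breeding programmes screen diverse wheat germplasm for terminal drought and
heat tolerance by growing many genotypes once each, because seed and space
are scarce, alongside a few replicated check cultivars. This package
implements the full computational chain for such a screen: the augmented
randomized complete block design (RCBD) analysis that makes unreplicated
genotypes comparable, the genetic-variability statistics used to judge
whether selection on a trait is worthwhile, the morpho-physiological index
formulas recorded in such trials, water-stress indices from canopy thermal
images, and a multivariate layer (PCA, correlations, clustering, composite
ranking) that turns the trait table into a tolerance classification.

## Augmented design model

The trial has b blocks, c check genotypes replicated once per block and t
test genotypes grown exactly once (default study layout: b = 4, c = 5,
t = 41, N = 61 plots). The observation model is additive,

    y_ij = mu + g_i + b_j + e_ij,  e_ij ~ N(0, sigma_e^2).

Replicated checks identify the block effects: the effect of block j is the
mean of its checks minus the grand check mean, so effects sum to zero. A
test genotype's adjusted mean is its single observation minus its block's
effect; a check's adjusted mean is its plain mean over blocks. Adding a
constant to one block moves every test adjusted mean by the constant over
b, so all test-vs-test comparisons are invariant to block shifts.

The ANOVA partitions N − 1 df as Block (b−1, ignoring treatments),
Genotypes adjusted for blocks (c+t−1, split into Check c−1 and a combined
Test and Test-vs-Check row with t df), and Residual ((b−1)(c−1), the
check-only two-way interaction, which coincides with the full
least-squares residual because every test observation is fit exactly).
Sums of squares are computed sequentially (mean → blocks → genotypes), so
they agree with a brute-force least-squares decomposition; the
block-eliminating / genotype-ignoring dual and the test/test-vs-check
split are retained in a verbose field because published tables print only
the combined convention. F statistics test each mean square against the
residual; with noise-free data the residual SS is snapped to exactly zero
(tolerance 1e−12 relative to the total SS) so F is reported as infinite
rather than as float dust.

Standard errors for the four comparison classes follow the classical
augmented-design formulas: check−check √(2·MSE/b), tests in the same block
√(2·MSE), tests in different blocks √(2·MSE·(1+1/c)), test−check
√(MSE·(1+1/b+1/c+1/(bc))); critical differences multiply by the two-sided
t quantile at the residual df.

## Variance components and genetic advance

EV is the residual mean square. PV is the sample variance of the adjusted
genotype means (checks counted once) and GV = PV − EV, truncated at zero
with a logged diagnostic, so PV = GV + EV holds exactly by construction.
The alternative textbook estimator GV = adjusted-Genotypes-MS − EV is
available behind `estimator="mean_square"` but is not the default: checks
enter the genotype sum of squares with b replicates, which inflates that
mean square, and in simulation at the study's design the MS-based GV
overshoots the generating genotype-effect variance by roughly 20% while
the adjusted-means estimator is within a few percent.

Derived statistics, all on the adjusted-means trait mean: coefficients of
variation XCV = 100·√XV/mean for X ∈ {G, P, E}; broad-sense heritability
h² = GV/PV; genetic advance GA = k·√PV·h² with k = 2.063 (the standardized
selection differential at 5% selection, configurable); GAM = 100·GA/mean.
CV and GAM categories are low below 10%, medium from 10 to below 20%, high
from 20% up, with boundary values assigned upward.

## Physiological indices

All formulas are direct per-sample computations (percent scales):

- ELWL over 0–4 h, 4–8 h, 0–8 h: interval weight loss per unit initial
  water content; the three satisfy the mass balance
  ELWL_0–8·(FW0−DW) = ELWL_0–4·(FW0−DW) + ELWL_4–8·(FW4−DW).
- RWC = 100·(FW−DW)/(TW−DW); Fv/Fm = (Fm−Fo)/Fm.
- RCI = 100·(1 − (1−T1/T2)/(1−C1/C2)), the standard relative-injury form
  for paired control/heat-treated conductivity readings.
- FLSm = 100·(1 − SPAD_m/SPAD_a)/days, the endpoint senescence rate in
  percent relative greenness per day; the genotype-specific day span is a
  required input, never inferred.
- Phyllochron intervals are sowing-anchored cumulative growing degree
  days, daily GDD = max(0, (t_max+t_min)/2 − base) with base 0 °C (the
  wheat convention; configurable). The early-vigour composite divides the
  summed area of leaves 1–3 by the thermal time to third-leaf emergence;
  the components are always stored because the composite definition is a
  design choice.
- HI = 100·GY/AGDM; spike fertility is reported as grains per 100
  spikelets (×100 scale), matching how screening tables print values like
  81.21.

Degenerate denominators raise errors; out-of-range but computable values
(e.g. Fv/Fm with Fo ≥ Fm) are returned with a logged warning, never
clamped.

## Thermal imaging

Canopy segmentation runs two-means on the 1-D pixel temperature
distribution and takes the cooler cluster as canopy (transpiring leaves
sit below the warmer background). The split must be genuinely bimodal:
the between-centre gap must exceed 4× the pooled within-cluster sd,
a threshold chosen between the ratio a single Gaussian mode produces
(≈2.6) and the ≥8 produced by a leaf-to-background gap of a few °C at
realistic pixel noise; unimodal images fail rather than being cut
arbitrarily. A provided external mask bypasses segmentation.

Wet and dry reference temperatures are symmetric tail means of the canopy
pixels — the coolest and hottest ⌈tail·n⌉ pixels, default tail 5% — a
frequency-analysis realization of empirical references. Then T_c is the
mean canopy temperature and

    CWSI = (T_c − T_wet)/(T_dry − T_wet),
    Ig   = (T_dry − T_c)/(T_c − T_wet) = (1 − CWSI)/CWSI,
    CTD  = T_a − T_c.

Values are never clipped: with externally supplied references T_c can fall
outside [T_wet, T_dry], and the summary then carries the out-of-range
value plus a flag, because silent clipping would distort exactly the
inconsistent rows one wants to notice. Per-genotype summaries average
per-image indices, not per-image temperatures, since averaging order
changes ratio indices.

A limitation worth knowing: when references come from the image's own
canopy distribution and that distribution is symmetric (as in the
synthetic generator), CWSI centres near 0.5 regardless of absolute canopy
temperature — discrimination between plants then flows through T_c and
CTD. Real canopies with genuinely water-stressed and unstressed leaf area
spread their tails asymmetrically, which is what the index exploits.

## Multivariate screening

Adjusted means are assembled into a genotypes × traits matrix and
z-standardized per column (n−1 sd; zero-variance columns are an error,
missing cells fail unless column-mean imputation is enabled). PCA is the
eigen-decomposition of the trait correlation matrix; loadings are
eigenvectors scaled by √eigenvalue (trait–component correlations), so
eigenvalues sum to the number of traits and squared loadings per trait sum
to one over all components; scores are the standardized data projected on
the eigenvectors, and squared cosines are per-entity shares of squared
distance across components. Component signs are fixed deterministically
(largest-|loading| entry positive). Varimax rotation of the retained
loading block (via statsmodels) is available behind a flag and preserves
the retained sum of squared loadings; unrotated PCA is the default because
the upstream R packages default to it even where published tables say
"rotated".

Correlations are pairwise Pearson r with two-sided t-test p-values and a
significance mask at alpha (no multiple-testing correction by default, an
optional Holm flag exists). Clustering is agglomerative on Euclidean
distances of the standardized rows, Ward linkage by default. Ranking
orients each trait by its registered direction (rank 1 most favourable,
average ranks for ties), combines per-trait ranks into a weighted mean
(equal weights default) and classifies the best 10 as top and worst 5 as
low, mirroring the screening-table convention; the published ranking
criteria are not defined anywhere, so this rank-sum is one defensible
realization and is labelled as such.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design verbatim (4 blocks, 5 checks
replicated per block, 41 tests once each, round-robin block assignment —
position within block never enters the model) with additive Gaussian
effects. Default trait means and effect variances are back-derived from
the published per-trait genotypic variances and coefficients of variation
(mean = 100·√GV/GCV, e.g. grain yield ≈ 3.97 g, error sd √0.02), so
simulations sit at the study's signal-to-noise operating point. Thermal
images are a centred elliptical canopy of Normal pixels over a warmer
background with 0.1 °C jitter; senescence series decline linearly in
relative greenness. Ground truth is always returned next to the data.

What passing tests therefore show: the estimators recover known additive
effects, variance components and canopy statistics under Gaussian
assumptions at realistic effect sizes. What they do not show: robustness
to spatial field trends, non-Gaussian errors, genotype×block interaction,
occlusion/mixed pixels in real thermography, or nonlinear senescence —
none of which the generator produces.

## Problem sizes and numerical choices

Parameter-recovery suites use 200 replicates of the full 61-plot design
(GV bias, null p-value uniformity via Kolmogorov–Smirnov at the 1% level)
and 500 replicates of a 15-plot design for the module-level uniformity
property; oracle-equivalence checks run on 2-block/2-check/2-test toys at
1e−8 and on 10×6 random matrices for PCA. Derandomized seeds are drawn
from fixed parent generators. Segmentation accuracy is measured over 50
seeded images at a 3 °C offset and 0.3 °C canopy noise (≥99% pixel
agreement with the ground-truth mask). Published worked examples (genetic
advance from printed variance pairs, CWSI from printed temperatures) are
checked at the tables' two-decimal printing precision; recomputed PCV from
two-decimal inputs is checked at ±0.05 because the printed inputs are
themselves rounded.
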