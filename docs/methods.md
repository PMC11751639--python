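# Methods

`octphen` re-creates, end to end and on synthetic data, a self-supervised
phenotyping study of macular OCT volume scans: thickness-map extraction,
autoencoder embedding, imaging-GWAS with multi-trait meta-analysis and
conditional locus refinement, inversion genotyping from tagging alleles, and
embedding-based survival modeling.  This note records the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic validation does and does not establish about real data.

## Synthetic data model

**Morphology.** Retinal thickness over the scanned area is a smooth field:
a per-subject mean (`mean_thickness`, px), a Gaussian foveal pit
(`pit_depth`, `pit_width`), a linear temporal–nasal gradient (`tilt`,
px/column), and a per-subject "texture" field — a sum of random Gaussian
bumps — standing in for idiosyncratic retinal topography.  The texture term
matters: without it a cohort of maps would span only the four named degrees
of freedom and any autoencoder bottleneck of size ≥ 4 would saturate, making
bottleneck-size comparisons meaningless.  With 24 bumps per subject the map
ensemble has intrinsic dimension well above 128, so reconstruction error
falls as the bottleneck widens, which is the qualitative behaviour the
pipeline is designed to measure.

Defaults emulate a macular cohort at full scan scale (650-row B-scans):
mean thickness 220 px with 15 px between-subject SD, 60-px pit with sigma
12 % of scan width, speckle SD 0.05 on the [0, 1] intensity scale.  Length
parameters scale linearly with image height, so desk-scale geometries keep
the same relative anatomy.

**Rendering.** Each B-scan is three constant intensity bands (vitreous 0.05,
retina 0.75, deeper tissue 0.25) between two smooth surfaces, plus additive
Gaussian speckle, clipped to [0, 1].  A pixel row `r` is retina iff
`upper <= r < lower` (half-open).  This convention makes the mask-row count
an unbiased estimator of the continuous thickness `lower − upper`; an
inclusive band would bias every column by +1 px and sub-pixel agreement with
the closed-form field would be unattainable.  No attempt is made at
layer-level realism, pathology, or physical speckle statistics: only the two
outer boundaries are ever segmented.

**Genotypes.** Haplotypes come from per-block AR(1) latent Gaussians
thresholded at the allele-frequency quantile: Hardy–Weinberg holds by
construction, LD decays geometrically with variant distance (`ld_decay` is
the per-adjacent-pair latent correlation), and blocks are independent.
Causal variants add to a morphology field under additive (dosage), dominant
(carrier) or recessive (homozygote) coding.  The structural inversion is a
latent biallelic haplotype (default frequency 0.22, the European-like
estimate) tracked by tag variants that copy the inversion allele with
probability `sqrt(r²)` per haplotype, which yields exactly the requested
haplotype r².

**Covariates and outcomes.** Age, sex, height, weight, refraction and 20
simulated genetic PCs (standard normals — the simulated cohort has no
population structure, so PCs are placeholders with the correct interface).
Disease outcomes are exponential-hazard times with a log-linear predictor on
standardized morphology fields, censored uniformly on a 10-year window; this
is the simplest model under which the Cox estimands are known exactly.

All randomness flows from one master seed through named substreams
(`covariates`, `genotypes`, `inversion`, `morphology`, `texture`,
`outcomes`, `render:<i>`), so any stage can be regenerated independently and
runs are bit-reproducible.

## Thickness mapping

B-scans are cropped symmetrically to a square (650×512 → 512×512 removes 69
rows from each edge; an odd remainder takes the extra row from the bottom).
Two segmenters share one contract:

* the **deterministic oracle** smooths each column (Gaussian, sigma 1.5 px),
  finds the strongest positive and negative vertical-gradient peaks, refines
  each peak to sub-pixel precision by a local centroid, and converts the two
  edge positions to mask rows.  The centroid step is what keeps the oracle
  within 1 px of the true boundary at every column of a noise-free scan:
  raw threshold crossings sit systematically half a pixel to one pixel
  outside the band.  Columns without sufficient gradient contrast are
  flagged, never failed.
* the **U-Net** (contracting/expansive paths with skip connections, double
  3×3 convolutions, 2× max-pool/upsample, BCE loss, Adam, 50 epochs) is
  trained on labeled pairs and post-processed per column to the longest
  vertical run, which removes speckle islands.  The default architecture is
  depth 4 with 16 base channels; validation runs use depth 3 with 8 base
  channels at 64×64, where held-out boundary error is well under 2 px.

Thickness is the inclusive mask-row count (`lower − upper + 1`), so a 1-px
mask has thickness 1.  Flagged cells are interpolated bilinearly (nearest at
edges); a map with more than 20 % flagged cells is rejected, mirroring
image-quality exclusions.  Map orientation is fixed: row = B-scan index,
column = A-scan position, row 0 of each B-scan superior.

The neural-network layers themselves (convolution via im2col, pooling,
upsampling, dense, Adam) are a small self-contained numpy engine with
hand-written backprop, verified against finite-difference gradients in the
test suite.  Training at the package's working resolutions takes minutes on
one CPU core.

## Latent phenotyping

Maps are area-averaged to a square working resolution (default 64×64;
validation uses 32×32) and scaled to [0, 1] by a factor fitted on the
training split only.  The autoencoder is conventional: conv/pool encoder,
dense bottleneck (16–128 latent units; 64 is the study default), mirrored
decoder with nearest-neighbour upsampling, sigmoid output, MSE loss, 150
epochs by default with a seeded subject-level 2500/500 train/test split.
Embeddings for **all** subjects are extracted with the final-epoch weights —
the training subset exists only to fit the compressor.  PCA of the embedding
matrix (first 25 components) provides the alternative trait set.

Before association testing every trait column is rank-based
inverse-normal transformed with the Blom offset,
`Phi^{-1}((rank − 3/8)/(n + 1/4))`, average ranks at ties, missing values
passed through; an all-constant column is an error since its ranks are
undefined.  The Blom variant is the GWAS-standard choice.

## Genetic association

**QC.** MAF ≥ 5 %, Hardy–Weinberg exact-test P > 1e-15, call rate > 99 %,
optional region exclusions.  The HWE test is the exact conditional test on
the heterozygote count (log-space recurrence, so it is stable at n in the
hundreds of thousands); continuous dosages are rounded to genotype classes
for the test only.

**GWAS.** Per variant, OLS of the normalized trait on dosage plus all
covariates (age, sex, height, weight, refraction, genetic PCs; intercept
always included).  The implementation residualizes trait and dosages against
an orthonormal covariate basis (Frisch–Waugh), so a 10⁴-variant screen is a
single matrix product.  P-values are two-sided normal on beta/se — at the
sample sizes involved the t correction is negligible — and −log10 p is
carried alongside so planted strong effects never underflow.  Missing
dosages are handled per-variant complete-case.  Collinear covariates are
dropped with a warning.  A two-step whole-genome-ridge association model is
deliberately not reproduced: the simulated cohorts contain no relatedness,
so the single-step OLS estimand coincides.

**Genomic inflation.** `lambda = median(chi²) / qchisq(0.5, 1)`.

**Genetic correlation.** Pearson r of aligned effect sizes over variants
significant in either trait; allele flips negate betas before correlating;
fewer than 3 shared variants yields NaN with a warning.

**Multi-trait meta-analysis.** Traits are grouped by connected components of
the |r| > 0.9 genetic-correlation graph.  Within a group with effect
correlation matrix ρ and null z-score correlation Σ (estimated from variants
with all |z| < 1.96; identity fallback below 30 such variants), the updated
target z is the GLS combination `z_new = wᵀz / sqrt(wᵀΣw)` with
`w = Σ⁻¹ρ_t`.  A singleton group is the identity.  This is a deliberate
simplification of the published moment estimator — the acceptance surface is
an independent brute-force GLS on the same arrays, not external software.
Under the null the combination provably preserves type-I error, which the
suite checks.

**Conditional selection.** Stepwise forward selection in z-space against an
LD reference: at each step the variant with the largest conditional |z| is
added if its conditional p beats the threshold, where
`z_j|S = (z_j − r_jS R_SS⁻¹ z_S) / sqrt(1 − r_jS R_SS⁻¹ r_Sj)`.
Variants on different chromosomes or more than 10 Mb apart are treated as
unlinked; candidates with |r| > 0.9 to a selected variant are skipped
(collinearity guard).  Joint effects rescale marginal betas to the
standardized-genotype scale, solve against `R_SS`, and rescale back, so with
zero LD the joint model reduces exactly to the marginal one.  Selected
leads within 1 Mb on a chromosome merge into one locus.  On raw-genotype
blocks of ≤ 20 variants the conditional p-values track exact multivariable
regression to within 10 % on the log scale.

**Thresholds.** Computed, never hard-coded: genome-wide 5e-8; study-wide =
5e-8 / n_analyses (64 embeddings + 64 meta-analysed + 25 PCs = 153 →
3.27e-10); replication = family alpha / n_discovery_loci (0.01 / 118 =
8.47e-5).  Both two-significant-figure renderings (rounded and truncated)
are exposed because published reports mix the two conventions for these
numbers.

**Replication.** Effect sizes at discovery lead variants are compared
against an independent subject split; strand-ambiguous (A/T, C/G) variants
are dropped before alignment; output is the beta–beta table, Pearson r, sign
agreement and its binomial test against 0.5.

## Phenotype epidemiology

Direct embedding correlations are clustered (average linkage on 1 − |r|)
and the leaf order is applied to both the direct and the genetic matrix, so
discrepancies between the two are visible block by block.  PheWAS is
maximum-likelihood logistic regression of each 3-character diagnosis
category on the predictor plus age, sex, height and weight, restricted to
codes with more than `min_cases` cases; the case floor scales with cohort
size (1000 cases per 85 000 subjects) so desk-scale cohorts exercise the
inclusion rule.  Additive, dominant and recessive predictor codings are
supported; separation or non-convergence falls back to an L2-penalized fit
and is flagged.

Dominance difference maps compare per-pixel mean thickness across genotype
classes.  The significance mask keeps pixels where |hom − ref| exceeds the
95th percentile of a 200-permutation null (labels permuted, seeded), and the
dominance index `d = Σ diff_het / Σ diff_hom` is computed over that mask —
a scalar ratio is far more stable than per-pixel ratios, and the per-pixel
maps are still emitted.  d ≈ 0.5 marks additive effects, ≈ 0 recessive,
≈ 1 dominant; it is undefined (NaN) when a genotype class is smaller than 20
subjects or the hom signal vanishes.

Inversion genotypes are called from the per-subject mean alternative-allele
dosage over the tag variants by 1-D k-means with centers initialized at
0/1/2 and ties assigned to the lower class; fewer than three occupied
classes triggers fixed 0.5/1.5 thresholds with a warning.  At tag r² = 0.9
and inversion frequency 0.22 (n = 2000) the caller is > 95 % accurate and
the frequency estimate is within ±0.02.

## Survival modeling

Penalized Cox proportional hazards with elastic-net mixing, Breslow ties
(scikit-survival backend; the convex problem makes fits deterministic).
The study's single stated hyperparameter, penalty strength 0.1, is treated
as the overall λ with mixing α = 0.5 by default — the mixing ratio is
exposed in config since only the overall strength is pinned down.  Penalty
0 falls back to the unpenalized Breslow model.  Harrell's C counts
comparable pairs (the earlier time is an event) with half-credit ties; it is
verified against exhaustive pair enumeration for every censoring pattern up
to n = 50.  Cross-validation is 20 repetitions of 5 folds stratified on
(sex, event), standardization fitted on training folds only; folds without
events or comparable pairs are skipped with a record.  High-risk cohorts are
the top quartile of the fitted linear predictor within each sex;
Kaplan–Meier curves come from lifelines.

## Validation scale and what it shows

Desk-scale problem sizes are used throughout validation: 64×64 to 96×64
B-scans, 8–64 slices per volume, cohorts of 60–2000 subjects, 10⁴ null
variants, 100 U-Net training pairs at 50 epochs, autoencoder comparisons at
32×32 input with 256/64 splits and 25 epochs.  These sizes preserve every
qualitative contract of the full-scale study (sub-pixel thickness fidelity,
bottleneck-size ordering of reconstruction error, calibrated type-I error,
λ ≈ 1 under the null, > 90 % recovery of planted common effects, inversion
caller accuracy, dominance-index separation of additive from recessive
effects, null-band cross-validated concordance) while completing in minutes
on one CPU core.

What passing does **not** show: realism of speckle or pathology, behaviour
under population structure or relatedness (the generator plants none; PCs
are simulated), imputation uncertainty, X-chromosome effects, or the
absolute effect sizes and locus counts of any real cohort.  Recovery of a
planted effect says the estimator is consistent and calibrated under the
generator's assumptions, nothing more.

## Known limitations

* The GLS multi-trait combination and the z-space conditional selection are
  documented simplifications of the corresponding published estimators;
  their oracles are exact in-package computations, not the external tools.
* The conditional-selection joint SEs use `se_joint = se · sqrt(diag(R⁻¹))`,
  which ignores the (small) change in residual variance from conditioning.
* Logistic PheWAS uses an L2 fallback rather than a Firth correction for
  separated fits; flagged rows should be treated as qualitative.
* The numpy NN engine is single-threaded and intentionally minimal; it is
  not suitable for full 650×512×128 volumes, which is why working
  resolutions are configurable.
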