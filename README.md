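# octphen

Self-supervised phenotyping of retinal OCT volume scans, end to end:

1. **Thickness mapping** — segment the inner limiting membrane and Bruch's
   membrane in each B-scan (a deterministic gradient oracle or a trainable
   U-Net), measure per-column thickness, and stack the 128 slices of a
   volume into one thickness map per eye.
2. **Latent phenotyping** — compress thickness maps with a convolutional
   autoencoder to a k-dimensional embedding per subject (k = 64 by default;
   16–128 supported for bottleneck comparison), PCA of the embeddings, and
   rank-based inverse-normal transformation of every trait.
3. **Genetic association** — variant QC (MAF ≥ 5 %, exact Hardy–Weinberg,
   call rate), covariate-adjusted linear GWAS per trait, genomic inflation
   λ, effect-size genetic correlation, a GLS multi-trait meta-analysis over
   correlated embeddings, stepwise conditional selection of independent lead
   variants against an LD reference, Bonferroni significance regimes, and
   discovery/replication beta–beta concordance.
4. **Phenotype epidemiology** — embedding correlation structure with
   hierarchical clustering, logistic PheWAS against ICD10-style disease
   codes, genotype-stratified thickness difference maps with a dominance
   index, and genotyping of a structural inversion from tagging-allele
   patterns.
5. **Risk modeling** — Cox elastic net on embeddings, cross-validated
   Harrell's C, Kaplan–Meier stratification of high-risk cohorts.

Real OCT-plus-genotype cohorts are access-restricted, so the package ships a
first-class synthetic-data generator (`octphen.simulate`) producing OCT-like
volumes with known boundary surfaces, LD-structured genotypes with planted
additive/dominant/recessive effects, covariates, and proportional-hazards
disease outcomes — every pipeline stage is validated against this ground
truth. It is aimed at methodologists in imaging genetics who want a tested,
seedable reference implementation of this analysis pattern.

## The statistics at the core

For a normalized trait y (inverse-rank-normal:
`y_i = Φ⁻¹((rank_i − 3/8)/(n + 1/4))`) and dosage g, the per-variant model is
OLS of y on g plus covariates; λ = median(χ²)/χ²₀.₅(1). Genetically
correlated traits (|r| > 0.9, connected components) are meta-analysed by GLS:
with effect correlation ρ and null z-score correlation Σ,

    z_new = wᵀz / √(wᵀΣw),   w = Σ⁻¹ρ_t .

Independent lead variants are chosen stepwise; conditional on a selected set
S with LD matrix R,

    z_j|S = (z_j − r_jS R_SS⁻¹ z_S) / √(1 − r_jS R_SS⁻¹ r_Sj) ,

with variants on different chromosomes or > 10 Mb apart treated as unlinked.
The dominance index of a variant's effect on thickness is
d = Σ(het − ref)/Σ(hom − ref) over a permutation-masked region (≈ 0.5
additive, ≈ 0 recessive, ≈ 1 dominant). Survival uses the Breslow partial
likelihood with penalty λ(α‖β‖₁ + (1−α)/2‖β‖₂²), λ = 0.1, and Harrell's
C = (concordant + ½ tied)/comparable. See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from octphen.simulate import (ScanGeometry, SimConfig, BlockSpec, CausalSpec,
                              simulate_cohort, thickness_field)
from octphen.thickness import oracle_segment, thickness_profile, assemble_map
from octphen.assoc import gwas_linear, genomic_lambda

g = ScanGeometry(n_slices=24, n_rows=96, n_cols=64)
cfg = SimConfig(geometry=g, noise_sd=0.02,
                blocks=[BlockSpec(50, maf=0.3, ld_decay=0.5)],
                causal_map=[CausalSpec(10, "mean_thickness", 5.0, "additive")])
coh = simulate_cohort(400, 50, seed=7, config=cfg, render_volumes=True)

# volume -> thickness map, checked against the generator's closed form
vol = coh.volumes[0]
profiles = [thickness_profile(oracle_segment(vol.slices[i])) for i in range(g.n_slices)]
tmap = assemble_map(profiles)
truth = thickness_field(coh.params[0], g)
print(f"map MAE vs closed form: {np.abs(tmap.map - truth).mean():.3f} px")

# GWAS of ground-truth mean thickness on the planted variant
ss = gwas_linear(coh.morphology["mean_thickness"].to_numpy(), coh.genotypes, None)
hit = ss.df.iloc[10]
print(f"planted variant: beta={hit.beta:.2f} (truth 5.0), -log10 p={hit.neglog10_p:.1f}")
```

Output (seed 7):

```
map MAE vs closed form: 0.335 px
planted variant: beta=5.00 (truth 5.0), -log10 p=158.8
```

The assembled map tracks the analytic thickness field to about a quarter of
a pixel, and the regression recovers the planted 5-px-per-allele effect with
overwhelming significance.

The same flow is available from the shell:

```bash
octphen run-all --config config.yaml --seed 7 --out runs/demo
```

which executes simulate → segment → embed → gwas → mtag → cojo → replicate
→ phewas → dominance → survive, resuming from existing artifacts on rerun.

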