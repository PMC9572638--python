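# Methods note

This note records the statistical models implemented in `metstab`, the
defaults of the synthetic trial generator and why they were chosen, what
the generator does and does not emulate, and the numerical conventions
the implementation relies on. Every number quoted here is computed by
code in this repository.

## 1. Linear model and ANOVA

Observations are modelled as a balanced fixed-effects factorial

Y = μ + (factor main effects) + (all interactions) + ε, ε ~ N(0, σ²e),

with genotype, water regime and harvest as factors. Sums of squares are
computed from marginal means by inclusion–exclusion over factor subsets;
in a balanced layout this is exact and order-independent (equivalently,
Type-I = Type-II = Type-III). Unequal cell counts raise
`UnbalancedDataError` rather than silently changing the estimand. F
statistics test each term against the residual mean square.

Mean separation uses the least significant difference
LSD = t(1−α/2, df_e)·√(2·MS_e/n) with a compact letter display built by
the insert-and-absorb algorithm on descending means. The coefficient of
variation is CV% = 100·√MS_e / x̄. Homogeneity of variances between
regimes is checked with Bartlett's test (`scipy.stats.bartlett`), with a
guard raising `ContractError` for zero-variance groups.

## 2. Variance components, GCV/PCV, heritability

From the one-regime genotype (× harvest) ANOVA with r effective
replicates per genotype:

- σ²e = MS_residual
- σ²g = (MS_genotype − MS_residual)/r, truncated at 0; truncation is
  flagged (`truncated=True`) rather than hidden.
- σ²p = σ²g + σ²e (plot basis; no interaction variance enters σ²p).

GCV = 100·√σ²g/x̄, PCV = 100·√σ²p/x̄, H² = 100·σ²g/σ²p. When a regime has
exactly one replicate per genotype × harvest cell the residual has zero
degrees of freedom, so the genotype × harvest mean square is pooled into
the residual; this biases H² conservatively when real interaction is
present, and is reported as-is.

## 3. Drought indices and tolerance classification

- WUE = total dry weight per plant / irrigation volume per plant.
- STI = (Yp·Ys)/X̄p², where Yp and Ys are a genotype's mean yields under
  the well-watered and stressed regimes and X̄p is the well-watered grand
  mean. STI rankings are invariant to a common rescaling of all yields.

Classification z-scores {STI, WUE, TDW} per feature (population standard
deviation), builds an average-linkage tree under Manhattan (cityblock)
distance, and cuts it into k = 3 clusters. Cluster labels
(`highly_tolerant`, `moderately_tolerant`, `susceptible`) are assigned by
descending cluster-mean STI. Degenerate inputs (all genotypes identical)
warn and return a zero-height tree. Trees export to Newick.

## 4. AMMI and stability indices

The genotype × environment cell-mean matrix is double-centred and
decomposed by SVD: Y_ij = μ + g_i + e_j + Σ_k λ_k α_ik γ_jk + ρ_ij. With
replication r, SS_G = r·m·Σg², SS_E = r·n·Σe², SS_GEI = r·Σλ²_k, and each
interaction axis carries SS_IPCk = r·λ²_k on n+m−1−2k degrees of freedom;
unfitted axes accumulate into a GEI-residual row. The full-rank fit
reconstructs the cell means exactly (checked to 1e-8).

ASV = √[((SS_IPC1/SS_IPC2)·IPC1_i)² + IPC2_i²] on symmetric-scaled scores
α_ik·√λ_k; SS_IPC2 = 0 raises `ContractError` instead of dividing by
zero. YSI_i = rank(ASV_i, ascending) + rank(yield_i, descending), average
ties; lower is better on both axes.

## 5. Synthetic trial generator

`generate_met` draws genotype, harvest and replicate effects as centred
Gaussians (exactly sum-zero), and builds the genotype × harvest
interaction from QR-orthonormalised centred Gaussian score vectors so the
planted structure is exactly the AMMI decomposition: singular values
decay as λ_k = interaction_sd·√(nm)/(k+1). `generate_paired_stress_trial`
couples a wet and a stressed trial: each stressed cell expectation is the
wet expectation times a regime multiplier, and a seeded random tolerant
subpopulation suffers only a fraction of the yield penalty (effective
multiplier 1 − (1−m)·penalty_fraction). `generate_feed_quality` draws one
multivariate-normal quality vector (CP, NDF, ADF, ADL, IVOMD, Me) per
genotype from a block-structured correlation matrix (fibre block,
digestibility block, negative cross-block correlation), checked for
positive semi-definiteness before sampling.

### Defaults and rationale

| parameter | default | rationale |
| --- | --- | --- |
| n_genotypes / n_harvests / n_replicates | 84 / 6 / 2 | the panel size and staged-harvest design of the large forage screening trials this emulates |
| grand_mean | 10 | per-harvest dry weight on a convenient unit scale |
| sigma2_g / sigma2_e | 4 / 1 | plants a true plot-basis H² of 80%, typical of dry-weight traits in wide forage panels, and recoverable by the moment estimator (Monte-Carlo mean σ̂²g ≈ 4.0, Ĥ² ≈ 80%) |
| env_effect_sd | 1 | moderate harvest-to-harvest shifts |
| interaction_rank / interaction_sd | 2 / 0.5 | a low-rank G×E signal so AMMI-2 is the right model, small relative to main effects |
| stress multipliers | MWS 0.15, SWS 0.14 | severe dry-season yield reduction (~85%) characteristic of rain-fed tropical forage grass trials; SWS slightly harsher than MWS |
| tolerant_penalty_fraction | 0.2 | tolerant genotypes suffer one fifth of the stress penalty; with the multipliers above this separates tolerant from susceptible genotypes strongly enough for index-based screening to work, per an up-front power analysis |
| tolerance_fraction | 0.2 | a minority tolerant subpopulation, as in a diverse unselected panel |

The stress multipliers and penalty fraction were fixed by a design-time
power analysis before any validation thresholds were written, and have
not been tuned since.

### What the generator does and does not emulate

Emulated: the balanced paired-regime factorial design; exact sum-zero
main effects; an exactly low-rank AMMI interaction; a planted tolerant
subpopulation with reduced stress penalty; correlated feed-quality
traits. Not emulated: spatial field trends, unbalanced or missing plots,
repeated-measures correlation between harvests of the same plant,
genotype-specific error variances, and regime-specific genotype variance
beyond the multiplicative stress model. Published tables from real trials
are represented only by the transcribed annual-yield table; no synthetic
configuration claims to reproduce any other printed value.

## 6. Numerical conventions

- **SVD/eigenvector signs.** Singular vectors and PCA eigenvectors are
  sign-fixed so the largest-magnitude loading on each axis is positive,
  making outputs deterministic across platforms.
- **Seeding.** All randomness flows through `numpy.random.Generator`;
  derived seeds use `SeedSequence` / integer draws below 2³¹.
- **Truncation.** Negative moment estimates of σ²g are truncated to 0 and
  flagged, never reported negative.
- **Standardisation before clustering.** Features are z-scored before
  Manhattan distances so no single index dominates the metric;
  zero-variance features map to zeros.
- **ASV weight.** The SS_IPC1/SS_IPC2 ratio equals λ₁²/λ₂² and is
  computed from the fitted singular values, not re-estimated from the
  ANOVA table.
- **Determinism.** `run_pipeline` with a fixed (config, seed) writes
  byte-identical CSVs across runs; the run log records the seed, a
  configuration hash and the package version.

## 7. Limitations

- Fixed-effects ANOVA only; no REML/mixed-model machinery, so σ²g from
  unbalanced or deeply nested designs is out of scope by construction.
- H² is on a plot basis; entry-mean heritability would require dividing
  σ²e by the replicate count and is not reported.
- The Bartlett check assumes normality; its type-I calibration
  (empirically ≈ 5% under the null) does not extend to heavy-tailed
  residuals.
- Tolerance classes come from an unsupervised cut at k = 3; with weak
  separation the labels follow cluster-mean STI but carry no inferential
  guarantee.
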