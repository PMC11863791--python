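# Methods

`gsmrpipe` implements a two-sample Mendelian-randomisation (MR) analysis on
GWAS summary statistics of the kind used in large livestock breeding
populations, together with a synthetic-cohort generator that provides known
ground truth for every stage. This note records the models, the defaults and
the reasoning behind the design choices that were genuinely open.

## The causal model

For an exposure trait x and an outcome trait y, a SNP z that affects x with
effect b_zx and has no direct path to y affects y only through x, with
effect b_zy = b_xy · b_zx. Each genome-wide-significant, quasi-independent
SNP (instrumental variable, IV) therefore yields a ratio estimate
b_xy(i) = b_zy(i)/b_zx(i), and under the model all ratios estimate the same
b_xy. Horizontally pleiotropic SNPs — those with a direct effect on y —
violate this and must be removed before combining.

## Pipeline stages

1. **Cohort split.** Samples are split into two disjoint halves (sizes
   differing by at most one), each analysed independently, mimicking the
   computational split used when a national data set is too large for a
   single mixed-model run.
2. **GRM.** The genetic relationship matrix uses autosomal SNPs only:
   A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i)). SNPs with
   zero dosage variance are skipped and counted. X-chromosome markers are
   still *tested* in the scan; they simply do not enter the relationship
   matrix.
3. **MLMA.** Each SNP is a fixed effect in y = 1µ + xb + g + e with
   g ~ N(0, A σ²_g). Variance components are estimated once on the null
   model (no SNP) and held fixed across SNPs; each SNP is then a
   generalised-least-squares fit with a Wald χ²(1) test. The candidate SNP
   is not removed from the GRM (plain MLMA, not LOCO); with ~5,000 markers
   the resulting proximal contamination is mild and shows up only as slight
   conservativeness. The mean is the only covariate because the phenotypes
   are deregressed-proof-like values already corrected for environment and
   the population mean.
4. **Meta-analysis.** Cohorts are combined METAL-style with sample-size
   weights: z_meta = Σ √n_k z_k / √(Σ n_k). Genomic control is applied
   twice — to each cohort's statistics before combining, and to the combined
   statistic — with λ = median(z²)/0.4549364 (the χ²(1) median) and the
   *cap-at-one* convention: statistics are divided by √λ only when λ > 1,
   so deflated sets are never inflated. Meta Z-scores are transformed to
   allelic effects in phenotype-SD units with
   b = z/√(2p(1−p)(n+z²)), se = 1/√(2p(1−p)(n+z²)), which preserves
   b/se = z exactly. The se expression follows the same derivation as the
   b formula (an external convention; only b is usually printed). Combined
   allele frequency is the n-weighted mean of cohort frequencies. Alleles
   are reconciled by direct match, swap, strand complement or complement
   swap; A/T and C/G SNPs whose orientation disagrees are ambiguous and
   dropped with a log message.
5. **Clumping.** Candidates are SNPs with p below the Bonferroni threshold
   (α = 0.05 divided by the number of tests; 0.05/44,994 ≈ 1.11×10⁻⁶ for
   the reference array size). The lowest-p candidate becomes an index SNP
   and removes remaining candidates with r² > 0.05 against it within its
   chromosome, repeating greedily. Fewer than 10 index SNPs raises a typed
   "not testable" signal that the pipeline records instead of crashing.
6. **GSMR + HEIDI.** Per-IV ratios are combined by GLS,
   b̂_xy = (1ᵀV⁻¹b)/(1ᵀV⁻¹1), se² = 1/(1ᵀV⁻¹1), where V is the first-order
   delta-method variance–covariance of the ratios with the LD correlation
   r_ij between IVs:
   V_ij = r_ij [ se_zy,i se_zy,j/(b_zx,i b_zx,j) + b_zy,i b_zy,j se_zx,i se_zx,j/(b²_zx,i b²_zx,j) ].
   Before the GLS step, HEIDI removes pleiotropic outliers in a single
   pass: the ratio distribution is sorted and the *third quintile* taken
   (positions strictly above 0.4k and at most ⌈0.6k⌉ — the band around the
   median); the most strongly exposure-associated SNP in that band is the
   reference ("top") SNP. Selecting from the median band rather than from
   the top of the significance ranking matters: the globally strongest
   instrument may itself be pleiotropic, and pleiotropic ratios sit in the
   tails of the ratio distribution, so a tail SNP must never be the
   reference. Every other IV is tested on d_i = b_xy(i) − b_xy(top) with
   var(d_i) = V_ii + V_tt − 2V_it against χ²(1); IVs with p < 0.01 are
   removed. Instruments with |b_zx|/se_zx < 2 are refused before ratio
   formation — their ratio variance is unbounded — though the genome-wide
   significance filter makes this guard moot in practice. Pairs with fewer
   than three surviving IVs are flagged non-estimable. Significance of the
   pair uses the per-exposure threshold 0.05/SNP_INDEX, where SNP_INDEX is
   the post-clumping candidate count.
7. **Annotation.** Surviving IVs are assigned to every named gene whose
   interval extended by ±1000 bp (inclusive at both boundaries, 1-based
   coordinates, strand ignored) contains the SNP; multi-gene hits are all
   reported. Cross-exposure overlap sets report the exact-region counts of
   the Venn partition.

## REML variance components

The univariate model y = 1µ + g + e is fit by restricted maximum
likelihood after a spectral decomposition of the GRM; the restricted
likelihood is profiled down to a bounded 1-D search over the heritability
(absolute tolerance 1e-10 on h²), and standard errors come from the inverse
observed information in (σ²_g, σ²_e) with the h² SE by the delta method.

The bivariate model adds genetic and residual covariances. After rotating
both traits by the GRM eigenvectors the covariance of the i-th rotated pair
is the 2×2 block d_i G + E, so all likelihood quantities reduce to
vectorised 2×2 algebra. Fitting is average-information (AI) REML warm
started from the univariate fits and the phenotypic correlation, with a
trust-region cap on the Newton step, step-halving so the restricted
log-likelihood is non-decreasing by construction, and a gradient-ascent
fallback when the AI direction fails (this happens at degenerate optima
such as a trait paired with itself, where the AI matrix is singular).
Convergence is |Δ logL| < 1e-6 within 100 iterations; non-convergence is
flagged, never silent, and the recommended retry drops the residual
covariance (σ_e12 fixed at 0) — the same fallback used in practice when a
full bivariate fit fails. Variance components are floored at 1e-8 with a
warning; the genetic correlation r_G = σ_g12/√(σ²_g1 σ²_g2) is kept inside
(−1, 1) by clipping the covariance at 1 − 1e-8 of its bound, and its SE
comes from the inverse AI matrix by the delta method.

A bivariate fit on traits with zero cross-covariance reproduces the
univariate marginals to a few parts in 10³ rather than exactly: the
bivariate optimum estimates a (small, noisy) ĝ₁₂ and the marginals shift at
order ĝ₁₂². The test-suite checks agreement at 5×10⁻³.

## The synthetic cohort

The generator emulates a medium-density genotyping array in a single
population plus continuous pre-corrected phenotypes. What it reproduces:
block LD with tunable adjacent-SNP correlation, a MAF spectrum with a ≥1%
QC filter, an X chromosome excluded from the GRM, polygenic trait
architecture, a mediated exposure→outcome effect and planted horizontal
pleiotropy. What it does not reproduce: pedigree/family structure and
selection (the GRM of real cattle has far more long-range structure),
LD decaying smoothly with distance (blocks here are internally AR(1) and
mutually independent), reliability weighting of deregressed proofs (traits
are unit-variance Gaussian), and imputation error. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to those real-data features.

Haplotypes within a block follow a first-order Markov copying chain:
allele j+1 equals allele j with probability ρ and is otherwise a fresh
Bernoulli(p) draw, with one frequency p per block. This keeps marginal
frequencies exact and makes the adjacent-SNP haplotype correlation exactly
ρ — a latent-Gaussian threshold scheme was considered and rejected because
its allele-scale correlation is attenuated relative to the latent one and
would need per-MAF calibration.

Traits: exposure = polygenic value (empirically scaled to variance
h²_x) + Gaussian residual; outcome = b_xy·exposure + a direct polygenic
component of variance h²_y on its own disjoint causal set + direct effects
of the pleiotropic SNPs + residual, with the residual sized so the total
variance is ≈1. Pleiotropic SNPs receive *both* an exposure effect (drawn
like any causal SNP, so they surface as instruments) and a direct outcome
effect of fixed magnitude ±pleio_effect_sd with random sign. The fixed
magnitude is deliberate: the planted-outlier detection rate is a property
of the filter only if the planted effects have a controlled size; a
Gaussian draw near zero is not an outlier and nothing could detect it.

Defaults (the reference study conditions used throughout the validation
suite): n = 10,000 individuals; 9 autosomes + X with 500 SNPs each (5,000
markers); MAF ~ U(0.01, 0.5) refiltered at ≥1%; LD blocks of 20 SNPs with
ρ = 0.7; h²_x = 0.3, h²_y = 0.1 (a typical low-heritability fitness trait);
50 exposure-causal SNPs; b_xy = 0.4; 5 pleiotropic SNPs with
pleio_effect_sd = 0.1 per standardized genotype (~1% of outcome variance
each).

## Validation design and problem sizes

The validation suite and the reproduction script measure:

- **Recovery**: one full-pipeline run at the reference conditions above;
  the GSMR estimate must fall within 3 SE of the planted b_xy = 0.4. The
  planted-pleiotropy removal in that run is reported alongside.
- **HEIDI detection rate**: 20 seeded replicates at the summary-statistic
  level (instrument effects, sampling noise and planted direct effects
  drawn at the same scales the pipeline produces; 5 planted outliers among
  ~40 instruments each). Summary-level replication is used because the
  detection *rate* needs replicates and repeating the full mixed-model
  pipeline per replicate adds nothing to what the single full run already
  exercises.
- **Type-I error**: 200 summary-level null pairs (b_xy = 0, no
  pleiotropy); the fraction significant at 0.05/SNP_INDEX must stay below
  7.5%.
- **GREML**: univariate h² = 0.3 and bivariate r_G = 0.5 recovery within
  2 SE at n = 4,000, m = 2,000, in both residual-covariance modes.
- **Oracle agreement**: the GRM, the greedy clump, the GLS estimate and
  the gene-window annotation against independent brute-force
  implementations (naive double loops, explicit matrix inversion,
  exhaustive scans) on randomised small instances.
- **Calibration**: λ ∈ [0.9, 1.1] for a mixed-model scan of pure noise;
  genomic control maps a λ = 2 set exactly to λ = 1 and leaves λ ≤ 1 sets
  untouched; two equal cohorts at z = 3 combine to 3√2.

## Numerical choices and degenerate inputs

- GRM eigendecompositions are cached on the `Grm` object; eigenvalues are
  floored at 0 against round-off.
- Singular V in the GLS step is ridge-regularised with 1e-8·tr(V)/k and a
  warning.
- p-values are clipped away from exact 0 so downstream −log10 and
  significance comparisons stay finite.
- Ties in clumping are broken by (p, marker ID); ties in the HEIDI band by
  (p_zx, marker ID) — all orderings are deterministic.
- Monomorphic SNPs are skipped (GRM, scan) or mean-imputed (missing bed
  genotypes) with logged counts; truncated or mislabeled bed files raise
  format errors naming the file.
- Every generator output is a pure function of (config, seed); two runs of
  the pipeline with the same config produce byte-identical tables.

## Known limitations

- No LOCO scan, no covariates beyond the mean, no binary-trait liability
  models, no multi-GRM partitioning or dominance.
- HEIDI is single-pass; it does not iterate after removal. With very high
  pleiotropy density (> ~40% of instruments) the median band itself can be
  contaminated and the filter degrades.
- The meta-analysis offers only the sample-size-weighted mode (no
  inverse-variance weighting, no Cochran's Q across cohorts).
- The linear GSMR approximation: non-linear exposure–outcome relationships
  are outside the model.
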