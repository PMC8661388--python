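# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `namqtl`.

## Populations and genotype coding

The package targets biparental RIL families that share a common parent
(a NAM design). Genotypes are coded additively per marker: 0 = homozygous
for the common parent's allele, 1 = heterozygous, 2 = homozygous for the
family's alternative parent. Effect sizes are therefore *trait units per
allele-code unit*: a full homozygote substitution changes the expected
trait by twice the reported effect, and a positive effect means the
alternative-parent allele increases the trait. Heterozygous individuals
are retained in the additive coding.

## Synthetic-data generator

The generator exists so that every downstream estimate can be checked
against known truth. What it emulates, and what it does not:

**Genetic map.** `simulate_map` places `markers_per_chromosome` markers
per chromosome with uniformly jittered spacings rescaled so the mean
spacing is exactly the requested value (default use: 1.6 cM, mirroring a
~836-marker genome-wide frame). Physical positions are genetic positions
at 1 Mb/cM; they exist only for ordering and reporting, so no attempt is
made to model recombination-rate variation along chromosomes.

**RIL genotypes.** `simulate_ril_family` draws each chromosome from the
two-state RIL Markov chain: the first marker is 0/2 with probability ½
and adjacent markers at distance *d* cM switch parental state with
probability

  R = 2r/(1+2r),  r = ½(1 − e^(−2d/100)) (Haldane),

the classical expected recombination fraction between fully inbred selfed
RILs under no crossover interference. This closed form is exactly the
stationary behaviour of gamete-level simulation followed by selfing to
fixation (the test suite verifies the equivalence against a forward
Monte-Carlo of the two-locus selfing chain). Residual heterozygosity is
injected afterwards as independent per-cell replacement with code 1 at
rate 0.1% by default — NAM RILs are near-fixed, and the real panels'
residual heterozygosity and missingness rates are not published with the
trait data, so the default is the module's own choice. Consequences: no
segregation distortion, no genotyping error beyond optional missingness,
no interference.

**Phenotypes.** `simulate_phenotype` builds
y_i = offset(family_i) + Σ_k a_k x_ik + e_i with normal residuals. The
residual SD is set from the *realized* variance of the QTL genetic values
so that their variance fraction equals the target h² in expectation
(family offsets are fixed shifts and are not counted in h²; they exist to
exercise the family term of the joint model). h² = 0 means pure noise
(SD `null_sd`, default 1); h² = 1 means an exact linear trait and
requires nonzero genetic variance.

**Field trials.** `simulate_field_trial` randomizes test genotypes into
blocks of `block_size − checks_per_block` entries and adds
`checks_per_block` check plots per block: the common parent in every
block plus one rotating founder (with 20 + 2 this yields ~9–10% check
plots). Observations add a year effect, a block-within-year effect, and a
plot residual, all independent normals. Check genotype values default to
the grand mean (common parent) and family means (founders) — a RIL family
mean approximates the midparent. Not modelled: spatial row/column trends,
year-by-genotype interaction, heteroscedasticity.

All generator randomness flows from one user seed per operation;
`simulate_nam` draws families sequentially from a single stream, so a
one-family panel reproduces `simulate_ril_family` exactly.

Because the generator satisfies the mapping models' assumptions by
construction, passing tests demonstrate correctness of the *procedures*
(type-I error control, unbiased localization, calibrated TPVE), not
robustness to model misspecification in real field data.

## BLUE estimation

`fit_blue` fits observation = genotype (fixed, cell-means coding) + year
(random) + block-within-year (random) + residual. Plants measured within
a plot are averaged to one plot value first. The residual variance is
profiled out and the two variance ratios are estimated by REML via
Nelder-Mead on their logs (bounds e^±16, convergence tolerance 1e-10,
components below 1e-8·σ²ₑ reported as 0); with one year the year
component is dropped. BLUEs are the GLS genotype estimates at the
converged components — the genotype's expected value at average random
effects (least-squares-means convention), so on balanced complete designs
they reduce to genotype means. Standard errors come from
σ²ₑ(X'W⁻¹X)⁻¹. A union-find check over blocks warns when no shared
genotypes connect the incomplete blocks (estimates are still returned).
The implementation is dense linear algebra, adequate for trials of a few
thousand plots; the test suite cross-checks components and BLUEs against
an independent mixed-model REML implementation.

## Single-family scan and stepwise selection

`marker_scan` fits phenotype ~ intercept + conditioned markers + test
marker and records the partial F-test p-value of the test marker. The LOD
score is defined from the nested linear models,
LOD = (n/2)·log₁₀(RSS_reduced/RSS_full) — the standard
regression-mapping equivalence, used only for support intervals. Rows
missing the phenotype are dropped; rows missing the test marker's
genotype are dropped for that marker only; a test marker collinear with
the conditioned design (relative residual variance ≤ 1e-12) is recorded
as p = 1 with a flag.

`permutation_threshold` permutes the phenotype across RILs (destroying
marker-trait association while preserving the LD among markers), records
the genome-wide minimum p per permutation, and returns the order
statistic ⌈α·n_perm⌉ of the sorted minima — with 200 permutations and
α = 0.05, the 10th smallest minimum. This lower order statistic is
conservative and reproducible. When a conditioned set is supplied, the
conditioned marker rows are permuted together with the phenotype.

`stepwise_qtl` computes the threshold once from the unconditioned scan
and reuses it across rounds (recomputing after each acceptance is an
option flag, default off — with the threshold reused, each step's test is
against the same genome-wide null). Forward selection accepts the
minimum-p marker while p < threshold, breaking exact ties by lowest
(chromosome, position) for determinism. Reported per QTL: the p-value at
its acceptance step; cumulative TPVE = 100·R² of the model up to that
step (nondecreasing by construction); the effect size from the final
joint model; and the 1-LOD interval from a final scan conditioned on the
other accepted markers. `lod_support_interval` returns the maximal
contiguous marker run around the peak with LOD ≥ LOD_peak − drop on the
peak's chromosome; the drop is anchored at the requested peak marker's
own LOD (inside stepwise the conditional profile's maximum can sit at a
neighbouring marker), and conditioned markers — which have no LOD of
their own — do not break the run. Positions are reported in Mb to one
decimal.

## Joint-linkage mapping

`joint_scan` fits phenotype ~ family + marker:family: family mean term
plus one slope per family per marker. Because nested columns of different
families have disjoint support, the model decomposes into per-family
regressions, which the implementation exploits for vectorization; the
test statistic is the joint partial F over the nested slope block with
numerator df = the number of families where the marker segregates
(non-segregating families are dropped from the block with a flag).
Permutations shuffle the phenotype within each family independently,
preserving every family's mean exactly; the threshold is again the
α-order statistic of the minimum-p distribution (1000 permutations is the
conventional per-family count; the acceptance studies run 200 to keep
desk-scale runtimes).

Reporting conventions for the QTL table, where the single-row-per-QTL
format is inherently lossy for a nested model:

- *Assigned family*: the family whose nested effect has the smallest
  marginal p in the final model, with the full nested-effect table
  attached as `nested_effects`. (How published joint-linkage tables chose
  their single printed family is not documented; this rule is transparent
  and reproducible.)
- *Effect size*: the assigned family's nested effect.
- *TPVE*: 100·(RSS_family − RSS_family+QTL₁..j)/TSS — the share of total
  phenotypic variance explained by the QTL terms beyond family means.
  This excludes the family term's own contribution (whether published
  joint TPVE columns include it is ambiguous); it is nondecreasing over
  steps, and `final_r2` reports the full model's R² including the family
  term.

With a single family the joint model reduces exactly to the single-family
scan (identical F statistics, identical permutation stream), which the
tests assert.

## Trait correlations

`pearson_matrix` computes Pearson r per trait pair on the genotypes where
both traits are observed (pairwise-complete; a strict listwise mode is a
flag — the phrase "complete observations" is ambiguous and pairwise is
the common default of correlation-matrix routines). Two-sided p-values
come from the exact t-distribution; Holm's step-down adjustment is
applied across all off-diagonal pairs tested in the matrix. Pairs with
fewer than 3 complete observations or zero variance are reported missing
and flagged rather than guessed.

## Numerical choices and degenerate inputs

- Scans clip partial r² at 1 − 1e-15 before the F transform; exact-fit
  phenotypes underflow to p ≈ 0 rather than erroring.
- Constant phenotypes, empty maps, invalid rates/thresholds, undefined
  permutation quantiles (n_perm·α < 1), and h² = 1 with zero genetic
  variance raise `ValueError` with specific messages.
- Imputation rounds the conditional expected code to the nearest of
  {0, 1, 2} (numpy half-to-even at exact ties); a RIL with no informative
  marker on a chromosome gets the prior expectation (code 1) with a
  warning; observed codes are never altered and an `imputed` mask is
  returned.
- MAF filtering keeps markers at exactly the threshold (the removal rule
  is "less than"); heterozygotes contribute one allele of each kind.

## Problem sizes of the validation studies

The acceptance studies use 200 null replicates (single-family; 156 RILs,
200 markers, 200 permutations) and 100 null replicates (joint; 624 RILs
over four families, 200 within-family permutations), plus 100-replicate
recovery and BLUE comparisons — sizes chosen to make Monte-Carlo error
small relative to the tested bounds while staying comfortably
reproducible on a laptop. The scans are fully vectorized
(permutation-by-marker cross products), which is what makes these
replicate counts cheap.

## Limitations

- Additive biallelic QTL only: no epistasis, dominance, or QTL-by-year
  interaction; forward selection only (no model refinement or interval
  mapping between markers).
- The permutation threshold is computed once from the unconditioned scan
  by default; conditional re-thresholding is available but changes the
  multiple-testing interpretation of later steps.
- BLUE fitting is dense (O(n³) per REML evaluation) and intended for
  trial-sized data, not genome-scale mixed models.
- HapMap reading derives genetic positions from physical positions at a
  constant cM/Mb (the format carries no genetic coordinate); supply a
  `GeneticMap` directly when a real linkage map is available.
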