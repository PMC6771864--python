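# Methods

## The two-stage liability model

The package's synthetic cohorts, and the analyses run on them, assume AD
develops in two stages on the probit (liability-threshold) scale:

1. **Amyloid deposition.** Latent amyloid liability
   `L_A = w_A · (d_ε4 − d_ε2) + ε`, with `ε ~ N(0, 1)` and `d_ε4`, `d_ε2`
   the alternate-allele dosages at the two APOE-coding SNP analogues.  A
   subject is amyloid-positive when `L_A` exceeds the empirical quantile
   `q_A` of the cohort's liabilities.  The PET read-out is
   `SUVR = 1.11 + 0.3 · (L_A − threshold)`, so the conventional AV45
   positivity cutoff of 1.11 coincides exactly with the liability
   threshold (SUVR is floored at 0.05; the floor matters only in a
   vanishing far-left tail).
2. **Conversion.** Among amyloid-positive subjects, conversion liability
   `L_C = PGS + w_C · (d_ε4 − d_ε2) + ε′`, where `PGS = Σ β_j G_j` over
   `n_causal` non-APOE variants with zero-mean effects rescaled so
   `SD(PGS) = w_poly`, and `ε′ ~ N(0, 1)` independent of stage 1.
   Converters are positives with `L_C` above the `q_C` quantile of the
   positive subjects' liabilities.  Clinical AD = amyloid-positive and
   converted.

Amyloid status therefore carries **no** polygenic information beyond APOE,
and conversion among positives carries polygenic information by
construction — the dissociation the analysis pipeline is designed to
detect, and the property the acceptance tests check.

## Generator parameters (study conditions)

| parameter | default | meaning |
|---|---|---|
| `n_target` | 770 | target-cohort size (subjects with genotypes and longitudinal diagnoses) |
| `n_discovery` | 3,000 | discovery-GWAS cohort size |
| `n_blocks` × `snps_per_block` | 50 × 20 | 1,000 SNPs in independent LD blocks; blocks > 1 Mb apart so clumping windows never span blocks |
| `ld_decay` | 0.7 | within-block haplotype-copying parameter; adjacent-SNP correlation ≈ 1 − ld_decay |
| `maf_range` | (0.05, 0.5) | per-SNP allele frequencies, uniform |
| `eps2_freq`, `eps4_freq` | 0.08, 0.15 | ε-haplotype frequencies at the APOE-like locus (European-ancestry-like) |
| `w_amyloid_apoe` | 1.6 | APOE weight on amyloid liability (≈ 50% of liability variance; gives amyloid AUC_APOE ≈ 0.78) |
| `w_convert_poly` | 1.2 | SD of the polygenic conversion component (≈ 59% of conversion-liability variance) |
| `w_convert_apoe` | 0.3 | residual APOE effect on conversion |
| `amyloid_threshold_quantile` | 0.5 | half the cohort amyloid-positive |
| `convert_threshold_quantile` | 0.6 | 40% of positives convert |
| `n_causal` | 60 | causal non-APOE variants |
| `p_prevalent_ad` | 0.45 | converters already AD at baseline (they form the stable-AD arm) |
| trajectory flip rates | 0.02 / 0.01 / 0.01 | CN→MCI, MCI→CN, AD→MCI label flips exercising the excluded/atypical classes |
| `suvr_missing_rate` | 0.115 | subjects without a PET scan |

These defaults are the package's study conditions: cohort sizes, APOE
frequencies, positivity and conversion rates, and the missing-scan rate
echo a longitudinal AD neuroimaging cohort; the liability weights were
calibrated once so that the generated cohorts reproduce the qualitative
pattern the analysis targets (strong APOE signal for amyloid, detectable
polygenic signal for conversion at n ≈ 770) and are not adjusted per run.
Allele pairs are drawn with a ~10% strand-ambiguous (A/T, C/G) fraction, as
on real arrays, so harmonization has palindromic variants to drop.

What the generator does **not** emulate: realistic human LD maps
(haplotype copying is first-order within rectangular blocks), imputation
uncertainty (all dosages are hard calls), age-dependent incidence (age is
drawn independently of liability), genotyping batch effects, and — except
via the optional `pop_divergence` toggle — population stratification.
Consequently, passing tests show the machinery is correct under the stated
model, not that real cohorts satisfy the model.

## Scoring pipeline

Fixed order, counts logged at every stage: variant QC → allele
harmonization → p ≤ 0.5 selection → LD clumping → APOE-region exclusion →
weighted dosage sum → PC adjustment → standardization.

* **QC**: missingness > 0.02, Hardy–Weinberg exact p < 10⁻⁶ (standard
  conditional enumeration, implemented here and verified against an exact
  rational-arithmetic oracle), MAF < 0.01.
* **Harmonization**: match by chromosome:position; allele swap negates the
  beta; strand flips resolved by complementing; palindromic variants
  dropped (strand unresolvable without reference frequencies).
* **Selection**: discovery p ≤ 0.5, inclusive (the threshold reported to
  maximise AD prediction accuracy).
* **Clumping**: greedy, p-value-ordered ("keep the most associated"); ties
  on p break by (chromosome, position); r² is the squared Pearson
  correlation of target-cohort dosages — no external reference panel in a
  single-cohort setting.  Property-tested against an exhaustive
  brute-force greedy oracle.
* **APOE region**: chr19:44,400,000–46,500,000, 1-based closed.  The
  "19:44,400–46,500 kb" convention is read as kilobases, the only reading
  containing APOE.
* **APOE term**: the ε-allele counts come from the standard two-SNP
  diplotype table resolved by maximum parsimony (the ε1 haplotype counts
  as neither ε2 nor ε4); the doubly-heterozygous diplotype is called
  ε2/ε4.  Weights are estimated by joint logistic regression of AD status
  on (ε2, ε4) counts in the target; reference values (−1.04, +1.55) can
  be supplied as a fixed override.
* **PCs**: computed once on the clumped genome-wide variants
  (centred by 2f, scaled by √(2f(1−f)), top-8 left singular vectors) and
  reused for pathway scores.  Genome-wide scores are adjusted for PCs
  only; pathway scores for PCs plus age and sex — then standardized
  (z-scored, sample SD, ddof = 1).
* **Missing dosages** stay missing through QC (the missingness filter
  needs them) and are mean-imputed per variant only inside the scoring
  dot product.

## Model battery

Logistic regression throughout (statsmodels MLE).  Each of the three
predictor sets (APOE, PRS, FULL) is fitted twice — without covariates, and
with sex (0/1) and age (years, uncentred) — giving the paired AUCs.  AUC
is the rank-based probability that a random case outscores a random
control, ties counted half, computed from fitted probabilities so the
covariate-including AUC reflects the whole linear predictor.  The
PRS-above-APOE test is the χ²₁ likelihood-ratio test on the
covariate-including fits, the standard deviance comparison for nested
binomial models.

**Degenerate designs.** Small contrast arms with a rare protective allele
occasionally quasi-separate (no case carries ε2), where the MLE diverges.
The battery then refits all nested models with a small L2 penalty
(α = 0.01, intercept unpenalized) on a common estimation path and flags
the event in the log; the deviance difference is then approximate.  The
`fit_logistic` primitive itself still raises an explicit separation
error — the stabilization is a battery-level policy, not a change to the
fitter.

The extremes analysis re-runs the battery on subjects with
|standardized PRS| > 1.5 SD (≈ 13.4% of a normal score distribution).
The Bonferroni threshold for pathway scans is α/(3 scenarios × 9 pathways)
= 1.85×10⁻³.

## Sample-overlap correction

Stage 1 estimates the overlap-induced effect-size variability: with the
known numbers of overlapping cases/controls removed at random, the
per-variant GWAS is refitted (vectorised Newton iterations over all
variants simultaneously); `c` is the mean over variants of the replicate
SD of β divided by the full-sample SE.  A single multiplier is used
because the quantity of interest is one cohort-level constant (a
per-variant option exists).  Stage 2 redraws each β from
Normal(β, c·SE), redefines p = 2Φ(−|β′/SE|) (the normal/Wald
approximation — the input betas are themselves Wald estimates),
re-selects, re-clumps, re-scores, refits, and averages the AUCs.  With
c = 0 the stage-2 output is bit-identical to the deterministic pipeline.
Stage-2 replicate counts default to 200 for desk runs (every report
states the count used); the experiment harness
(`run_overlap_experiment`) uses 30/40 stage-1/stage-2 draws per replicate
on a reduced cohort (600 target / 1,500 discovery subjects, 600 SNPs) —
sizes chosen so a 20-replicate paired experiment completes in minutes
while the inflation is still well-resolved.

The held-out-truth experiment shows the correction's character: with 30%
of target cases inside the discovery cohort, the naive AUC is inflated by
~0.06 over the disjoint-discovery truth; the corrected mean lands between
the two, closer to the truth than the naive value but not all the way —
perturbing betas by their overlap-induced variability dilutes part of the
noise-fitted advantage while leaving the rest in place.  The correction is
a mitigation, not an unbiasing.

## Cohort conventions

* Analysis labels from the (first, last) diagnosis pair: stable CN/MCI/AD
  keep their label; CN→MCI and MCI→CN are excluded; AD→MCI is analysed as
  MCI; MCI→AD converters are analysed in the **MCI arm** with a converter
  flag — the trajectory-table convention, logged as a warning because it
  deliberately disagrees with last-diagnosis labelling
  (`converters_as="AD"` switches to the alternative).  CN→AD is analysed
  as AD; AD→CN is excluded (rapid/implausible paths resolved by the same
  first/last logic).
* SUVR ≥ 1.11 is amyloid-**positive** (inclusive boundary, the common
  convention); the latest scan wins when several exist.
* The conversion contrast is defined among amyloid-positive subjects with
  baseline MCI; its subjects are by construction a subset of the amyloid
  contrast's positive arm.

## Numerical choices

* Empirical (not theoretical) quantiles threshold the liabilities, so
  configured positivity/conversion rates are exact in every replicate.
* The per-variant GWAS fitter runs two-parameter Newton steps vectorised
  across variants (tolerance 10⁻⁸, max 30 iterations); non-converged or
  monomorphic variants are excluded with a logged count.  It agrees with
  statsmodels to 10⁻⁶ on test fixtures.
* Clumping mean-imputes missing dosages before correlating; zero-variance
  columns yield r = NaN, treated as uncorrelated.
* All randomness flows from explicit seeds; identical configuration +
  seed reproduces every output byte-identically.

## Known limitations

* The LRT after ridge stabilization is approximate; it is used only where
  the unpenalized MLE does not exist.
* Palindromic variants are dropped rather than frequency-resolved; on the
  synthetic arrays this loses ~10% of variants.
* The overlap correction inherits the method's own limitation visible in
  the held-out experiment: it reduces, but does not remove, inflation.
* Single-chromosome-pair layout (chr1 + chr19): positions are realistic
  but the genome is far smaller than a real array; absolute AUCs should
  not be compared against real-data values, only patterns.
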