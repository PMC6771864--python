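"""Synthetic cohorts with a two-stage liability architecture.

The generator emulates the data a stage-aware PRS analysis needs:

* hard-call genotypes organised in LD blocks, with a designated two-SNP
  APOE-like locus whose haplotypes define epsilon2/epsilon3/epsilon4
  analogues (the rs429358/rs7412 coding);
* a discovery cohort, optionally sharing subjects with the target cohort,
  from which per-variant logistic GWAS summary statistics are computed;
* a two-stage probit-liability phenotype: the APOE-like locus drives a
  latent amyloid liability (thresholded into PET positivity with a SUVR
  read-out), and a polygenic background drives conversion from amyloid
  positivity to clinical AD;
* visit-level diagnosis trajectories (stable CN/MCI/AD, MCI-to-AD
  converters, and small fractions of the atypical paths) plus age and sex;
* gene intervals tiling the simulated chromosomes and gene sets (pathways),
  one of which always contains the APOE-like locus.

Every generator is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DX_CODES = ("CN", "MCI", "AD")

#: complementary DNA bases, used when assigning ref/alt pairs
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ApoeLocus:
    """Location of the two SNPs whose haplotypes define the epsilon alleles.

    ``slot_eps4`` is the rs429358 analogue (alt allele C tags epsilon4) and
    ``slot_eps2`` the rs7412 analogue (alt allele T tags epsilon2); both are
    within-block variant indices and may be negative (counted from the end
    of the block, as in Python indexing).
    """

    block: int = -1
    slot_eps4: int = -2
    slot_eps2: int = -1


@dataclass(frozen=True)
class SimConfig:
    """Free parameters of the synthetic study.

    Liability weights are on the probit scale: the latent amyloid liability
    is ``w_amyloid_apoe * (eps4 dosage - eps2 dosage) + N(0, 1)`` noise, and
    the conversion liability (meaningful only for amyloid-positive subjects)
    is a polygenic score with standard deviation ``w_convert_poly`` plus an
    APOE term weighted by ``w_convert_apoe`` plus unit noise.  Thresholds
    are empirical quantiles, so ``amyloid_threshold_quantile = 0.5`` makes
    half the cohort amyloid-positive.
    """

    seed: int = 0
    n_target: int = 770
    n_discovery: int = 3000
    n_overlap_cases: int = 0
    n_overlap_controls: int = 0
    n_blocks: int = 50
    snps_per_block: int = 20
    ld_decay: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    apoe_locus: ApoeLocus = field(default_factory=ApoeLocus)
    w_amyloid_apoe: float = 1.6
    w_convert_poly: float = 1.2
    w_convert_apoe: float = 0.3
    amyloid_threshold_quantile: float = 0.5
    convert_threshold_quantile: float = 0.6
    n_causal: int = 60
    n_visits: int = 5
    # epsilon-haplotype frequencies at the APOE-like locus
    eps2_freq: float = 0.08
    eps4_freq: float = 0.15
    # trajectory composition
    p_mci_given_negative: float = 0.5
    p_mci_given_positive: float = 0.7
    p_prevalent_ad: float = 0.45
    flip_cn_to_mci: float = 0.02
    flip_mci_to_cn: float = 0.01
    flip_ad_to_mci: float = 0.01
    suvr_missing_rate: float = 0.115
    # SUVR read-out: threshold + scale * (liability - liability threshold)
    suvr_threshold: float = 1.11
    suvr_scale: float = 0.3
    # optional two-population toggle for PC tests: allele-frequency
    # divergence between two equal halves of the sample (0 = one population)
    pop_divergence: float = 0.0

    def validate(self) -> None:
        if min(self.n_target, self.n_discovery, self.n_blocks, self.snps_per_block) <= 0:
            raise ValueError("counts must be positive")
        if self.n_overlap_cases < 0 or self.n_overlap_controls < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.n_overlap_cases + self.n_overlap_controls > self.n_discovery:
            raise ValueError("overlap counts exceed the discovery cohort size")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be ordered and within (0, 0.5]")
        if not 0 <= self.ld_decay <= 1:
            raise ValueError("ld_decay must be in [0, 1]")
        for q in (self.amyloid_threshold_quantile, self.convert_threshold_quantile):
            if not 0 < q < 1:
                raise ValueError("threshold quantiles must be in (0, 1)")
        for w in (self.w_amyloid_apoe, self.w_convert_poly, self.w_convert_apoe):
            if not np.isfinite(w):
                raise ValueError("liability weights must be finite")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        _, s4, s2 = self.resolved_apoe()
        if not (0 <= s4 < self.snps_per_block and 0 <= s2 < self.snps_per_block):
            raise ValueError("apoe_locus slot out of range")
        if s4 == s2:
            raise ValueError("the two APOE slots must be distinct variants")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        n_non_apoe = (self.n_blocks - 1) * self.snps_per_block
        if self.n_causal > n_non_apoe:
            raise ValueError("n_causal exceeds the number of non-APOE variants")

    def resolved_apoe(self) -> tuple[int, int, int]:
        """(block, eps4 slot, eps2 slot) with negative indices resolved."""
        block = self.apoe_locus.block % self.n_blocks
        s4 = self.apoe_locus.slot_eps4 % self.snps_per_block
        s2 = self.apoe_locus.slot_eps2 % self.snps_per_block
        return block, s4, s2


@dataclass
class DosageMatrix:
    """Samples-by-variants additive allele dosages with variant metadata.

    ``dosages`` holds alternate-allele counts as float64 with NaN for
    missing calls; ``variants`` carries id, chrom, pos (1-based), ref, alt.
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape does not match metadata")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_samples(self, index: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(
            samples=np.asarray(self.samples)[index],
            variants=self.variants,
            dosages=self.dosages[index],
        )

    def subset_variants(self, mask_or_index) -> "DosageMatrix":
        """Positional subset of variants (boolean mask or integer index)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return DosageMatrix(
            samples=self.samples,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency, missing calls excluded."""
        return np.nanmean(self.dosages, axis=0) / 2.0


def _block_layout(config: SimConfig) -> pd.DataFrame:
    """Variant metadata: positions strictly increasing, blocks > 1 Mb apart.

    Non-APOE blocks tile chromosome 1 at 1.5 Mb strides; the APOE-like block
    sits on chromosome 19 inside the canonical 44.4-46.5 Mb region so the
    region-exclusion step removes exactly that block.
    """
    spacing = 2_000  # bp between adjacent variants within a block
    apoe_block, _, _ = config.resolved_apoe()
    rows = []
    chr1_block = 0
    for b in range(config.n_blocks):
        if b == apoe_block:
            chrom, start = "19", 45_300_000
        else:
            chrom, start = "1", 1_000_000 + chr1_block * 1_500_000
            chr1_block += 1
        for j in range(config.snps_per_block):
            rows.append((f"snp_b{b}_{j}", chrom, start + j * spacing, b, j))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos", "block", "slot"])
    return df


def gen_ld_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> DosageMatrix:
    """Generate hard-call dosages for the target plus discovery samples.

    Within a block, haplotype alleles follow a first-order copying scheme:
    each allele copies its left neighbour with probability ``1 - ld_decay``
    and is otherwise drawn fresh at that variant's allele frequency, giving
    adjacent-variant correlation that decays geometrically along the block.
    Blocks are mutually independent.  The two APOE-slot variants are instead
    derived from epsilon-haplotype draws (eps2/eps3/eps4 with configured
    frequencies), so the epsilon1 haplotype never occurs in truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_target + config.n_discovery
    meta = _block_layout(config)
    m = len(meta)
    rho = 1.0 - config.ld_decay
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    # ref/alt alleles: random distinct bases, ~10% strand-ambiguous
    # (palindromic) pairs as on real arrays; APOE slots overwritten below
    ref_idx = rng.integers(0, 4, size=m)
    comp_idx = 3 - ref_idx  # A<->T, C<->G under the ACGT ordering
    other = np.array([[1, 2], [0, 3], [0, 3], [1, 2]])  # non-self, non-complement
    alt_idx = np.where(
        rng.random(m) < 0.10,
        comp_idx,
        other[ref_idx, rng.integers(0, 2, size=m)],
    )

    hap = np.empty((2 * n, m), dtype=np.int8)
    copy = rng.random((2 * n, m)) < rho
    fresh = (rng.random((2 * n, m)) < maf[None, :]).astype(np.int8)
    block_ids = meta["block"].to_numpy()
    for j in range(m):
        if j == 0 or block_ids[j] != block_ids[j - 1]:
            hap[:, j] = fresh[:, j]
        else:
            hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])

    # optional two-population structure: shift allele usage in one half
    if config.pop_divergence > 0:
        half = n  # first n haplotype pairs -> interleave by sample
        d = config.pop_divergence
        shifted = np.clip(maf + rng.choice([-d, d], size=m), 0.01, 0.99)
        pop2 = np.zeros(2 * n, dtype=bool)
        pop2[n:] = True  # haplotypes of the second half of samples
        redraw = rng.random((2 * n, m)) < 0.5
        fresh2 = (rng.random((2 * n, m)) < shifted[None, :]).astype(np.int8)
        sel = pop2[:, None] & redraw
        hap[sel] = fresh2[sel]

    # APOE-like locus: epsilon haplotypes (eps2 = T at rs7412 slot,
    # eps4 = C at rs429358 slot, eps3 = neither); epsilon1 never generated.
    apoe_block, s4, s2 = config.resolved_apoe()
    j4 = int(meta.index[(meta["block"] == apoe_block) & (meta["slot"] == s4)][0])
    j2 = int(meta.index[(meta["block"] == apoe_block) & (meta["slot"] == s2)][0])
    u = rng.random(2 * n)
    is_eps2 = u < config.eps2_freq
    is_eps4 = u >= 1.0 - config.eps4_freq
    hap[:, j4] = is_eps4.astype(np.int8)
    hap[:, j2] = is_eps2.astype(np.int8)

    dosages = (hap[0::2] + hap[1::2]).astype(np.float64)
    # pair haplotypes 2i, 2i+1 into sample i
    variants = meta.copy()
    variants["ref"] = _BASES[ref_idx]
    variants["alt"] = _BASES[alt_idx]
    variants.loc[j4, ["ref", "alt"]] = ["T", "C"]  # rs429358 analogue
    variants.loc[j2, ["ref", "alt"]] = ["C", "T"]  # rs7412 analogue
    variants["is_apoe_slot"] = False
    variants.loc[[j4, j2], "is_apoe_slot"] = True
    samples = np.array([f"S{i:05d}" for i in range(n)])
    return DosageMatrix(samples=samples, variants=variants, dosages=dosages)


def plant_effects(variants: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign true per-variant liability effects for the two stages.

    ``n_causal`` variants outside the APOE block receive conversion-stage
    effects drawn zero-mean normal and rescaled so the polygenic conversion
    liability has standard deviation ``w_convert_poly`` (computed from the
    2p(1-p) binomial variance of each dosage, blocks treated as
    independent).  The APOE slots carry the only amyloid-stage effects:
    +w on the eps4 slot, -w on the eps2 slot, and analogously signed
    conversion-stage effects of magnitude ``w_convert_apoe``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    apoe_block, _, _ = config.resolved_apoe()
    effects = pd.DataFrame(
        {
            "id": variants["id"].to_numpy(),
            "beta_amyloid": 0.0,
            "beta_convert": 0.0,
            "causal": False,
        }
    )
    eligible = np.flatnonzero((variants["block"] != apoe_block).to_numpy())
    if config.n_causal > len(eligible):
        raise ValueError("n_causal exceeds the number of non-APOE variants")
    causal = rng.choice(eligible, size=config.n_causal, replace=False)
    if config.n_causal > 0:
        raw = rng.normal(size=config.n_causal)
        if "maf" in variants.columns:
            p = variants["maf"].to_numpy()[causal]
        else:
            p = np.full(config.n_causal, 0.25)
        var_g = 2.0 * p * (1.0 - p)
        scale = config.w_convert_poly / np.sqrt(np.sum(raw**2 * var_g))
        effects.loc[causal, "beta_convert"] = raw * scale
        effects.loc[causal, "causal"] = True

    slot4 = variants.index[variants.get("is_apoe_slot", False) & (variants["alt"] == "C")]
    slot2 = variants.index[variants.get("is_apoe_slot", False) & (variants["alt"] == "T")]
    if len(slot4) == 1 and len(slot2) == 1:
        effects.loc[slot4[0], "beta_amyloid"] = config.w_amyloid_apoe
        effects.loc[slot2[0], "beta_amyloid"] = -config.w_amyloid_apoe
        effects.loc[slot4[0], "beta_convert"] = config.w_convert_apoe
        effects.loc[slot2[0], "beta_convert"] = -config.w_convert_apoe
        effects.loc[[slot4[0], slot2[0]], "causal"] = config.w_amyloid_apoe != 0 or config.w_convert_apoe != 0
    return effects


@dataclass
class PhenotypeSet:
    """Visit-level cohort table plus the per-subject generating truth."""

    cohort: pd.DataFrame  # IID, SEX, AGE, VISIT, DX, SUVR
    truth: pd.DataFrame  # per-subject latent quantities and true statuses


def gen_two_stage_phenotypes(
    dosages: DosageMatrix,
    effects: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeSet:
    """Realise the two-stage liability phenotype and visit trajectories.

    Amyloid positivity is a probit threshold on the amyloid-stage genetic
    score plus unit normal noise; conversion (defined among the
    amyloid-positive) is a second probit threshold on the conversion-stage
    score plus independent unit noise.  Clinical AD is amyloid positivity
    followed by conversion.  Trajectories over ``n_visits`` visits realise
    stable CN/MCI/AD subjects, MCI-to-AD converters, and small label-flip
    fractions of the atypical paths (CN->MCI, MCI->CN, AD->MCI).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    D = np.nan_to_num(dosages.dosages)
    n = dosages.n_samples
    ba = effects["beta_amyloid"].to_numpy()
    bc = effects["beta_convert"].to_numpy()
    if "is_apoe_slot" in dosages.variants.columns:
        is_apoe = dosages.variants["is_apoe_slot"].to_numpy()
    else:
        is_apoe = ba != 0
    g_amy = D @ ba
    g_conv_poly = D @ np.where(is_apoe, 0.0, bc)
    g_conv_apoe = D @ np.where(is_apoe, bc, 0.0)

    lia_amy = g_amy + rng.normal(size=n)
    thr_amy = float(np.quantile(lia_amy, config.amyloid_threshold_quantile))
    amyloid_pos = lia_amy > thr_amy
    if amyloid_pos.all() or not amyloid_pos.any():
        raise ValueError("amyloid threshold produced an empty group")

    lia_conv = g_conv_poly + g_conv_apoe + rng.normal(size=n)
    thr_conv = float(np.quantile(lia_conv[amyloid_pos], config.convert_threshold_quantile))
    converter = amyloid_pos & (lia_conv > thr_conv)
    if not converter.any() or converter.all():
        raise ValueError("conversion threshold produced an empty group")

    suvr = config.suvr_threshold + config.suvr_scale * (lia_amy - thr_amy)
    suvr = np.maximum(suvr, 0.05)  # PET ratios are positive; far-left tail clipped
    suvr_missing = rng.random(n) < config.suvr_missing_rate

    age = rng.uniform(55.0, 90.0, size=n)
    sex = rng.integers(0, 2, size=n)

    # trajectory archetypes
    u = rng.random(n)
    base = np.empty(n, dtype=object)
    final = np.empty(n, dtype=object)
    switch_visit = np.full(n, -1)
    prevalent = converter & (rng.random(n) < config.p_prevalent_ad)
    incident = converter & ~prevalent
    pos_nonconv = amyloid_pos & ~converter
    neg = ~amyloid_pos

    base[prevalent] = "AD"
    final[prevalent] = "AD"
    base[incident] = "MCI"
    final[incident] = "AD"
    if config.n_visits > 1:
        switch_visit[incident] = rng.integers(1, config.n_visits, size=int(incident.sum()))
    else:
        base[incident] = "AD"  # single-visit studies see converters as AD

    mci_flag = np.where(pos_nonconv, u < config.p_mci_given_positive, u < config.p_mci_given_negative)
    stable = pos_nonconv | neg
    base[stable & mci_flag] = "MCI"
    final[stable & mci_flag] = "MCI"
    base[stable & ~mci_flag] = "CN"
    final[stable & ~mci_flag] = "CN"

    # post-hoc label flips exercising the atypical trajectory classes
    if config.n_visits > 1:
        r = rng.random(n)
        cn = stable & ~mci_flag
        mci = stable & mci_flag
        final[cn & (r < config.flip_cn_to_mci)] = "MCI"
        final[mci & (r < config.flip_mci_to_cn)] = "CN"
        final[prevalent & (r < config.flip_ad_to_mci)] = "MCI"

    nv = config.n_visits
    vv = np.tile(np.arange(nv), n)
    sv = np.repeat(switch_visit, nv)
    dx = np.where(
        sv >= 0,
        np.where(vv >= sv, "AD", "MCI"),
        np.where(vv == nv - 1, np.repeat(final.astype(str), nv), np.repeat(base.astype(str), nv)),
    )
    cohort = pd.DataFrame(
        {
            "IID": np.repeat(dosages.samples, nv),
            "SEX": np.repeat(sex, nv).astype(int),
            "AGE": np.repeat(np.round(age, 1), nv),
            "VISIT": vv,
            "DX": dx,
            "SUVR": np.repeat(np.where(suvr_missing, np.nan, np.round(suvr, 4)), nv),
        }
    )

    truth = pd.DataFrame(
        {
            "IID": dosages.samples,
            "amyloid_liability": lia_amy,
            "conversion_liability": lia_conv,
            "polygenic_score": g_conv_poly,
            "amyloid_positive": amyloid_pos,
            "converter": converter,
            "ad_status": converter,  # clinical AD = converted (incl. prevalent)
            "suvr": suvr,
            "suvr_missing": suvr_missing,
            "age": age,
            "sex": sex,
        }
    )
    return PhenotypeSet(cohort=cohort, truth=truth)


def _logistic_gwas(X: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-8):
    """Per-column two-parameter logistic MLE, Newton-iterated in parallel.

    Fits ``logit P(y=1) = a_j + b_j x_j`` independently for every column of
    ``X`` at once.  Returns (beta, se, converged).
    """
    n, m = X.shape
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    ok = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        eta = a[None, :] + X * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y[:, None] - p
        u0 = r.sum(axis=0)
        u1 = (X * r).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * X).sum(axis=0)
        i11 = (w * X * X).sum(axis=0)
        det = i00 * i11 - i01 * i01
        det = np.where(det <= 0, np.nan, det)
        da = (i11 * u0 - i01 * u1) / det
        db = (i00 * u1 - i01 * u0) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        a += da
        b += db
        if np.max(np.abs(np.concatenate([da, db]))) < tol:
            break
    # final information for SE
    eta = a[None, :] + X * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    i00 = w.sum(axis=0)
    i01 = (w * X).sum(axis=0)
    i11 = (w * X * X).sum(axis=0)
    det = i00 * i11 - i01 * i01
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(i00 / det)
    ok &= np.isfinite(se) & (np.abs(b) < 15)
    return b, se, ok


def gen_discovery_sumstats(dosages: DosageMatrix, phenotype: np.ndarray) -> pd.DataFrame:
    """Single-SNP logistic GWAS of a binary phenotype on each variant.

    Returns the summary-statistic table (SNP, CHR, BP, A1 = counted
    alternate allele, A2, BETA, SE, P, FRQ, N); monomorphic and
    non-converged variants are excluded with a logged count.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("discovery phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("discovery phenotype is constant")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = np.nan_to_num(dosages.dosages)
    poly = X.std(axis=0) > 0
    beta = np.full(dosages.n_variants, np.nan)
    se = np.full(dosages.n_variants, np.nan)
    ok = np.zeros(dosages.n_variants, dtype=bool)
    b, s, conv = _logistic_gwas(X[:, poly], y)
    beta[poly], se[poly], ok[np.flatnonzero(poly)[conv]] = b, s, True
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("discovery GWAS: %d monomorphic/non-converged variants excluded", n_dropped)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "SNP": dosages.variants["id"].to_numpy(),
            "CHR": dosages.variants["chrom"].to_numpy(),
            "BP": dosages.variants["pos"].to_numpy(),
            "A1": dosages.variants["alt"].to_numpy(),
            "A2": dosages.variants["ref"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "P": np.clip(pval, np.nextafter(0, 1), 1.0),
            "FRQ": X.mean(axis=0) / 2.0,
            "N": len(y),
        }
    )
    return out[ok].reset_index(drop=True)


def gen_gene_annotation(
    variants: pd.DataFrame,
    n_sets: int = 9,
    set_sizes: tuple[int, ...] | None = None,
    seed: int = 0,
    genes_per_block: int = 2,
):
    """Gene intervals tiling the simulated chromosomes, plus gene sets.

    Each LD block is split into ``genes_per_block`` disjoint intervals that
    jointly cover it, so every variant lies inside exactly one gene.  The
    first gene set always contains the gene holding the APOE-like locus
    (the pathway-minus-APOE-region subtraction then has work to do); sets
    may share genes.  Default sizes echo an AD pathway collection
    (protein-lipid complex and related lipid/immune sets).
    """
    n_genes_total = genes_per_block * variants["block"].nunique()
    if set_sizes is None:
        set_sizes = (20, 10, 40, 12, 17, 35, 18, 11, 432)[:n_sets]
        set_sizes = tuple(min(s, max(2, n_genes_total // 3)) for s in set_sizes)
    if len(set_sizes) != n_sets:
        raise ValueError("set_sizes length must equal n_sets")
    rng = np.random.default_rng(seed)
    genes = []
    apoe_gene = None
    for (chrom, block), grp in variants.groupby(["chrom", "block"], sort=False):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        edges = np.linspace(lo - 1, hi, genes_per_block + 1).astype(int)
        for g in range(genes_per_block):
            name = f"GENE_b{block}_{g}"
            start, end = int(edges[g]) + 1, int(edges[g + 1])  # 1-based closed
            genes.append((name, str(chrom), start, end))
            if grp.get("is_apoe_slot", pd.Series(False, index=grp.index)).any():
                slots = grp.loc[grp["is_apoe_slot"], "pos"]
                if ((slots >= start) & (slots <= end)).any():
                    apoe_gene = name
    gene_df = pd.DataFrame(genes, columns=["gene", "chrom", "start", "end"])
    names = gene_df["gene"].to_numpy()
    # most genes belong to no annotated pathway: reserve a quarter of them
    # so the whole-genome-minus-pathways complement is never empty
    n_reserved = max(1, len(names) // 4)
    reserved = set(rng.choice(names, size=n_reserved, replace=False))
    reserved.discard(apoe_gene)
    eligible = np.array([g for g in names if g not in reserved])
    if any(s > len(eligible) for s in set_sizes):
        raise ValueError("set size exceeds the number of eligible genes")
    sets: dict[str, list[str]] = {}
    for k, size in enumerate(set_sizes):
        members = list(rng.choice(eligible, size=size, replace=False))
        if k == 0 and apoe_gene is not None and apoe_gene not in members:
            members[0] = apoe_gene
        sets[f"PATHWAY_{k + 1}"] = members
    return gene_df, sets


@dataclass
class SimStudy:
    """A complete synthetic study: genotypes, truth, phenotypes, sumstats."""

    config: SimConfig
    genotypes: DosageMatrix  # all samples (target first, then discovery pool)
    effects: pd.DataFrame
    phenotypes: PhenotypeSet  # all samples; restrict by the index arrays
    target_index: np.ndarray
    discovery_index: np.ndarray
    sumstats: pd.DataFrame
    genes: pd.DataFrame
    gene_sets: dict

    @property
    def target(self) -> DosageMatrix:
        return self.genotypes.subset_samples(self.target_index)

    @property
    def target_cohort(self) -> pd.DataFrame:
        ids = set(np.asarray(self.genotypes.samples)[self.target_index])
        return self.phenotypes.cohort[self.phenotypes.cohort["IID"].isin(ids)].reset_index(drop=True)

    @property
    def target_truth(self) -> pd.DataFrame:
        return self.phenotypes.truth.iloc[self.target_index].reset_index(drop=True)


def simulate_study(config: SimConfig) -> SimStudy:
    """Run the whole generator: genotypes, effects, phenotypes, GWAS, genes.

    The target cohort is the first ``n_target`` samples.  The discovery
    cohort takes ``n_overlap_cases`` AD cases and ``n_overlap_controls``
    non-cases from the target (shared subjects by construction) and fills
    the remainder from the dedicated discovery pool.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    geno = gen_ld_genotypes(config, rng=np.random.default_rng(rng.integers(2**31)))
    geno.variants["maf"] = geno.allele_frequency()
    geno.variants["maf"] = np.minimum(geno.variants["maf"], 1 - geno.variants["maf"])
    effects = plant_effects(geno.variants, config, rng=np.random.default_rng(rng.integers(2**31)))
    phen = gen_two_stage_phenotypes(geno, effects, config, rng=np.random.default_rng(rng.integers(2**31)))

    n_t = config.n_target
    target_index = np.arange(n_t)
    pool = np.arange(n_t, geno.n_samples)
    ad = phen.truth["ad_status"].to_numpy()
    ov_rng = np.random.default_rng(rng.integers(2**31))
    overlap = []
    if config.n_overlap_cases or config.n_overlap_controls:
        t_cases = np.flatnonzero(ad[:n_t])
        t_ctrls = np.flatnonzero(~ad[:n_t])
        if config.n_overlap_cases > len(t_cases) or config.n_overlap_controls > len(t_ctrls):
            raise ValueError("overlap counts exceed available target cases/controls")
        overlap = np.concatenate(
            [
                ov_rng.choice(t_cases, size=config.n_overlap_cases, replace=False),
                ov_rng.choice(t_ctrls, size=config.n_overlap_controls, replace=False),
            ]
        ).tolist()
    n_fill = config.n_discovery - len(overlap)
    discovery_index = np.concatenate([np.asarray(overlap, dtype=int), pool[:n_fill]])

    disc_geno = geno.subset_samples(discovery_index)
    disc_y = ad[discovery_index].astype(float)
    sumstats = gen_discovery_sumstats(disc_geno, disc_y)
    genes, gene_sets = gen_gene_annotation(geno.variants, seed=int(rng.integers(2**31)))
    return SimStudy(
        config=config,
        genotypes=geno,
        effects=effects,
        phenotypes=phen,
        target_index=target_index,
        discovery_index=discovery_index,
        sumstats=sumstats,
        genes=genes,
        gene_sets=gene_sets,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: copy a configuration with a new seed."""
    return replace(config, seed=int(seed))
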