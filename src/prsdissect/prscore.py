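"""Polygenic score construction.

Pipeline order is fixed: variant QC -> allele harmonization against the
discovery summary statistics -> p-value selection (p <= 0.5) -> greedy LD
clumping (r^2 >= 0.1 within a 1,000 kb window, keeping the most associated
variant) -> APOE-region exclusion (chr19:44,400,000-46,500,000) -> weighted
allele-dosage sum -> principal-component adjustment -> standardization.
The APOE epsilon2/epsilon4 alleles enter the full score directly, with
effect sizes estimated by joint logistic regression in the target cohort
(reference magnitudes -1.04 and +1.55 may be supplied as a fixed override).

Pathway-specific scores restrict the already-clumped genome-wide weight
table to variants inside member genes; the complement score uses all
clumped variants outside every pathway.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .synthio import DosageMatrix

log = logging.getLogger(__name__)

#: APOE region, 1-based closed, bp ("19:44,400-46,500 kb")
APOE_REGION = ("19", 44_400_000, 46_500_000)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# QC


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value for one bi-allelic SNP.

    Conditional on allele counts, sums the probabilities of all genotype
    configurations no more likely than the observed one (the standard
    exact-test convention for HWE).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # enumerate heterozygote counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    lp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    lp -= lp.max()
    p = np.exp(lp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class QCResult:
    keep: np.ndarray  # boolean mask over variants
    n_missingness: int
    n_hwe: int
    n_maf: int

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def variant_qc(
    dosages: DosageMatrix,
    max_missing: float = 0.02,
    hwe_min_p: float = 1e-6,
    min_maf: float = 0.01,
) -> QCResult:
    """Standard per-variant filters on hard-call dosages.

    Removes variants with genotype missingness > ``max_missing``, HWE exact
    p < ``hwe_min_p`` (tested in the full sample), or minor allele
    frequency < ``min_maf``; removal counts per filter are logged.
    """
    D = dosages.dosages
    n = D.shape[0]
    miss = np.isnan(D).mean(axis=0)
    freq = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.ones(D.shape[1])
    for j in range(D.shape[1]):
        col = D[:, j]
        col = col[np.isfinite(col)]
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        n_hom_ref = int((col == 0).sum())
        hwe_p[j] = hwe_exact_p(n_het, n_hom_ref, n_hom_alt)
    fail_miss = miss > max_missing
    fail_hwe = hwe_p < hwe_min_p
    fail_maf = ~(maf >= min_maf)  # catches NaN frequency too
    keep = ~(fail_miss | fail_hwe | fail_maf)
    res = QCResult(
        keep=keep,
        n_missingness=int(fail_miss.sum()),
        n_hwe=int(fail_hwe.sum()),
        n_maf=int(fail_maf.sum()),
    )
    log.info(
        "variant QC: kept %d/%d (missingness removed %d, HWE %d, MAF %d)",
        res.n_kept, D.shape[1], res.n_missingness, res.n_hwe, res.n_maf,
    )
    return res


# ---------------------------------------------------------------------------
# harmonization and selection


def match_alleles(variants: pd.DataFrame, sumstats: pd.DataFrame) -> pd.DataFrame:
    """Harmonize discovery weights onto target variants by chrom:pos.

    Exact allele match keeps the discovery beta as the weight on the target
    alternate-allele dosage; swapped alleles negate it; strand flips
    (complement alleles) are resolved the same way; palindromic A/T and C/G
    variants are dropped (strand unresolvable without frequencies), as are
    allele mismatches.  Returns the weight table (id, chrom, pos, weight,
    se, p) with drop counts logged.
    """
    t = variants[["id", "chrom", "pos", "ref", "alt"]].copy()
    t["chrom"] = t["chrom"].astype(str)
    s = sumstats.rename(columns={"CHR": "chrom", "BP": "pos"}).copy()
    s["chrom"] = s["chrom"].astype(str)
    merged = t.merge(s[["chrom", "pos", "A1", "A2", "BETA", "SE", "P"]], on=["chrom", "pos"], how="inner")

    ref, alt, a1, a2 = (merged[c].to_numpy() for c in ("ref", "alt", "A1", "A2"))
    comp = np.vectorize(lambda x: _COMPLEMENT.get(x, "N"))
    palindromic = (alt == comp(ref)) | (a1 == comp(a2))
    exact = (a1 == alt) & (a2 == ref)
    swapped = (a1 == ref) & (a2 == alt)
    flip_exact = (comp(a1) == alt) & (comp(a2) == ref)
    flip_swapped = (comp(a1) == ref) & (comp(a2) == alt)

    sign = np.where(exact | flip_exact, 1.0, np.where(swapped | flip_swapped, -1.0, np.nan))
    usable = ~palindromic & np.isfinite(sign)
    n_pal = int(palindromic.sum())
    n_mismatch = int((~palindromic & ~np.isfinite(sign)).sum())
    n_unmatched = len(t) - len(merged)
    log.info(
        "allele matching: %d matched, %d palindromic dropped, %d mismatched dropped, %d positions unmatched",
        int(usable.sum()), n_pal, n_mismatch, n_unmatched,
    )
    out = merged[usable].copy()
    out["weight"] = (merged["BETA"].to_numpy() * sign)[usable]
    out = out.rename(columns={"SE": "se", "P": "p"})
    return out[["id", "chrom", "pos", "ref", "alt", "weight", "se", "p"]].reset_index(drop=True)


def select_by_p(weights: pd.DataFrame, p_max: float = 0.5) -> pd.DataFrame:
    """Retain variants with discovery p <= p_max (inclusive)."""
    return weights[weights["p"] <= p_max].reset_index(drop=True)


def exclude_region(weights: pd.DataFrame, region: tuple[str, int, int] = APOE_REGION) -> pd.DataFrame:
    """Drop variants inside a 1-based closed chromosomal region."""
    chrom, start, end = region
    if start > end:
        raise ValueError("region start > end")
    inside = (
        (weights["chrom"].astype(str) == str(chrom))
        & (weights["pos"] >= start)
        & (weights["pos"] <= end)
    )
    return weights[~inside].reset_index(drop=True)


def ld_clump(
    weights: pd.DataFrame,
    dosages: DosageMatrix,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping, r^2 from target dosages.

    Repeatedly takes the unclaimed variant with the smallest discovery p as
    an index variant and removes every unclaimed variant on the same
    chromosome within ±``window_kb`` whose squared Pearson correlation of
    dosages with the index is >= ``r2_max``.  Ties on p break by
    (chromosome, position) ascending.  Only index variants are returned.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if weights.empty:
        return weights.copy()
    idx_in_dos = pd.Series(np.arange(dosages.n_variants), index=dosages.variants["id"])
    cols = idx_in_dos.reindex(weights["id"]).to_numpy()
    if np.isnan(cols).any():
        raise ValueError("weights contain variants absent from the dosage matrix")
    cols = cols.astype(int)
    D = dosages.dosages[:, cols]
    D = np.where(np.isnan(D), np.nanmean(D, axis=0, keepdims=True), D)
    Dc = D - D.mean(axis=0)
    norms = np.sqrt((Dc**2).sum(axis=0))
    norms[norms == 0] = np.nan

    order = np.lexsort(
        (weights["pos"].to_numpy(), weights["chrom"].astype(str).to_numpy(), weights["p"].to_numpy())
    )
    chrom = weights["chrom"].astype(str).to_numpy()
    pos = weights["pos"].to_numpy()
    window = window_kb * 1000.0
    claimed = np.zeros(len(weights), dtype=bool)
    kept = []
    for i in order:
        if claimed[i]:
            continue
        kept.append(i)
        claimed[i] = True
        near = (~claimed) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if near.any():
            j = np.flatnonzero(near)
            with np.errstate(invalid="ignore"):
                r = (Dc[:, j].T @ Dc[:, i]) / (norms[j] * norms[i])
            claimed[j[np.nan_to_num(r) ** 2 >= r2_max]] = True
    kept = sorted(kept)
    out = weights.iloc[kept].reset_index(drop=True)
    log.info("LD clumping: %d -> %d index variants (r2 >= %g within %g kb removed)",
             len(weights), len(out), r2_max, window_kb)
    return out


# ---------------------------------------------------------------------------
# APOE handling

#: (eps4-slot alt dosage, eps2-slot alt dosage) -> (eps2 count, eps4 count)
#: by maximum-parsimony haplotype assignment (epsilon1 minimised); the
#: doubly-heterozygous diplotype resolves as epsilon2/epsilon4.
_DIPLOTYPE = {
    (0, 0): (0, 0),  # e3/e3
    (0, 1): (1, 0),  # e2/e3
    (0, 2): (2, 0),  # e2/e2
    (1, 0): (0, 1),  # e3/e4
    (1, 1): (1, 1),  # e2/e4 (ambiguous with e1/e3; resolved as e2/e4)
    (1, 2): (1, 0),  # e1/e2
    (2, 0): (0, 2),  # e4/e4
    (2, 1): (0, 1),  # e1/e4
    (2, 2): (0, 0),  # e1/e1
}


def apoe_allele_counts(dosages: DosageMatrix, eps4_id: str, eps2_id: str) -> pd.DataFrame:
    """Map the two APOE-SNP genotypes to epsilon2/epsilon4 allele counts.

    ``eps4_id`` is the rs429358 analogue (alt C tags epsilon4) and
    ``eps2_id`` the rs7412 analogue (alt T tags epsilon2).  Subjects with a
    missing genotype at either SNP get missing counts.
    """
    ids = list(dosages.variants["id"])
    try:
        j4, j2 = ids.index(eps4_id), ids.index(eps2_id)
    except ValueError as e:
        raise ValueError("APOE-defining variant absent from the dosage matrix") from e
    d4, d2 = dosages.dosages[:, j4], dosages.dosages[:, j2]
    eps2 = np.full(len(d4), np.nan)
    eps4 = np.full(len(d4), np.nan)
    ok = np.isfinite(d4) & np.isfinite(d2)
    for (a, b), (e2, e4) in _DIPLOTYPE.items():
        m = ok & (d4 == a) & (d2 == b)
        eps2[m] = e2
        eps4[m] = e4
    return pd.DataFrame({"IID": dosages.samples, "EPS2": eps2, "EPS4": eps4})


def estimate_apoe_weights(y: np.ndarray, apoe: pd.DataFrame, penalized: bool = False) -> dict:
    """Joint logistic regression of case status on epsilon allele counts.

    Returns betas and SEs for epsilon2 and epsilon4; these become the APOE
    term of the full PRS (beta_eps2 * eps2 + beta_eps4 * eps4).  Perfect
    separation raises with advice to enable the ridge-penalized fallback
    (``penalized=True``) or fix the weights via the reference override.
    """
    X = sm.add_constant(apoe[["EPS2", "EPS4"]].to_numpy())
    yv = np.asarray(y, dtype=float)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
            ok = np.all(np.isfinite(fit.bse)) and np.all(np.abs(fit.params) < 30)
        except Exception:  # statsmodels raises PerfectSeparationError et al.
            fit, ok = None, False
    if not ok:
        if not penalized:
            raise RuntimeError(
                "APOE weight estimation failed (possible separation); retry "
                "with penalized=True or supply fixed reference weights, "
                "e.g. beta_eps2=-1.04, beta_eps4=1.55"
            )
        from .assoc import _ridge_logistic

        mf = _ridge_logistic(yv, apoe[["EPS2", "EPS4"]].to_numpy(dtype=float), ["EPS2", "EPS4"])
        b = mf.coef.set_index("name")
        return {
            "beta_eps2": float(b.loc["EPS2", "beta"]),
            "beta_eps4": float(b.loc["EPS4", "beta"]),
            "se_eps2": float(b.loc["EPS2", "se"]),
            "se_eps4": float(b.loc["EPS4", "se"]),
        }
    return {
        "beta_eps2": float(fit.params[1]),
        "beta_eps4": float(fit.params[2]),
        "se_eps2": float(fit.bse[1]),
        "se_eps4": float(fit.bse[2]),
    }


# ---------------------------------------------------------------------------
# scoring


def compute_raw_prs(dosages: DosageMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Weighted allele-dosage sum; missing dosages mean-imputed here only."""
    if weights.empty:
        raise ValueError("no overlapping variants to score")
    idx_in_dos = pd.Series(np.arange(dosages.n_variants), index=dosages.variants["id"])
    cols = idx_in_dos.reindex(weights["id"]).to_numpy()
    if np.isnan(cols).any():
        raise ValueError("weights contain variants absent from the dosage matrix")
    D = dosages.dosages[:, cols.astype(int)]
    D = np.where(np.isnan(D), np.nanmean(D, axis=0, keepdims=True), D)
    return D @ weights["weight"].to_numpy()


def compute_pcs(dosages: DosageMatrix, k: int = 8) -> np.ndarray:
    """Top-k principal components of the standardized dosage matrix.

    Variants are centred by 2f and scaled by sqrt(2f(1-f)); the returned
    n-by-k matrix has orthonormal columns (left singular vectors).
    """
    D = dosages.dosages
    D = np.where(np.isnan(D), np.nanmean(D, axis=0, keepdims=True), D)
    f = D.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * f * (1.0 - f))
    ok = denom > 0
    Z = (D[:, ok] - 2.0 * f[ok]) / denom[ok]
    if k > min(Z.shape):
        raise ValueError(f"k={k} exceeds the rank bound min{Z.shape}")
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    if k > np.sum(s > s[0] * 1e-12):
        raise ValueError(f"k={k} exceeds the numerical rank")
    return U[:, :k]


def adjust_standardize(scores: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize scores on covariates (with intercept), then z-score.

    Ordinary least squares; the result has sample mean 0 and SD 1 (ddof=1).
    Rank-deficient covariates are an error.
    """
    X = np.column_stack([np.ones(len(scores)), np.asarray(covariates)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, np.asarray(scores, dtype=float), rcond=None)
    resid = scores - X @ beta
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("score has zero residual variance")
    return resid / sd


# ---------------------------------------------------------------------------
# pathways


def snps_in_genes(weights: pd.DataFrame, genes: pd.DataFrame, members: list[str], flank_bp: int = 0) -> np.ndarray:
    """Boolean mask: weight-table variants inside any member gene interval."""
    sub = genes[genes["gene"].isin(members)]
    mask = np.zeros(len(weights), dtype=bool)
    chrom = weights["chrom"].astype(str).to_numpy()
    pos = weights["pos"].to_numpy()
    for _, g in sub.iterrows():
        mask |= (chrom == str(g["chrom"])) & (pos >= g["start"] - flank_bp) & (pos <= g["end"] + flank_bp)
    return mask


def pathway_partition(
    weights: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    genes: pd.DataFrame,
    drop_apoe: bool = False,
    flank_bp: int = 0,
    region: tuple[str, int, int] = APOE_REGION,
) -> dict[str, pd.DataFrame]:
    """Split a clumped weight table into per-pathway tables + complement.

    A variant belongs to a pathway iff its position lies within any member
    gene's interval (± ``flank_bp``); the complement holds every weight
    outside the union of all pathways.  With ``drop_apoe``, the APOE region
    is excluded from each pathway table first.  Gene-set members missing
    from the gene map are logged.
    """
    known = set(genes["gene"])
    union = np.zeros(len(weights), dtype=bool)
    out: dict[str, pd.DataFrame] = {}
    for name, members in gene_sets.items():
        unmapped = [g for g in members if g not in known]
        if unmapped:
            log.info("pathway %s: %d member genes not in the gene map", name, len(unmapped))
        mask = snps_in_genes(weights, genes, members, flank_bp=flank_bp)
        union |= mask
        table = weights[mask].reset_index(drop=True)
        out[name] = exclude_region(table, region) if drop_apoe else table
    out["_complement"] = weights[~union].reset_index(drop=True)
    return out
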