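"""Readers and writers for every on-disk format the pipeline touches.

Formats: GWAS summary-statistics TSV (CHR, BP, SNP, A1, A2, BETA, SE, P,
FRQ), VCF 4.2 with GT hard calls, BED gene intervals, GMT gene sets, and the
visit-level cohort TSV (IID, SEX, AGE, VISIT, DX, SUVR).

Conventions, stated once and used everywhere:

* internal coordinates are 1-based closed; BED's 0-based half-open
  intervals are converted at ingestion and on write, nowhere else;
* missing dosages stay missing at load time (mean imputation happens only
  at scoring time, so QC sees true missingness);
* no silent coercion — every dropped row is counted and logged.

All writer/reader pairs are mutually inverse on valid data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .synthio import DosageMatrix

log = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P")
COHORT_COLUMNS = ("IID", "SEX", "AGE", "VISIT", "DX")
DX_CODES = ("CN", "MCI", "AD")


class FormatError(ValueError):
    """A file violated the expectations of its format."""


# ---------------------------------------------------------------------------
# summary statistics


def load_sumstats(path) -> pd.DataFrame:
    """Load a summary-statistics TSV, validating and counting rejections.

    Rows with non-finite BETA/SE, SE <= 0, or P outside (0, 1] are dropped
    (counted in the log); duplicate variant keys (CHR:BP:A1:A2) are a hard
    error, as is a missing required column or an empty usable table.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str}, na_values=["NA", "nan", ""])
    for col in SUMSTAT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"summary statistics file is missing required column {col!r}")
    n0 = len(df)
    numeric = df[["BP", "BETA", "SE", "P"]].apply(pd.to_numeric, errors="coerce")
    df[["BP", "BETA", "SE", "P"]] = numeric
    good = (
        np.isfinite(numeric["BETA"])
        & np.isfinite(numeric["SE"])
        & (numeric["SE"] > 0)
        & (numeric["P"] > 0)
        & (numeric["P"] <= 1)
        & np.isfinite(numeric["BP"])
    )
    dropped = int(n0 - good.sum())
    if dropped:
        log.info("load_sumstats: dropped %d/%d invalid rows", dropped, n0)
    df = df[good].reset_index(drop=True)
    if df.empty:
        raise FormatError("summary statistics file has zero usable rows")
    key = df["CHR"].astype(str) + ":" + df["BP"].astype(int).astype(str) + ":" + df["A1"] + ":" + df["A2"]
    if key.duplicated().any():
        raise FormatError("duplicate variant keys in summary statistics")
    df["BP"] = df["BP"].astype(int)
    df.attrs["n_dropped"] = dropped
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# VCF


def load_dosages(path, split_multiallelic: bool = False) -> DosageMatrix:
    """Read GT hard calls from a VCF into an additive dosage matrix.

    Dosage is the count of alternate alleles; missing genotypes stay NaN
    (they are excluded from allele-frequency denominators, not zeroed).
    Multi-allelic records are rejected unless ``split_multiallelic``.
    """
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if not split_multiallelic:
                raise FormatError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                    "pass split_multiallelic=True or normalise the VCF first"
                )
            n_multi += 1
            continue
        gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan  # cyvcf2 encodes missing alleles as -1
        dos = (gt > 0).astype(float).sum(axis=1)
        dos[np.isnan(gt).any(axis=1)] = np.nan
        rows.append(dos)
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if n_multi:
        log.info("load_dosages: skipped %d multi-allelic records", n_multi)
    if not rows:
        raise FormatError("VCF contains no usable bi-allelic records")
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return DosageMatrix(samples=samples, variants=variants, dosages=np.asarray(rows).T)


def write_vcf(dosages: DosageMatrix, path) -> None:
    """Write hard-call dosages as an uncompressed GT-only VCF 4.2 file."""
    v = dosages.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chrom"]):
            length = int(v.loc[v["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, dosages.samples)) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(dosages.n_variants):
            row = v.iloc[j]
            calls = [gt_map.get(d, "./.") if np.isfinite(d) else "./." for d in dosages.dosages[:, j]]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# genes and gene sets


def load_gene_intervals(path) -> pd.DataFrame:
    """Load a BED file of gene intervals into 1-based closed coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start0", "end0", "gene"], usecols=[0, 1, 2, 3],
        dtype={0: str},
    )
    if (df["start0"] > df["end0"]).any():
        bad = df[df["start0"] > df["end0"]].iloc[0]
        raise FormatError(f"BED interval with start > end for {bad['gene']}")
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "chrom": df["chrom"].astype(str),
            "start": df["start0"].astype(int) + 1,  # 0-based half-open -> 1-based closed
            "end": df["end0"].astype(int),
        }
    )
    return out


def write_gene_intervals(genes: pd.DataFrame, path) -> None:
    """Write 1-based closed gene intervals as 0-based half-open BED."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start0": genes["start"].astype(int) - 1,
            "end0": genes["end"].astype(int),
            "gene": genes["gene"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def load_gene_sets(path) -> dict[str, list[str]]:
    """Load a GMT file (set name, description, member genes per line)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {ln}: expected >= 3 tab-separated fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gene_sets(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# cohort


def load_cohort(path) -> pd.DataFrame:
    """Load the visit-level cohort TSV, sorted by (IID, VISIT).

    Diagnosis codes are restricted to CN/MCI/AD; an unknown code or a
    duplicate (IID, VISIT) pair is a hard error.  SUVR is optional.
    """
    df = pd.read_csv(path, sep="\t", dtype={"IID": str}, na_values=["NA", ""])
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cohort file is missing required column {col!r}")
    bad_dx = set(df["DX"].unique()) - set(DX_CODES)
    if bad_dx:
        raise FormatError(f"unknown diagnosis code(s): {sorted(bad_dx)}")
    if df.duplicated(subset=["IID", "VISIT"]).any():
        raise FormatError("duplicate (IID, VISIT) records in cohort file")
    if "SUVR" not in df.columns:
        df["SUVR"] = np.nan
    return df.sort_values(["IID", "VISIT"], kind="mergesort").reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
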