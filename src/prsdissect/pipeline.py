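"""End-to-end orchestration: synthesize a study, build scores, fit models.

Two entry points:

* :func:`analyze_study` — the in-memory pipeline on a simulated (or
  externally assembled) study: QC -> harmonize -> select -> clump ->
  APOE-region exclusion -> score -> PCs -> standardize -> contrasts ->
  model battery (optionally pathway scores and the extremes analysis);
* :func:`run_pipeline` — the same pipeline driven by a file-based
  :class:`RunConfig`, writing score/label TSVs, report tables and a
  provenance manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cohort as cohort_mod, ioformats, overlapsim, prscore
from .synthio import SimConfig, SimStudy, simulate_study

log = logging.getLogger(__name__)

CONTRAST_NAMES = ("ad", "mci", "amyloid", "conversion")


@dataclass
class PipelineParams:
    """Scoring-pipeline knobs (defaults follow the reference analysis)."""

    p_max: float = 0.5
    r2_max: float = 0.1
    window_kb: float = 1000.0
    n_pcs: int = 8
    apoe_region: tuple = prscore.APOE_REGION
    extremes_sd: float = 1.5
    max_missing: float = 0.02
    hwe_min_p: float = 1e-6
    min_maf: float = 0.01
    apoe_weights_override: tuple[float, float] | None = None  # (beta_eps2, beta_eps4)
    flank_bp: int = 0


@dataclass
class AnalysisResult:
    """Everything the analysis computes, keyed for reporting."""

    scores: pd.DataFrame  # IID, PRS_RAW, PRS, EPS2, EPS4, SEX, AGE
    labels: pd.DataFrame
    amyloid: pd.DataFrame
    contrasts: dict
    batteries: dict[str, assoc.BatteryResult]
    extremes: dict[str, assoc.BatteryResult]
    apoe_weights: dict
    weights: pd.DataFrame  # final clumped non-APOE weight table
    pathways: dict[str, pd.DataFrame] = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def _battery_frame(scores: pd.DataFrame, con) -> tuple[np.ndarray, pd.DataFrame]:
    sub = scores.set_index("IID").loc[con.ids].reset_index()
    return con.y, sub


def analyze_study(
    study: SimStudy,
    params: PipelineParams | None = None,
    pathways: bool = False,
    extremes: bool = True,
    contrasts: tuple[str, ...] = CONTRAST_NAMES,
) -> AnalysisResult:
    """Run the full analysis on a synthetic study object."""
    params = params or PipelineParams()
    target = study.target
    counts: dict = {"n_variants": target.n_variants}

    # QC on the target genotypes
    qc = prscore.variant_qc(target, params.max_missing, params.hwe_min_p, params.min_maf)
    geno = target.subset_variants(qc.keep)
    counts.update(qc_kept=qc.n_kept, qc_removed_missing=qc.n_missingness,
                  qc_removed_hwe=qc.n_hwe, qc_removed_maf=qc.n_maf)

    # cohort labels and amyloid status
    labels = cohort_mod.classify_trajectory(study.target_cohort)
    amyloid = cohort_mod.assign_amyloid(study.target_cohort)
    built = cohort_mod.build_contrasts(labels, amyloid)
    cons = {k: v for k, v in built.items() if k in contrasts}

    # weights: harmonize -> p-select -> clump -> APOE-region exclusion
    weights = prscore.match_alleles(geno.variants, study.sumstats)
    counts["matched"] = len(weights)
    weights = prscore.select_by_p(weights, params.p_max)
    counts["p_selected"] = len(weights)
    clumped = prscore.ld_clump(weights, geno, params.r2_max, params.window_kb)
    counts["clumped"] = len(clumped)
    weights_no_apoe = prscore.exclude_region(clumped, params.apoe_region)
    counts["after_region_exclusion"] = len(weights_no_apoe)

    # APOE epsilon counts and weights from the AD-vs-control contrast
    slot = study.genotypes.variants[study.genotypes.variants["is_apoe_slot"]]
    eps4_id = slot.loc[slot["alt"] == "C", "id"].iloc[0]
    eps2_id = slot.loc[slot["alt"] == "T", "id"].iloc[0]
    apoe = prscore.apoe_allele_counts(target, eps4_id, eps2_id)
    if params.apoe_weights_override is not None:
        b2, b4 = params.apoe_weights_override
        apoe_w = {"beta_eps2": b2, "beta_eps4": b4, "se_eps2": np.nan, "se_eps4": np.nan}
    else:
        ad_con = built["ad"]
        apoe_sub = apoe.set_index("IID").loc[ad_con.ids]
        apoe_w = prscore.estimate_apoe_weights(ad_con.y, apoe_sub.reset_index(), penalized=True)

    # scores
    raw = prscore.compute_raw_prs(geno, weights_no_apoe)
    pcs = prscore.compute_pcs(geno.subset_variants(
        geno.variants["id"].isin(clumped["id"]).to_numpy()), k=params.n_pcs)
    std = prscore.adjust_standardize(raw, pcs)

    demo = study.target_truth[["IID", "sex", "age"]].rename(columns={"sex": "SEX", "age": "AGE"})
    scores = pd.DataFrame({"IID": target.samples, "PRS_RAW": raw, "PRS": std})
    scores = scores.merge(apoe, on="IID").merge(demo, on="IID")

    batteries: dict[str, assoc.BatteryResult] = {}
    extreme_batteries: dict[str, assoc.BatteryResult] = {}
    for name, con in cons.items():
        y, frame = _battery_frame(scores, con)
        batteries[name] = assoc.run_model_battery(y, frame, name)
        if extremes and name in ("ad", "mci"):
            mask = assoc.extreme_subset(frame["PRS"].to_numpy(), params.extremes_sd)
            if mask.sum() and 0 < y[mask].sum() < mask.sum():
                try:
                    extreme_batteries[name] = assoc.run_model_battery(
                        y[mask], frame[mask].reset_index(drop=True), f"{name}_extremes")
                except (RuntimeError, ValueError) as e:
                    log.warning("extremes battery for %s skipped: %s", name, e)

    result = AnalysisResult(
        scores=scores, labels=labels, amyloid=amyloid, contrasts=cons,
        batteries=batteries, extremes=extreme_batteries, apoe_weights=apoe_w,
        weights=weights_no_apoe, counts=counts,
    )

    if pathways:
        result.pathways = _pathway_scores(study, geno, clumped, scores, params, built)
    return result


def _pathway_scores(study, geno, clumped, scores, params, contrasts_all):
    """Pathway-partitioned scores and their per-contrast association tables."""
    part = prscore.pathway_partition(clumped, study.gene_sets, study.genes, drop_apoe=False,
                                     flank_bp=params.flank_bp, region=params.apoe_region)
    part_no = prscore.pathway_partition(clumped, study.gene_sets, study.genes, drop_apoe=True,
                                        flank_bp=params.flank_bp, region=params.apoe_region)
    pcs = prscore.compute_pcs(geno.subset_variants(
        geno.variants["id"].isin(clumped["id"]).to_numpy()), k=params.n_pcs)

    def _score_tables(partition, frame):
        cols = {}
        for name, w in partition.items():
            if len(w) == 0:
                continue
            raw = prscore.compute_raw_prs(geno, w)
            # pathway scores adjust for PCs plus age and sex, then standardize
            cov = np.column_stack([pcs, frame["SEX"].to_numpy(), frame["AGE"].to_numpy()])
            cols[name] = prscore.adjust_standardize(raw, cov)
        return pd.DataFrame(cols, index=frame.index)

    ps = _score_tables(part, scores)
    ps_no = _score_tables(part_no, scores)
    counts = {k: len(v) for k, v in part.items()}
    counts_no = {k: len(v) for k, v in part_no.items()}

    out = {}
    for cname in ("ad", "amyloid", "conversion"):
        con = contrasts_all[cname]
        pos = scores.set_index("IID").index.get_indexer(con.ids)
        base = scores.iloc[pos].reset_index(drop=True)
        table = assoc.run_pathway_battery(
            con.y, base,
            ps.iloc[pos].reset_index(drop=True),
            ps_no.iloc[pos].reset_index(drop=True),
            counts, counts_no,
        )
        out[cname] = table
    return out


# ---------------------------------------------------------------------------
# file-based run


@dataclass
class RunConfig:
    """Paths + parameters for a file-driven pipeline run."""

    vcf: str
    sumstats: str
    cohort: str
    outdir: str
    genes: str | None = None
    gene_sets: str | None = None
    eps4_id: str = ""
    eps2_id: str = ""
    contrasts: tuple[str, ...] = CONTRAST_NAMES
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0
    pathways: bool = False

    def validate(self) -> None:
        for name in ("vcf", "sumstats", "cohort"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: no such file {p}")
        if self.pathways:
            for name in ("genes", "gene_sets"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"pathways enabled but config field {name!r} is unset")
                if not Path(p).exists():
                    raise FileNotFoundError(f"config field {name!r}: no such file {p}")
        if not self.eps4_id or not self.eps2_id:
            raise ValueError("config fields eps4_id and eps2_id must name the APOE-coding SNPs")


def synthesize(config: SimConfig, outdir) -> dict:
    """Generate a study and write every file format to ``outdir``.

    Emits target/discovery VCFs, the summary-statistics TSV, the visit-level
    cohort TSV, gene BED, pathway GMT and a manifest recording the seed and
    all parameters.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    ioformats.write_vcf(study.target, outdir / "target.vcf")
    ioformats.write_vcf(study.genotypes.subset_samples(study.discovery_index), outdir / "discovery.vcf")
    ioformats.write_sumstats(study.sumstats, outdir / "sumstats.tsv")
    ioformats.write_cohort(study.target_cohort, outdir / "cohort.tsv")
    ioformats.write_gene_intervals(study.genes, outdir / "genes.bed")
    ioformats.write_gene_sets(study.gene_sets, outdir / "pathways.gmt")
    slot = study.genotypes.variants[study.genotypes.variants["is_apoe_slot"]]
    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "eps4_id": slot.loc[slot["alt"] == "C", "id"].iloc[0],
        "eps2_id": slot.loc[slot["alt"] == "T", "id"].iloc[0],
        "files": ["target.vcf", "discovery.vcf", "sumstats.tsv", "cohort.tsv",
                  "genes.bed", "pathways.gmt"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-driven pipeline: load, score, fit, and write all reports."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params

    target = ioformats.load_dosages(config.vcf)
    sumstats = ioformats.load_sumstats(config.sumstats)
    cohort_df = ioformats.load_cohort(config.cohort)

    counts: dict = {"n_variants": target.n_variants}
    qc = prscore.variant_qc(target, params.max_missing, params.hwe_min_p, params.min_maf)
    geno = target.subset_variants(qc.keep)
    counts.update(qc_kept=qc.n_kept)

    labels = cohort_mod.classify_trajectory(cohort_df)
    amyloid = cohort_mod.assign_amyloid(cohort_df)
    built = cohort_mod.build_contrasts(labels, amyloid)
    cons = {k: v for k, v in built.items() if k in config.contrasts}

    weights = prscore.match_alleles(geno.variants, sumstats)
    weights = prscore.select_by_p(weights, params.p_max)
    clumped = prscore.ld_clump(weights, geno, params.r2_max, params.window_kb)
    weights_no_apoe = prscore.exclude_region(clumped, params.apoe_region)
    counts.update(matched=len(weights), clumped=len(clumped),
                  after_region_exclusion=len(weights_no_apoe))

    apoe = prscore.apoe_allele_counts(target, config.eps4_id, config.eps2_id)
    if params.apoe_weights_override is not None:
        b2, b4 = params.apoe_weights_override
        apoe_w = {"beta_eps2": b2, "beta_eps4": b4, "se_eps2": np.nan, "se_eps4": np.nan}
    else:
        ad_con = built["ad"]
        apoe_sub = apoe.set_index("IID").loc[ad_con.ids]
        apoe_w = prscore.estimate_apoe_weights(ad_con.y, apoe_sub.reset_index(), penalized=True)

    raw = prscore.compute_raw_prs(geno, weights_no_apoe)
    pcs = prscore.compute_pcs(geno.subset_variants(
        geno.variants["id"].isin(clumped["id"]).to_numpy()), k=params.n_pcs)
    std = prscore.adjust_standardize(raw, pcs)

    demo = (cohort_df.sort_values(["IID", "VISIT"]).groupby("IID", sort=True)
            .first().reset_index()[["IID", "SEX", "AGE"]])
    scores = pd.DataFrame({"IID": target.samples, "PRS_RAW": raw, "PRS": std})
    scores = scores.merge(apoe, on="IID").merge(demo, on="IID")

    batteries, extreme_batteries = {}, {}
    for name, con in cons.items():
        y, frame = _battery_frame(scores, con)
        batteries[name] = assoc.run_model_battery(y, frame, name)
        if name in ("ad", "mci"):
            mask = assoc.extreme_subset(frame["PRS"].to_numpy(), params.extremes_sd)
            if mask.sum() and 0 < y[mask].sum() < mask.sum():
                try:
                    extreme_batteries[name] = assoc.run_model_battery(
                        y[mask], frame[mask].reset_index(drop=True), f"{name}_extremes")
                except (RuntimeError, ValueError) as e:
                    log.warning("extremes battery for %s skipped: %s", name, e)

    result = AnalysisResult(
        scores=scores, labels=labels, amyloid=amyloid, contrasts=cons,
        batteries=batteries, extremes=extreme_batteries, apoe_weights=apoe_w,
        weights=weights_no_apoe, counts=counts,
    )
    write_reports(result, outdir, seed=config.seed, params=params)
    return result


def write_reports(result: AnalysisResult, outdir, seed: int = 0, params: PipelineParams | None = None) -> None:
    """Write scores, labels, battery tables and the provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = ["IID", "PRS_RAW", "PRS", "EPS2", "EPS4"]
    result.scores[cols].to_csv(outdir / "scores.tsv", sep="\t", index=False, float_format="%.10g")
    cohort_mod.write_labels(result.labels, result.amyloid, outdir / "labels.tsv")
    blocks = [b.summary() for b in result.batteries.values()]
    blocks += [b.summary() for b in result.extremes.values()]
    if blocks:
        pd.concat(blocks, ignore_index=True).to_csv(outdir / "model_battery.tsv", sep="\t", index=False, float_format="%.6g")
    for cname, table in result.pathways.items():
        table.to_csv(outdir / f"pathways_{cname}.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {
        "seed": seed,
        "params": asdict(params) if params is not None else None,
        "counts": result.counts,
        "apoe_weights": result.apoe_weights,
        "contrast_sizes": {k: [c.n_case, c.n_control] for k, c in result.contrasts.items()},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
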