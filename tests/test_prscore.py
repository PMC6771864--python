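"""Score construction: QC, harmonization, clumping, APOE, PCs, pathways."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsdissect import prscore
from prsdissect.synthio import DosageMatrix, SimConfig, gen_ld_genotypes


def _dm(dosages, chrom=None, pos=None, ref=None, alt=None, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": ids or [f"v{j}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "pos": pos or list(range(100, 100 + m)),
            "ref": ref or ["A"] * m,
            "alt": alt or ["G"] * m,
        }
    )
    return DosageMatrix(
        samples=np.array([f"S{i}" for i in range(n)]), variants=variants, dosages=dosages
    )


# ---------------------------------------------------------------------------
# HWE exact test


def hwe_oracle(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Independent enumeration with exact rational arithmetic."""
    from math import factorial

    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    denom = comb(2 * n, n_rare)
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        r_hom = (n_rare - h) // 2
        c_hom = n - h - r_hom
        if c_hom < 0:
            continue
        multinom = factorial(n) // (factorial(h) * factorial(r_hom) * factorial(c_hom))
        probs[h] = Fraction(2**h * multinom, denom)
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize(
    "het, hom1, hom2",
    [(0, 50, 50), (25, 25, 50), (10, 5, 3), (57, 14, 50), (1, 0, 1), (0, 10, 0)],
)
def test_hwe_exact_matches_enumeration_oracle(het, hom1, hom2):
    assert prscore.hwe_exact_p(het, hom1, hom2) == pytest.approx(
        hwe_oracle(het, hom1, hom2), rel=1e-9
    )


def test_hwe_extreme_deficit_is_tiny():
    """50/0/50 has a vanishing heterozygote count under HWE."""
    assert prscore.hwe_exact_p(0, 50, 50) < 1e-25


class TestVariantQC:
    def test_excess_missingness_removed(self, rng):
        d = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
        d[:6, 0] = np.nan  # 3% missing
        res = prscore.variant_qc(_dm(d))
        assert not res.keep[0] and res.keep[1]
        assert res.n_missingness == 1

    def test_monomorphic_removed(self, rng):
        d = np.column_stack([np.zeros(300), rng.binomial(2, 0.4, 300)]).astype(float)
        res = prscore.variant_qc(_dm(d))
        assert not res.keep[0] and res.keep[1]

    def test_hwe_violation_removed(self, rng):
        bad = np.concatenate([np.zeros(150), np.full(150, 2.0)])  # no hets
        good = rng.binomial(2, 0.4, 300).astype(float)
        res = prscore.variant_qc(_dm(np.column_stack([bad, good])))
        assert not res.keep[0] and res.keep[1]
        assert res.n_hwe >= 1

    def test_rare_variant_removed(self, rng):
        rare = np.zeros(300)
        rare[0] = 1.0  # MAF 1/600 < 0.01
        good = rng.binomial(2, 0.4, 300).astype(float)
        res = prscore.variant_qc(_dm(np.column_stack([rare, good])))
        assert not res.keep[0] and res.keep[1]


# ---------------------------------------------------------------------------
# harmonization


class TestMatchAlleles:
    def _sumstats(self, rows):
        return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"])

    def test_exact_and_swapped(self):
        variants = _dm(np.zeros((2, 2)), ref=["G", "G"], alt=["A", "A"], pos=[100, 101]).variants
        ss = self._sumstats(
            [("v0", "1", 100, "A", "G", 0.1, 0.05, 0.01),
             ("v1", "1", 101, "G", "A", 0.1, 0.05, 0.01)]
        )
        w = prscore.match_alleles(variants, ss)
        assert w.loc[w["id"] == "v0", "weight"].iloc[0] == pytest.approx(0.1)
        assert w.loc[w["id"] == "v1", "weight"].iloc[0] == pytest.approx(-0.1)

    def test_strand_flip_resolved(self):
        variants = _dm(np.zeros((2, 1)), ref=["G"], alt=["A"]).variants
        # discovery reports the other strand: T/C complement of A/G
        ss = self._sumstats([("v0", "1", 100, "T", "C", 0.2, 0.05, 0.01)])
        w = prscore.match_alleles(variants, ss)
        assert w["weight"].iloc[0] == pytest.approx(0.2)

    def test_palindromic_dropped_counting_fixture(self):
        refs = ["A", "A", "A", "A", "A", "C", "C", "C", "A", "C"]
        alts = ["G", "G", "G", "G", "G", "T", "T", "T", "T", "G"]  # last two palindromic
        variants = _dm(np.zeros((2, 10)), ref=refs, alt=alts,
                       pos=list(range(100, 110))).variants
        ss = self._sumstats(
            [(f"v{j}", "1", 100 + j, alts[j], refs[j], 0.1, 0.05, 0.01) for j in range(10)]
        )
        w = prscore.match_alleles(variants, ss)
        assert len(w) == 8

    def test_mismatched_alleles_dropped(self):
        variants = _dm(np.zeros((2, 1)), ref=["G"], alt=["A"]).variants
        ss = self._sumstats([("v0", "1", 100, "C", "G", 0.2, 0.05, 0.01)])
        assert len(prscore.match_alleles(variants, ss)) == 0


def test_select_by_p_inclusive_boundary():
    w = pd.DataFrame({"p": [0.5, 0.500001, 0.1, 1.0]})
    out = prscore.select_by_p(w, 0.5)
    assert list(out["p"]) == [0.5, 0.1]
    assert len(prscore.select_by_p(w, 1.0)) == 4


def test_select_by_p_uniform_null_rate(rng):
    w = pd.DataFrame({"p": rng.uniform(size=10_000)})
    kept = len(prscore.select_by_p(w, 0.5))
    assert abs(kept - 5_000) < 3 * np.sqrt(10_000 * 0.25)


class TestExcludeRegion:
    region = ("19", 44_400_000, 46_500_000)

    @pytest.mark.parametrize(
        "chrom, pos, kept",
        [("19", 45_000_000, False), ("19", 44_399_999, True),
         ("19", 44_400_000, False), ("19", 46_500_000, False),
         ("19", 46_500_001, True), ("1", 45_000_000, True)],
    )
    def test_boundaries(self, chrom, pos, kept):
        w = pd.DataFrame({"id": ["v"], "chrom": [chrom], "pos": [pos], "weight": [1.0]})
        out = prscore.exclude_region(w, self.region)
        assert (len(out) == 1) is kept


# ---------------------------------------------------------------------------
# LD clumping vs brute-force oracle


def clump_oracle(weights: pd.DataFrame, dosages: DosageMatrix, r2_max, window_kb):
    """Direct greedy reference: full r2 matrix, explicit scan."""
    idx = {v: j for j, v in enumerate(dosages.variants["id"])}
    D = dosages.dosages[:, [idx[v] for v in weights["id"]]]
    D = np.where(np.isnan(D), np.nanmean(D, axis=0, keepdims=True), D)
    with np.errstate(invalid="ignore"):
        r2 = np.corrcoef(D.T) ** 2
    r2 = np.nan_to_num(np.atleast_2d(r2))
    order = sorted(
        range(len(weights)),
        key=lambda i: (weights["p"].iat[i], str(weights["chrom"].iat[i]), weights["pos"].iat[i]),
    )
    removed = set()
    kept = []
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in range(len(weights)):
            if j in removed or j == i:
                continue
            same_chrom = str(weights["chrom"].iat[j]) == str(weights["chrom"].iat[i])
            close = abs(weights["pos"].iat[j] - weights["pos"].iat[i]) <= window_kb * 1000
            if same_chrom and close and r2[i, j] >= r2_max:
                removed.add(j)
    return weights.iloc[sorted(kept)].reset_index(drop=True)


def _random_instance(rng, m, n=60):
    cfg = SimConfig(
        seed=int(rng.integers(2**31)), n_target=n, n_discovery=5,
        n_blocks=max(2, m // 8), snps_per_block=8, n_causal=0, ld_decay=0.5,
    )
    g = gen_ld_genotypes(cfg)
    take = rng.choice(g.n_variants, size=min(m, g.n_variants), replace=False)
    g = g.subset_variants(np.sort(take))
    w = g.variants[["id", "chrom", "pos"]].copy()
    w["weight"] = rng.normal(size=len(w))
    w["p"] = rng.uniform(size=len(w))
    # inject p ties to exercise the tie-break rule
    if len(w) > 4:
        w.loc[w.index[:3], "p"] = 0.25
    return w, g


def test_clump_keeps_most_associated_within_window():
    d = np.array([[0, 0], [1, 1], [2, 2], [0, 1], [2, 1], [1, 0]], dtype=float)
    w = pd.DataFrame({"id": ["a", "b"], "chrom": ["1", "1"],
                      "pos": [1_000_000, 1_500_000], "p": [1e-8, 1e-4]})
    out = prscore.ld_clump(w, _dm(d, pos=[1_000_000, 1_500_000], ids=["a", "b"]))
    assert list(out["id"]) == ["a"]


def test_clump_window_semantics():
    d = np.tile(np.array([[0.0], [1.0], [2.0], [1.0]]), (1, 2))  # r2 = 1
    w = pd.DataFrame({"id": ["a", "b"], "chrom": ["1", "1"],
                      "pos": [1_000_000, 2_500_001], "p": [1e-8, 1e-4]})
    out = prscore.ld_clump(w, _dm(d, pos=[1_000_000, 2_500_001], ids=["a", "b"]))
    assert list(out["id"]) == ["a", "b"]  # 1,500.001 kb apart: outside the window


def test_clump_parameter_validation(small_study):
    w = pd.DataFrame({"id": [], "chrom": [], "pos": [], "p": []})
    with pytest.raises(ValueError):
        prscore.ld_clump(w, small_study.target, r2_max=0.0)
    with pytest.raises(ValueError):
        prscore.ld_clump(w, small_study.target, window_kb=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=5, max_value=120))
def test_clump_equals_bruteforce_oracle(seed, m):
    rng = np.random.default_rng(seed)
    w, g = _random_instance(rng, m)
    ours = prscore.ld_clump(w, g, r2_max=0.1, window_kb=1000)
    ref = clump_oracle(w, g, r2_max=0.1, window_kb=1000)
    pd.testing.assert_frame_equal(ours, ref)


# ---------------------------------------------------------------------------
# APOE


class TestApoeCounts:
    @pytest.mark.parametrize(
        "d4, d2, eps2, eps4",
        [
            (2, 0, 0, 2),  # e4/e4
            (0, 2, 2, 0),  # e2/e2
            (1, 1, 1, 1),  # double het resolved as e2/e4
            (0, 0, 0, 0),  # e3/e3
            (0, 1, 1, 0),  # e2/e3
            (1, 0, 0, 1),  # e3/e4
            (2, 1, 0, 1),  # e1/e4: the e1 haplotype counts as neither
            (1, 2, 1, 0),  # e1/e2
        ],
    )
    def test_diplotype_table(self, d4, d2, eps2, eps4):
        dm = _dm(np.array([[d4, d2]], dtype=float), ref=["T", "C"], alt=["C", "T"],
                 ids=["rs429358L", "rs7412L"])
        out = prscore.apoe_allele_counts(dm, "rs429358L", "rs7412L")
        assert out.loc[0, "EPS2"] == eps2
        assert out.loc[0, "EPS4"] == eps4
        assert out.loc[0, "EPS2"] + out.loc[0, "EPS4"] <= 2

    def test_missing_genotype_gives_missing_counts(self):
        dm = _dm(np.array([[np.nan, 1.0]]), ids=["a", "b"])
        out = prscore.apoe_allele_counts(dm, "a", "b")
        assert np.isnan(out.loc[0, "EPS2"]) and np.isnan(out.loc[0, "EPS4"])

    def test_absent_variant_rejected(self):
        dm = _dm(np.zeros((2, 1)), ids=["a"])
        with pytest.raises(ValueError):
            prscore.apoe_allele_counts(dm, "a", "zzz")

    def test_counts_match_haplotype_truth(self, small_study):
        """Genotype-level counting agrees with epsilon-frequency expectations."""
        v = small_study.genotypes.variants
        eps4_id = v.loc[v["is_apoe_slot"] & (v["alt"] == "C"), "id"].iloc[0]
        eps2_id = v.loc[v["is_apoe_slot"] & (v["alt"] == "T"), "id"].iloc[0]
        out = prscore.apoe_allele_counts(small_study.genotypes, eps4_id, eps2_id)
        n_hap = 2 * len(out)
        f2, f4 = out["EPS2"].sum() / n_hap, out["EPS4"].sum() / n_hap
        assert abs(f2 - 0.08) < 0.02
        assert abs(f4 - 0.15) < 0.02


class TestApoeWeights:
    def _simulate(self, rng, n, b2, b4):
        eps2 = rng.binomial(2, 0.08, n)
        eps4 = rng.binomial(2, 0.15, n)
        eta = -0.5 + b2 * eps2 + b4 * eps4
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return pd.DataFrame({"IID": np.arange(n).astype(str), "EPS2": eps2, "EPS4": eps4}), y

    def test_planted_effects_recovered_within_ci(self, rng):
        apoe, y = self._simulate(rng, 5000, -0.8, 1.2)
        est = prscore.estimate_apoe_weights(y, apoe)
        assert abs(est["beta_eps2"] + 0.8) < 1.96 * est["se_eps2"] + 0.05
        assert abs(est["beta_eps4"] - 1.2) < 1.96 * est["se_eps4"] + 0.05

    def test_null_effects_near_zero(self, rng):
        apoe, _ = self._simulate(rng, 5000, 0.0, 0.0)
        y = rng.integers(0, 2, 5000).astype(float)
        est = prscore.estimate_apoe_weights(y, apoe)
        assert abs(est["beta_eps2"]) < 3 * est["se_eps2"]
        assert abs(est["beta_eps4"]) < 3 * est["se_eps4"]

    def test_separation_raises_unless_penalized(self):
        apoe = pd.DataFrame({"IID": list("abcd"), "EPS2": [0, 0, 2, 2], "EPS4": [0, 0, 0, 0]})
        y = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(RuntimeError, match="penalized"):
            prscore.estimate_apoe_weights(y, apoe)
        est = prscore.estimate_apoe_weights(y, apoe, penalized=True)
        assert np.isfinite(est["beta_eps2"])


# ---------------------------------------------------------------------------
# scoring


class TestRawPrs:
    def test_zero_dosages_zero_score(self):
        dm = _dm(np.zeros((3, 2)))
        w = dm.variants[["id", "chrom", "pos"]].copy()
        w["weight"] = [1.0, -2.0]
        np.testing.assert_array_equal(prscore.compute_raw_prs(dm, w), np.zeros(3))

    def test_single_variant_arithmetic(self):
        dm = _dm(np.array([[2.0]]))
        w = dm.variants[["id", "chrom", "pos"]].copy()
        w["weight"] = [1.55]
        assert prscore.compute_raw_prs(dm, w)[0] == pytest.approx(3.10)

    def test_matches_dot_product_oracle(self, rng):
        D = rng.binomial(2, 0.3, size=(100, 50)).astype(float)
        dm = _dm(D, pos=list(range(100, 150)))
        w = dm.variants[["id", "chrom", "pos"]].copy()
        w["weight"] = rng.normal(size=50)
        np.testing.assert_allclose(
            prscore.compute_raw_prs(dm, w), D @ w["weight"].to_numpy(), atol=1e-10
        )

    def test_missing_dosages_mean_imputed(self, rng):
        D = rng.binomial(2, 0.5, size=(10, 1)).astype(float)
        D[0, 0] = np.nan
        dm = _dm(D)
        w = dm.variants[["id", "chrom", "pos"]].copy()
        w["weight"] = [1.0]
        scores = prscore.compute_raw_prs(dm, w)
        assert scores[0] == pytest.approx(np.nanmean(D))

    def test_no_overlap_is_error(self):
        dm = _dm(np.zeros((2, 1)))
        with pytest.raises(ValueError):
            prscore.compute_raw_prs(dm, dm.variants.iloc[:0])


class TestPcs:
    def test_columns_orthonormal(self, small_study):
        pcs = prscore.compute_pcs(small_study.target, k=8)
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(8), atol=1e-8)

    def test_two_populations_separate_on_pc1(self):
        from sklearn.metrics import roc_auc_score

        cfg = SimConfig(seed=3, n_target=400, n_discovery=10, n_blocks=12,
                        snps_per_block=10, n_causal=0, pop_divergence=0.2)
        g = gen_ld_genotypes(cfg)
        pcs = prscore.compute_pcs(g, k=2)
        pop = np.zeros(g.n_samples)
        pop[g.n_samples // 2:] = 1
        auc = roc_auc_score(pop, pcs[:, 0])
        assert max(auc, 1 - auc) > 0.95

    def test_sample_permutation_equivariance(self, small_study, rng):
        g = small_study.target
        perm = rng.permutation(g.n_samples)
        pcs = prscore.compute_pcs(g, k=4)
        pcs_perm = prscore.compute_pcs(g.subset_samples(perm), k=4)
        # left singular vectors are determined up to column sign
        for j in range(4):
            col, col_p = pcs[perm, j], pcs_perm[:, j]
            assert min(np.abs(col - col_p).max(), np.abs(col + col_p).max()) < 1e-8

    def test_k_exceeding_rank_rejected(self):
        dm = _dm(np.random.default_rng(0).binomial(2, 0.4, size=(5, 3)).astype(float))
        with pytest.raises(ValueError):
            prscore.compute_pcs(dm, k=5)


class TestAdjustStandardize:
    def test_mean_zero_sd_one(self, rng):
        s = rng.normal(size=500)
        C = rng.normal(size=(500, 8))
        out = prscore.adjust_standardize(s, C)
        assert abs(out.mean()) < 1e-8
        assert abs(out.std(ddof=1) - 1) < 1e-8

    def test_residual_orthogonal_to_covariates(self, rng):
        s = rng.normal(size=500)
        C = rng.normal(size=(500, 8))
        out = prscore.adjust_standardize(s, C)
        for j in range(8):
            assert abs(np.corrcoef(out, C[:, j])[0, 1]) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        s = rng.normal(size=300)
        C = rng.normal(size=(300, 5))
        X = np.column_stack([np.ones(300), C])
        beta = np.linalg.solve(X.T @ X, X.T @ s)
        resid = s - X @ beta
        expected = resid / resid.std(ddof=1)
        np.testing.assert_allclose(prscore.adjust_standardize(s, C), expected, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        C = rng.normal(size=(100, 2))
        C = np.column_stack([C, C[:, 0]])
        with pytest.raises(ValueError):
            prscore.adjust_standardize(rng.normal(size=100), C)


# ---------------------------------------------------------------------------
# pathways


class TestPathwayPartition:
    def _setup(self, rng, n_var=40):
        pos = list(range(1_000_000, 1_000_000 + n_var * 10, 10))
        dm = _dm(np.zeros((2, n_var)), pos=pos)
        w = dm.variants[["id", "chrom", "pos"]].copy()
        w["weight"] = rng.normal(size=n_var)
        w["p"] = rng.uniform(size=n_var)
        genes = pd.DataFrame(
            {
                "gene": ["gA", "gB", "gC"],
                "chrom": ["1", "1", "1"],
                "start": [1_000_000, 1_000_100, 1_000_150],
                "end": [1_000_120, 1_000_200, 1_000_260],
            }
        )
        sets = {"S1": ["gA"], "S2": ["gB", "gC"], "S_overlap": ["gA", "gB"]}
        return w, genes, sets

    def test_member_gene_variants_assigned(self, rng):
        w, genes, sets = self._setup(rng)
        part = prscore.pathway_partition(w, sets, genes)
        in_ga = (w["pos"] >= 1_000_000) & (w["pos"] <= 1_000_120)
        assert set(part["S1"]["id"]) == set(w.loc[in_ga, "id"])

    def test_overlapping_pathways_share_variants(self, rng):
        w, genes, sets = self._setup(rng)
        part = prscore.pathway_partition(w, sets, genes)
        both = set(part["S1"]["id"]) & set(part["S_overlap"]["id"])
        assert both
        assert not both & set(part["_complement"]["id"])

    def test_union_plus_complement_is_identity(self, rng):
        w, genes, sets = self._setup(rng)
        part = prscore.pathway_partition(w, sets, genes)
        union = set()
        for name, tbl in part.items():
            if name != "_complement":
                union |= set(tbl["id"])
        assert union | set(part["_complement"]["id"]) == set(w["id"])
        assert not union & set(part["_complement"]["id"])

    def test_drop_apoe_region_applied(self, rng):
        w, genes, sets = self._setup(rng)
        w["chrom"] = "19"
        w["pos"] = w["pos"] + 44_000_000  # inside the APOE region
        genes["chrom"] = "19"
        genes[["start", "end"]] += 44_000_000
        part = prscore.pathway_partition(w, sets, genes, drop_apoe=True)
        assert all(len(tbl) == 0 for name, tbl in part.items() if name != "_complement")
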