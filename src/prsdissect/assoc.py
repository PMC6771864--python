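"""Nested logistic models, paired AUCs, and the model battery.

For each case/control contrast three predictor models are fitted:

1. **APOE** — epsilon2 and epsilon4 allele counts;
2. **PRS**  — the standardized non-APOE polygenic score;
3. **FULL** — both.

Each model is fitted twice, without and with the sex and age covariates,
giving the two AUCs reported side by side (rank-based AUC of the fitted
probabilities).  Whether the polygenic score improves on APOE alone is the
chi-square likelihood-ratio (deviance) test of the nested covariate-including
fits.  The battery also supports the extremes analysis (subjects beyond
±1.5 SD of the standardized score) and pathway-specific score blocks with a
Bonferroni threshold of alpha / (scenarios x pathways).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """One fitted logistic model."""

    coef: pd.DataFrame  # name, beta, se, z, p
    loglik: float
    fitted: np.ndarray
    manifest: tuple[str, ...]  # predictor names, covariates included

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def n_params(self) -> int:
        return len(self.coef)


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of two properly nested logistic fits."""

    d_deviance: float
    d_df: int
    p: float


@dataclass
class AucPair:
    auc_bare: float  # predictors only
    auc_cov: float  # predictors + sex + age


def fit_logistic(
    y: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic regression with an intercept.

    ``predictors`` may be empty (intercept-only fit).  Perfect separation
    raises an explicit error naming the offending predictor set.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i}" for i in range(X.shape[1])]
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is not full rank")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as e:
            raise RuntimeError(f"logistic fit failed for predictors {names}: {e}") from e
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 30):
        raise RuntimeError(f"perfect separation suspected for predictors {names}")
    coef = pd.DataFrame(
        {
            "name": ["intercept", *names],
            "beta": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModelFit(coef=coef, loglik=float(fit.llf), fitted=np.asarray(fit.predict()), manifest=tuple(names))


def _ridge_logistic(y: np.ndarray, X: np.ndarray, names: list[str], alpha: float = 1e-2) -> ModelFit:
    """IRLS with a small L2 penalty (intercept unpenalized).

    Safeguard for (quasi-)separated designs in small contrast arms, where
    the unpenalized MLE diverges; the reported log-likelihood is the
    unpenalized one evaluated at the stabilized estimate.
    """
    design = np.column_stack([np.ones(len(y)), X])
    pen = np.full(design.shape[1], alpha)
    pen[0] = 0.0
    beta = np.zeros(design.shape[1])
    for _ in range(100):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        H = design.T @ (design * w[:, None]) + np.diag(pen)
        g = design.T @ (y - p) - pen * beta
        step = np.linalg.solve(H, g)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = design @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    z = beta / se
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    coef = pd.DataFrame(
        {"name": ["intercept", *names], "beta": beta, "se": se, "z": z,
         "p": 2.0 * stats.norm.sf(np.abs(z))}
    )
    return ModelFit(coef=coef, loglik=llf, fitted=p, manifest=tuple(names))


def auc_rank(y: np.ndarray, score: np.ndarray) -> float:
    """Rank-based AUC: P(random case outscores random control), ties half."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, score))


def auc_pair(y: np.ndarray, fit_bare: ModelFit, fit_cov: ModelFit) -> AucPair:
    """AUCs of the fitted probabilities without and with sex/age covariates."""
    return AucPair(auc_bare=auc_rank(y, fit_bare.fitted), auc_cov=auc_rank(y, fit_cov.fitted))


def lrt_nested(full: ModelFit, reduced: ModelFit) -> ModelComparison:
    """Chi-square likelihood-ratio test of nested logistic fits."""
    if not set(reduced.manifest) <= set(full.manifest):
        raise ValueError("models are not nested (reduced manifest not a subset)")
    if len(full.fitted) != len(reduced.fitted):
        raise ValueError("models were fitted on different sample sets")
    d_dev = reduced.deviance - full.deviance
    d_df = full.n_params - reduced.n_params
    if d_df == 0:
        return ModelComparison(d_deviance=max(d_dev, 0.0), d_df=0, p=1.0)
    p = float(stats.chi2.sf(max(d_dev, 0.0), d_df))
    return ModelComparison(d_deviance=float(d_dev), d_df=d_df, p=p)


def extreme_subset(scores: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of subjects with |standardized score| > k SD."""
    scores = np.asarray(scores, dtype=float)
    return np.abs(scores) > k


def bonferroni_alpha(alpha: float = 0.05, m: int = 27) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# battery


@dataclass
class ModelBlock:
    """One model of the battery: bare + covariate fits and the AUC pair."""

    name: str
    fit_bare: ModelFit
    fit_cov: ModelFit
    auc: AucPair


@dataclass
class BatteryResult:
    """The three genome-wide models plus the full-vs-APOE comparison."""

    contrast: str
    n_case: int
    n_control: int
    models: dict[str, ModelBlock]
    comparison: ModelComparison  # FULL vs APOE, covariate-including fits

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, blk in self.models.items():
            prs_rows = blk.fit_cov.coef[blk.fit_cov.coef["name"] == "PRS"]
            rows.append(
                {
                    "contrast": self.contrast,
                    "model": name,
                    "auc_bare": blk.auc.auc_bare,
                    "auc_cov": blk.auc.auc_cov,
                    "prs_beta": float(prs_rows["beta"].iloc[0]) if len(prs_rows) else np.nan,
                    "prs_p": float(prs_rows["p"].iloc[0]) if len(prs_rows) else np.nan,
                }
            )
        df = pd.DataFrame(rows)
        df["lrt_p_full_vs_apoe"] = self.comparison.p
        return df


def _model_frames(scores: pd.DataFrame) -> dict[str, list[str]]:
    return {
        "APOE": ["EPS2", "EPS4"],
        "PRS": ["PRS"],
        "FULL": ["EPS2", "EPS4", "PRS"],
    }


def run_model_battery(
    y: np.ndarray,
    scores: pd.DataFrame,
    contrast_name: str = "",
) -> BatteryResult:
    """Fit the APOE / PRS / FULL models for one contrast.

    ``scores`` must carry columns EPS2, EPS4, PRS (standardized non-APOE
    score), SEX, AGE, row-aligned with ``y``.  Each model is fitted without
    and with the sex/age covariates; the likelihood-ratio comparison of
    FULL vs APOE uses the covariate-including fits.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    needed = {"EPS2", "EPS4", "PRS", "SEX", "AGE"}
    if not needed <= set(scores.columns):
        raise ValueError(f"scores frame must contain {sorted(needed)}")
    models: dict[str, ModelBlock] = {}
    ridge_used = False
    for name, cols in _model_frames(scores).items():
        try:
            fb = fit_logistic(y, scores[cols])
            fc = fit_logistic(y, scores[cols + ["SEX", "AGE"]])
        except (RuntimeError, ValueError):
            # quasi-separation or a constant predictor in a small arm:
            # stabilize with a tiny ridge
            ridge_used = True
            fb = _ridge_logistic(y, scores[cols].to_numpy(dtype=float), cols)
            fc = _ridge_logistic(y, scores[cols + ["SEX", "AGE"]].to_numpy(dtype=float), cols + ["SEX", "AGE"])
        models[name] = ModelBlock(name=name, fit_bare=fb, fit_cov=fc, auc=auc_pair(y, fb, fc))
    if ridge_used:
        # a valid deviance difference needs both nested fits on the same
        # (stabilized) estimation path
        log.warning("%s: ridge-stabilized fits used (quasi-separation)", contrast_name)
        for name, cols in _model_frames(scores).items():
            models[name].fit_cov = _ridge_logistic(
                y, scores[cols + ["SEX", "AGE"]].to_numpy(dtype=float), cols + ["SEX", "AGE"])
    comparison = lrt_nested(models["FULL"].fit_cov, models["APOE"].fit_cov)
    return BatteryResult(
        contrast=contrast_name,
        n_case=int(y.sum()),
        n_control=int(len(y) - y.sum()),
        models=models,
        comparison=comparison,
    )


@dataclass
class PathwayRow:
    pathway: str
    n_snps: int
    beta: float
    p: float
    n_snps_no_apoe: int
    beta_no_apoe: float
    p_no_apoe: float
    significant: bool


def run_pathway_battery(
    y: np.ndarray,
    base: pd.DataFrame,
    pathway_scores: pd.DataFrame,
    pathway_scores_no_apoe: pd.DataFrame,
    snp_counts: dict[str, int],
    snp_counts_no_apoe: dict[str, int],
    alpha: float = 0.05,
    n_scenarios: int = 3,
) -> pd.DataFrame:
    """Per-pathway logistic associations, with and without the APOE region.

    ``base`` carries SEX and AGE; each pathway's standardized score is
    tested as the sole genetic predictor (covariates included).  The
    complement score (all clumped variants outside every pathway) is
    reported alongside.  The Bonferroni flag uses
    alpha / (n_scenarios x n_pathways), the pathway count excluding the
    complement.
    """
    names = [c for c in pathway_scores.columns]
    n_pathways = len([n for n in names if n != "_complement"])
    thr = bonferroni_alpha(alpha, n_scenarios * max(n_pathways, 1))
    rows = []
    for name in names:
        def _one(frame):
            if name not in frame.columns or frame[name].std() == 0:
                return np.nan, np.nan
            X = pd.DataFrame({"PRS": frame[name], "SEX": base["SEX"], "AGE": base["AGE"]})
            fit = fit_logistic(y, X)
            r = fit.coef[fit.coef["name"] == "PRS"].iloc[0]
            return float(r["beta"]), float(r["p"])

        beta, p = _one(pathway_scores)
        beta0, p0 = _one(pathway_scores_no_apoe) if name != "_complement" else (np.nan, np.nan)
        rows.append(
            PathwayRow(
                pathway=name,
                n_snps=snp_counts.get(name, 0),
                beta=beta,
                p=p,
                n_snps_no_apoe=snp_counts_no_apoe.get(name, 0),
                beta_no_apoe=beta0,
                p_no_apoe=p0,
                significant=bool(p <= thr) if np.isfinite(p) else False,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.attrs["bonferroni_threshold"] = thr
    return df
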