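"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

* Cochran's Q over per-SNP Wald ratios (chi-square, J-1 df) — excess
  heterogeneity flags invalid instruments.
* The Egger intercept test — a nonzero intercept indicates directional
  horizontal pleiotropy.
* MR-PRESSO — a parametric-simulation residual-sum-of-squares framework
  with global, per-SNP outlier, and distortion tests, implemented from the
  published algorithmic description (leave-one-out expected values plus
  Monte-Carlo replicates on both exposure and outcome sides).
* Leave-one-out IVW with sign-flip and significance-flip flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _arrays, egger, ivw, ivw_beta_se_fixed
from .exceptions import InsufficientInstrumentsError, TsmrError
from .sumstats import HarmonizedDataset


def cochran_q(hd: HarmonizedDataset) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios: Q = sum w_j (ratio_j - beta_IVW)^2 with
    w_j = (beta_Xj/se_Yj)^2; p from chi-square on J-1 df."""
    j = len(hd)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q", 2, j)
    bx, _, by, sy = _arrays(hd)
    beta, _ = ivw_beta_se_fixed(bx, by, sy)
    w = bx**2 / sy**2
    q = float(np.sum(w * (by / bx - beta) ** 2))
    df = j - 1
    pval = float(stats.chi2.sf(q, df))
    return q, df, pval


def egger_intercept_test(hd: HarmonizedDataset) -> tuple[float, float, float]:
    """Egger intercept, its SE, and the two-sided t(J-2) p-value."""
    e = egger(hd)
    return e.extras["intercept"], e.extras["intercept_se"], e.extras["intercept_pval"]


@dataclass
class PressoResult:
    """MR-PRESSO global / outlier / distortion results."""

    global_rss_observed: float
    global_pval: float
    per_snp_outlier_pvals: dict[str, float]
    outlier_ids: list[str]
    distortion_pval: float | None
    estimate_raw: MREstimate
    estimate_outlier_corrected: MREstimate | None
    n_sim: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "global_rss_observed": self.global_rss_observed,
            "global_pval": self.global_pval,
            "per_snp_outlier_pvals": self.per_snp_outlier_pvals,
            "outlier_ids": self.outlier_ids,
            "distortion_pval": self.distortion_pval,
            "estimate_raw": self.estimate_raw.to_row(),
            "estimate_outlier_corrected": (
                self.estimate_outlier_corrected.to_row()
                if self.estimate_outlier_corrected
                else None
            ),
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """IVW slope with each SNP left out, via sufficient-statistic downdate."""
    w = 1.0 / sy**2
    num = np.sum(w * bx * by)
    den = np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def mr_presso(
    hd: HarmonizedDataset,
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
    n_distortion_sets: int = 1000,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    Global: observed RSS = sum_j w_j (beta_Yj - bhat_(-j) beta_Xj)^2 with
    w_j = 1/se_Yj^2 and bhat_(-j) the leave-one-out IVW slope; its p-value is
    the add-one Monte-Carlo tail probability against ``n_sim`` parametric
    replicates drawing beta_Yj* ~ N(bhat_(-j) beta_Xj, se_Yj) and
    beta_Xj* ~ N(beta_Xj, se_Xj).  Outlier: per-SNP add-one p on the squared
    weighted residual, Bonferroni-multiplied by J; outliers are adjusted
    p < ``significance``.  Distortion: the raw-vs-corrected IVW difference
    compared against the same difference under random pseudo-outlier subsets
    of the observed size.
    """
    j = len(hd)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO", 4, j)
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(hd)
    w = 1.0 / sy**2
    ids = hd.snp_ids

    slopes_loo = _loo_slopes(bx, by, sy)
    resid_obs = by - slopes_loo * bx
    resid2_obs = w * resid_obs**2
    rss_obs = float(np.sum(resid2_obs))

    expected = slopes_loo * bx
    count_global = 0
    count_snp = np.zeros(j)
    for _ in range(n_sim):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(expected, sy)
        sl = _loo_slopes(bxs, bys, sy)
        r2 = w * (bys - sl * bxs) ** 2
        rss_sim = float(np.sum(r2))
        if rss_sim >= rss_obs:
            count_global += 1
        count_snp += r2 >= resid2_obs
    global_pval = (1 + count_global) / (n_sim + 1)
    raw_p = (1 + count_snp) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * j)
    per_snp = {ids[k]: float(adj_p[k]) for k in range(j)}
    outlier_ids = [ids[k] for k in range(j) if adj_p[k] < significance]

    estimate_raw = ivw(hd)
    estimate_corrected = None
    distortion_pval = None
    if outlier_ids:
        if len(outlier_ids) == j:
            raise TsmrError("MR-PRESSO: every instrument flagged as outlier")
        kept = hd.drop(outlier_ids)
        estimate_corrected = ivw(kept)
        observed_diff = estimate_raw.beta - estimate_corrected.beta
        k = len(outlier_ids)
        diffs = np.empty(n_distortion_sets)
        idx = np.arange(j)
        for t in range(n_distortion_sets):
            pseudo = rng.choice(idx, size=k, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[pseudo] = False
            b_wo, _ = ivw_beta_se_fixed(bx[mask], by[mask], sy[mask])
            diffs[t] = estimate_raw.beta - b_wo
        distortion_pval = float(
            (1 + np.sum(np.abs(diffs) >= abs(observed_diff))) / (n_distortion_sets + 1)
        )
    return PressoResult(
        global_rss_observed=rss_obs,
        global_pval=float(global_pval),
        per_snp_outlier_pvals=per_snp,
        outlier_ids=outlier_ids,
        distortion_pval=distortion_pval,
        estimate_raw=estimate_raw,
        estimate_outlier_corrected=estimate_corrected,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(hd: HarmonizedDataset, alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated with each SNP omitted.

    Returns one row per left-out SNP with the re-estimate and flags for a
    sign flip or a significance flip relative to the full-set IVW.
    """
    j = len(hd)
    if j < 2:
        raise InsufficientInstrumentsError("leave-one-out", 2, j)
    full = ivw(hd)
    full_sig = full.pval < alpha
    rows = []
    for pair in hd:
        sub = hd.drop([pair.snp_id])
        est = ivw(sub)
        rows.append(
            {
                "snp_id": pair.snp_id,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "flag_sign_flip": (est.beta > 0) != (full.beta > 0),
                "flag_significance_flip": (est.pval < alpha) != full_sig,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Bundle of all diagnostics for one exposure-outcome pair."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: PressoResult | None = None
    loo: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso": self.presso.to_dict() if self.presso else None,
            "leave_one_out": (
                self.loo.to_dict(orient="records") if self.loo is not None else None
            ),
            "notes": self.notes,
        }


def sensitivity_report(
    hd: HarmonizedDataset,
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
) -> SensitivityReport:
    """Compute the full diagnostic battery, degrading gracefully when the
    instrument count is below a test's minimum (noted, not fatal)."""
    notes: list[str] = []
    q, qdf, qp = cochran_q(hd)
    if len(hd) >= 3:
        alpha, se_a, p_a = egger_intercept_test(hd)
    else:
        alpha = se_a = p_a = math.nan
        notes.append("egger-intercept: needs >= 3 instruments")
    presso = None
    if len(hd) >= 4:
        presso = mr_presso(hd, n_sim=n_sim, significance=significance, seed=seed)
    else:
        notes.append("mr-presso: needs >= 4 instruments")
    loo = leave_one_out(hd)
    return SensitivityReport(q, qdf, qp, alpha, se_a, p_a, presso, loo, notes)


def funnel_source(hd: HarmonizedDataset) -> pd.DataFrame:
    """Per-SNP ratio and precision for funnel-plot reconstruction."""
    from .estimators import ratio_estimates

    est = ratio_estimates(hd)
    return pd.DataFrame(
        [{"snp_id": e.snp_id, "ratio": e.ratio, "se_ratio": e.se_ratio} for e in est]
    )


def scatter_source(hd: HarmonizedDataset) -> pd.DataFrame:
    """Per-SNP exposure/outcome betas and SEs for scatter-plot reconstruction."""
    return hd.to_frame()[["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]]
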