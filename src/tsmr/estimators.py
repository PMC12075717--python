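"""Causal-effect estimators for two-sample MR.

Implements the standard five-method battery: inverse-variance-weighted
(IVW) meta-analysis of per-SNP Wald ratios (primary), MR-Egger regression
(free intercept absorbing directional pleiotropy), the weighted median
(consistent when >=50% of instrument weight is valid), and kernel-mode
estimators in weighted and simple (unweighted) variants.

Conventions
-----------
* Per-SNP ratios use the first-order delta standard error se_Yj/|beta_Xj|.
* IVW defaults to the multiplicative random-effects variant: the fixed
  standard error is inflated by max(1, sqrt(Q/(J-1))), so underdispersion
  never tightens the interval.
* Egger inference is on t with J-2 degrees of freedom; IVW, median and mode
  use the normal.
* Median/mode standard errors come from a parametric bootstrap that redraws
  both exposure and outcome betas from their reported sampling
  distributions; a seed is required for reproducible pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError, NoInstrumentsError
from .sumstats import HarmonizedDataset, HarmonizedPair

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with first-order delta SE and IVW weight."""

    snp_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale.

    ``or_scale`` properties expose exp(beta) and the exponentiated CI for
    binary outcomes.  ``extras`` carries method-specific fields (Egger
    intercept and its test, bootstrap replicate count, random-effects
    scale).
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
        }


def wald_ratio(pair: HarmonizedPair) -> RatioEstimate:
    """Single-SNP causal estimate beta_out/beta_exp with delta-method SE."""
    if pair.beta_exp == 0:
        raise ValueError(f"{pair.snp_id}: zero exposure effect, ratio undefined")
    return RatioEstimate(
        snp_id=pair.snp_id,
        ratio=pair.beta_out / pair.beta_exp,
        se_ratio=pair.se_out / abs(pair.beta_exp),
    )


def ratio_estimates(hd: HarmonizedDataset) -> list[RatioEstimate]:
    return [wald_ratio(p) for p in hd]


def _arrays(hd: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([p.beta_exp for p in hd])
    sx = np.array([p.se_exp for p in hd])
    by = np.array([p.beta_out for p in hd])
    sy = np.array([p.se_out for p in hd])
    return bx, sx, by, sy


def ivw_beta_se_fixed(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Closed-form IVW slope and fixed-effects SE (regression through origin
    of outcome on exposure betas, weights 1/se_out^2)."""
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    return beta, math.sqrt(1.0 / denom)


def _cochran_q(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, beta: float) -> float:
    w = bx**2 / sy**2
    ratios = by / bx
    return float(np.sum(w * (ratios - beta) ** 2))


def ivw(hd: HarmonizedDataset, effects_model: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``effects_model``: ``"fixed"`` or ``"mre"`` (multiplicative random
    effects; SE inflated by max(1, sqrt(Q/(J-1)))).  A single instrument
    reduces to the Wald ratio.
    """
    j = len(hd)
    if j == 0:
        raise NoInstrumentsError("IVW: no instruments")
    if effects_model not in ("fixed", "mre"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    bx, sx, by, sy = _arrays(hd)
    beta, se_fixed = ivw_beta_se_fixed(bx, by, sy)
    scale = 1.0
    if j >= 2:
        q = _cochran_q(bx, by, sy, beta)
        if effects_model == "mre":
            scale = max(1.0, math.sqrt(q / (j - 1)))
    se = se_fixed * scale
    z = beta / se
    pval = 2 * stats.norm.sf(abs(z))
    return MREstimate(
        method="IVW",
        beta=beta,
        se=se,
        pval=float(pval),
        n_snp=j,
        extras={"effects_model": effects_model, "re_scale": scale, "se_fixed": se_fixed},
    )


def egger(hd: HarmonizedDataset) -> MREstimate:
    """MR-Egger regression: WLS of outcome on exposure betas with a free
    intercept (the average directional-pleiotropy term).

    Pairs are first oriented so every exposure beta is non-negative (joint
    sign flip leaves the Wald ratio unchanged).  Inference uses t(J-2) and
    the residual scale floored at 1.
    """
    j = len(hd)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger", 3, j)
    bx, sx, by, sy = _arrays(hd)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    sigma2 = rss_w / (j - 2)
    cov_unscaled = np.linalg.inv(xtwx)
    infl = max(1.0, math.sqrt(sigma2))
    se_int, se_slope = infl * np.sqrt(np.diag(cov_unscaled))
    alpha, slope = coef
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), df=j - 2)
    p_alpha = 2 * stats.t.sf(abs(alpha / se_int), df=j - 2)
    tcrit = stats.t.ppf(0.975, df=j - 2)
    return MREstimate(
        method="MR-Egger",
        beta=float(slope),
        se=float(se_slope),
        pval=float(p_slope),
        n_snp=j,
        ci_low=float(slope - tcrit * se_slope),
        ci_high=float(slope + tcrit * se_slope),
        extras={
            "intercept": float(alpha),
            "intercept_se": float(se_int),
            "intercept_pval": float(p_alpha),
            "residual_scale": sigma2,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _parametric_bootstrap(
    hd: HarmonizedDataset,
    point_fn,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    bx, sx, by, sy = _arrays(hd)
    j = len(hd)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = 1e-12
        ratios = bys / bxs
        se_r = sy / np.abs(bxs)
        draws[b] = point_fn(ratios, 1.0 / se_r**2)
    return float(np.std(draws, ddof=1))


def weighted_median(
    hd: HarmonizedDataset, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    j = len(hd)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median", 3, j)
    est = ratio_estimates(hd)
    ratios = np.array([e.ratio for e in est])
    weights = np.array([e.weight for e in est])
    point = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    se = _parametric_bootstrap(hd, _weighted_median_point, n_boot, rng)
    pval = 2 * stats.norm.sf(abs(point / se)) if se > 0 else 0.0
    return MREstimate(
        method="weighted-median",
        beta=point,
        se=se,
        pval=float(pval),
        n_snp=j,
        extras={"n_boot": n_boot},
    )


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    w = weights / weights.sum()
    if ratios.size == 1 or np.allclose(ratios, ratios[0]):
        return float(ratios[0])
    s = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    h = phi * 0.9 * spread * ratios.size ** (-1 / 5)
    if h <= 0:
        return float(ratios[np.argmax(w)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = (w[:, None] * stats.norm.pdf((grid[None, :] - ratios[:, None]) / h)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    hd: HarmonizedDataset,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimator: argmax of a normal-kernel density over the
    per-SNP ratios (modified Silverman bandwidth, factor ``phi``).

    ``weighted=True`` scales each kernel by the normalized IVW weight;
    ``weighted=False`` is the simple (equal-weight) mode.
    """
    j = len(hd)
    if j < 3:
        raise InsufficientInstrumentsError("mode estimator", 3, j)
    est = ratio_estimates(hd)
    ratios = np.array([e.ratio for e in est])
    weights = (
        np.array([e.weight for e in est]) if weighted else np.ones(j)
    )
    point = _mode_point(ratios, weights, phi)
    rng = np.random.default_rng(seed)

    if weighted:
        point_fn = lambda r, w: _mode_point(r, w, phi)  # noqa: E731
    else:
        point_fn = lambda r, w: _mode_point(r, np.ones_like(r), phi)  # noqa: E731
    se = _parametric_bootstrap(hd, point_fn, n_boot, rng)
    pval = 2 * stats.norm.sf(abs(point / se)) if se > 0 else 0.0
    return MREstimate(
        method="weighted-mode" if weighted else "simple-mode",
        beta=point,
        se=se,
        pval=float(pval),
        n_snp=j,
        extras={"phi": phi, "n_boot": n_boot},
    )


METHODS = ("IVW", "MR-Egger", "weighted-median", "weighted-mode", "simple-mode")


def estimate_all(
    hd: HarmonizedDataset,
    effects_model: str = "mre",
    n_boot: int = 1000,
    phi: float = 1.0,
    seed: int | None = None,
) -> dict[str, MREstimate]:
    """Run the five-method battery; methods whose instrument-count
    requirement is not met are omitted from the result (IVW with one SNP
    degrades gracefully to the Wald ratio)."""
    if len(hd) == 0:
        raise NoInstrumentsError(
            f"no instruments for {hd.exposure_id} -> {hd.outcome_id}"
        )
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child = ss.spawn(3)
    out: dict[str, MREstimate] = {"IVW": ivw(hd, effects_model)}
    if len(hd) >= 3:
        out["MR-Egger"] = egger(hd)
        out["weighted-median"] = weighted_median(
            hd, n_boot, int(child[0].generate_state(1)[0] % 2**31)
        )
        out["weighted-mode"] = mode_estimator(
            hd, True, phi, n_boot, int(child[1].generate_state(1)[0] % 2**31)
        )
        out["simple-mode"] = mode_estimator(
            hd, False, phi, n_boot, int(child[2].generate_state(1)[0] % 2**31)
        )
    return out
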