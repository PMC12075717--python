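"""Candidate-pair screening over many exposures, plus reverse-direction MR.

A pair survives when: the primary IVW estimate is significant; at least one
of MR-Egger and the weighted median corroborates it (p < 0.05) — the rule
this workflow uses in place of panel-wide multiplicity correction; the
IVW / Egger / weighted-median estimates agree in direction and magnitude
(same sign, overlapping 95% CIs); heterogeneity (Cochran's Q) and
directional pleiotropy (Egger intercept) tests are non-significant;
MR-PRESSO finds no outliers, or the estimate is stable after one round of
outlier removal; and reverse-direction MR shows no significant effect of
the outcome on the exposure.  An optional Benjamini-Hochberg switch across
the exposure panel exists but is off by default.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MREstimate, estimate_all, ivw
from .exceptions import ConfigurationError, NoInstrumentsError, TsmrError
from .selection import LDMatrix, SelectionConfig
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import SummaryDataset


@dataclass
class ScreeningCriteria:
    """Rule thresholds for :func:`evaluate_pair`."""

    p_primary: float = 0.05
    p_corroboration: float = 0.05
    require_direction_agreement: bool = True
    q_pval_min: float = 0.05
    egger_intercept_pval_min: float = 0.05
    reverse_pval_min: float = 0.05
    fdr_alpha: float | None = None  # optional BH across the exposure panel

    def __post_init__(self) -> None:
        for nm in ("p_primary", "p_corroboration", "q_pval_min",
                   "egger_intercept_pval_min", "reverse_pval_min"):
            v = getattr(self, nm)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{nm} must lie in (0, 1)")


@dataclass
class ScreeningDecision:
    """Outcome of the rule battery for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    reverse: MREstimate | None = None

    def to_row(self) -> dict:
        iv = self.estimates.get("IVW")
        return {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "passed": self.passed,
            "failed_rules": ";".join(self.failed_rules),
            "ivw_or": iv.odds_ratio if iv else float("nan"),
            "ivw_ci_low": iv.or_ci[0] if iv else float("nan"),
            "ivw_ci_high": iv.or_ci[1] if iv else float("nan"),
            "ivw_p": iv.pval if iv else float("nan"),
        }


def _ci_overlap(a: MREstimate, b: MREstimate) -> bool:
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high


def evaluate_pair(
    estimates: dict[str, MREstimate],
    sensitivity: SensitivityReport | None,
    reverse_estimate: MREstimate | None,
    criteria: ScreeningCriteria | None = None,
    exposure_id: str = "",
    outcome_id: str = "",
) -> ScreeningDecision:
    """Apply the screening rule battery; deterministic given its inputs."""
    criteria = criteria or ScreeningCriteria()
    for required in ("IVW", "MR-Egger", "weighted-median"):
        if required not in estimates:
            raise ConfigurationError(f"evaluate_pair: missing {required} estimate")
    failed: list[str] = []
    iv = estimates["IVW"]
    eg = estimates["MR-Egger"]
    wm = estimates["weighted-median"]

    if not (iv.pval < criteria.p_primary):
        failed.append("p_primary")
    if not (
        eg.pval < criteria.p_corroboration or wm.pval < criteria.p_corroboration
    ):
        failed.append("corroboration")
    if criteria.require_direction_agreement:
        same_sign = len({iv.beta > 0, eg.beta > 0, wm.beta > 0}) == 1
        overlap = _ci_overlap(iv, eg) and _ci_overlap(iv, wm) and _ci_overlap(eg, wm)
        if not (same_sign and overlap):
            failed.append("direction")
    if sensitivity is not None:
        if not (sensitivity.q_pval > criteria.q_pval_min):
            failed.append("heterogeneity")
        if not (
            np.isnan(sensitivity.egger_intercept_pval)
            or sensitivity.egger_intercept_pval > criteria.egger_intercept_pval_min
        ):
            failed.append("egger-intercept")
        presso = sensitivity.presso
        if presso is not None and presso.outlier_ids:
            corrected = presso.estimate_outlier_corrected
            stable = (
                corrected is not None
                and (corrected.beta > 0) == (presso.estimate_raw.beta > 0)
                and corrected.pval < criteria.p_primary
            )
            if not stable:
                failed.append("presso-outliers")
    if reverse_estimate is not None and not (
        reverse_estimate.pval >= criteria.reverse_pval_min
    ):
        failed.append("reverse-causality")
    return ScreeningDecision(
        exposure_id=exposure_id or "exposure",
        outcome_id=outcome_id or "outcome",
        passed=not failed,
        failed_rules=failed,
        estimates=estimates,
        sensitivity=sensitivity,
        reverse=reverse_estimate,
    )


def reverse_mr(
    outcome_ds: SummaryDataset,
    exposure_ds: SummaryDataset,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    effects_model: str = "mre",
) -> MREstimate:
    """Reverse-direction MR: instrument the original outcome trait and
    estimate its effect on the original exposure with the identical
    selection + IVW pipeline."""
    from .pipeline import harmonized_leg

    hd = harmonized_leg(outcome_ds, exposure_ds, ld, config)
    return ivw(hd, effects_model)


def run_screen(
    exposures: list[SummaryDataset],
    outcome_ds: SummaryDataset,
    ld: LDMatrix | None = None,
    criteria: ScreeningCriteria | None = None,
    config: SelectionConfig | None = None,
    seed: int | None = None,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> list[ScreeningDecision]:
    """Screen every exposure against the outcome.

    Per-exposure failures (e.g. no instruments) are recorded as failed
    decisions, never fatal to the batch.  Decisions are order-independent
    across exposures: each exposure's stochastic stages get a seed derived
    from the root seed and the trait id, not from batch position.
    """
    from .pipeline import harmonized_leg

    criteria = criteria or ScreeningCriteria()
    decisions: list[ScreeningDecision] = []
    for exposure_ds in exposures:
        # trait-keyed seed: stable under reordering of the exposure list
        sub_seed = (
            None
            if seed is None
            else int(
                np.random.SeedSequence(
                    [seed, zlib.crc32(exposure_ds.trait_id.encode()) % 2**31]
                ).generate_state(1)[0]
                % 2**31
            )
        )
        try:
            hd = harmonized_leg(exposure_ds, outcome_ds, ld, config)
            estimates = estimate_all(hd, n_boot=n_boot, seed=sub_seed)
            if len(hd) < 3:
                raise NoInstrumentsError(
                    f"{exposure_ds.trait_id}: fewer than 3 instruments"
                )
            sens = sensitivity_report(hd, n_sim=presso_n_sim, seed=sub_seed)
            try:
                rev = reverse_mr(outcome_ds, exposure_ds, ld, config)
            except TsmrError:
                rev = None  # outcome has no instruments: reverse rule vacuous
            decisions.append(
                evaluate_pair(
                    estimates, sens, rev, criteria,
                    exposure_id=exposure_ds.trait_id,
                    outcome_id=outcome_ds.trait_id,
                )
            )
        except TsmrError as err:
            decisions.append(
                ScreeningDecision(
                    exposure_id=exposure_ds.trait_id,
                    outcome_id=outcome_ds.trait_id,
                    passed=False,
                    failed_rules=[f"no-instruments: {err}"],
                )
            )
    if criteria.fdr_alpha is not None:
        _apply_fdr(decisions, criteria.fdr_alpha)
    return decisions


def _apply_fdr(decisions: list[ScreeningDecision], alpha: float) -> None:
    from statsmodels.stats.multitest import multipletests

    idx = [i for i, d in enumerate(decisions) if "IVW" in d.estimates]
    if not idx:
        return
    pvals = [decisions[i].estimates["IVW"].pval for i in idx]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for i, rej in zip(idx, reject):
        if not rej and "fdr" not in decisions[i].failed_rules:
            decisions[i].failed_rules.append("fdr")
            decisions[i].passed = False


def decisions_table(decisions: list[ScreeningDecision]) -> pd.DataFrame:
    return pd.DataFrame([d.to_row() for d in decisions])
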