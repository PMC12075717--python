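"""Synthetic GWAS summary statistics with known causal structure.

The generator works directly in summary-statistic space (two-sample MR
never touches individual-level genotypes): each variant gets a true
per-allele effect on each trait from an exposure -> mediator -> outcome
causal chain, and observed betas are drawn around the truth with standard
errors se = 1/sqrt(2 maf (1-maf) n), the standard approximation for a
standardized trait.

Causal chain.  Exposure-instrument SNPs carry effects gamma_j on the
exposure; mediator-instrument SNPs carry effects delta_j directly on the
mediator (a mediator trait has genetics of its own — without this block the
mediator GWAS would yield no instruments and step-2 MR would be
impossible).  With beta_xm the exposure->mediator effect, beta_my the
mediator->outcome effect and beta_direct the exposure->outcome effect not
through the mediator, true per-SNP effects are

    exposure:  gamma_j
    mediator:  beta_xm * gamma_j + delta_j
    outcome:   (beta_direct + beta_xm*beta_my) * gamma_j
               + beta_my * delta_j + alpha_j

where alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2) is horizontal
pleiotropy (balanced when the mean is zero, directional otherwise).
Planted outliers displace the observed outcome beta of the strongest
exposure instruments by ``outlier_shift_se`` outcome standard errors.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .selection import LDMatrix
from .sumstats import SummaryDataset, VariantAssociation

# allele pairs that are not strand-ambiguous
_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimScenario:
    """Complete description of one simulated three-trait GWAS study.

    Default sample sizes mirror the scale of public microbiome
    (n ~ 18,000), immune-phenotype (n ~ 3,800) and biobank case-control
    (n ~ 177,000) GWAS; effect-size SDs are set so that a realistic
    fraction of SNPs clears the p < 1e-5 instrument threshold at those
    sizes.
    """

    n_snp: int = 30                 # exposure-instrument block
    n_snp_med: int = 30             # mediator-instrument block
    gamma_sd: float = 0.08          # SD of true SNP->exposure effects
    delta_sd: float = 0.15          # SD of true SNP->mediator effects
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 18_340
    n_med: int = 3_757
    n_out: int = 177_028
    beta_xm: float = 0.0            # exposure -> mediator (beta1 truth)
    beta_my: float = 0.0            # mediator -> outcome (beta2 truth)
    beta_direct: float = 0.0        # exposure -> outcome, not via mediator
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_count: int = 0
    outlier_shift_se: float = 0.0
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    palindromic_fraction: float = 0.0
    swap_fraction: float = 0.3      # outcome/mediator records stored on the swapped allele
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for nm in ("n_exp", "n_med", "n_out"):
            if getattr(self, nm) < 2:
                raise ConfigurationError(f"{nm} must be >= 2")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_within_r2 <= 1.0):
            raise ConfigurationError("ld_within_r2 must lie in [0, 1]")

    @property
    def beta_all_true(self) -> float:
        """Total exposure->outcome effect: direct + mediated."""
        return self.beta_direct + self.beta_xm * self.beta_my

    @property
    def prop_true(self) -> float:
        """True mediated proportion in percent (signed)."""
        if self.beta_all_true == 0:
            return math.nan
        return self.beta_xm * self.beta_my / self.beta_all_true * 100.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_all_true"] = self.beta_all_true
        d["prop_true"] = self.prop_true
        return d


@dataclass
class SyntheticStudy:
    """Three simulated GWAS plus the LD matrix and the generating truth."""

    exposure: SummaryDataset
    mediator: SummaryDataset
    outcome: SummaryDataset
    ld: LDMatrix
    truth: dict = field(default_factory=dict)


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _block_ld(n: int, block: int, r2: float) -> np.ndarray:
    mat = np.eye(n)
    if block > 1 and r2 > 0:
        for start in range(0, n, block):
            end = min(start + block, n)
            mat[start:end, start:end] = r2
            np.fill_diagonal(mat[start:end, start:end], 1.0)
    return mat


def simulate_study(scenario: SimScenario, seed: int | None = None) -> SyntheticStudy:
    """Draw one synthetic study; fully deterministic given (scenario, seed)."""
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    j_exp, j_med = scenario.n_snp, scenario.n_snp_med
    j = j_exp + j_med

    maf = rng.uniform(*scenario.maf_range, size=j)
    gamma = np.zeros(j)
    gamma[:j_exp] = rng.normal(0.0, scenario.gamma_sd, size=j_exp)
    delta = np.zeros(j)
    if j_med:
        delta[j_exp:] = rng.normal(0.0, scenario.delta_sd, size=j_med)
    alpha = (
        rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=j)
        if (scenario.pleiotropy_sd > 0 or scenario.pleiotropy_mean != 0)
        else np.zeros(j)
    )

    true_exp = gamma
    true_med = scenario.beta_xm * gamma + delta
    # pleiotropy is planted relative to the trait-increasing allele of the
    # SNP's own instrument trait, so a nonzero mean is directional in the
    # orientation MR-Egger uses
    orient = np.where(gamma != 0, np.sign(gamma), np.where(delta != 0, np.sign(delta), 1.0))
    true_out = scenario.beta_all_true * gamma + scenario.beta_my * delta + orient * alpha

    se_exp = _se(maf, scenario.n_exp)
    se_med = _se(maf, scenario.n_med)
    se_out = _se(maf, scenario.n_out)
    beta_exp = rng.normal(true_exp, se_exp)
    beta_med = rng.normal(true_med, se_med)
    beta_out = rng.normal(true_out, se_out)

    # plant outliers on the strongest observed exposure instruments so they
    # survive instrument selection
    outlier_ids: list[str] = []
    if scenario.outlier_count > 0 and j_exp > 0:
        order = np.argsort(-np.abs(beta_exp[:j_exp] / se_exp[:j_exp]))
        chosen = order[: scenario.outlier_count]
        signs = rng.choice([-1.0, 1.0], size=chosen.size)
        beta_out[chosen] = beta_out[chosen] + signs * scenario.outlier_shift_se * se_out[chosen]
        outlier_ids = [f"rs{100001 + int(k)}" for k in chosen]

    # alleles; a configurable fraction is strand-ambiguous
    n_pal = int(round(scenario.palindromic_fraction * j))
    pal_mask = np.zeros(j, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(j, size=n_pal, replace=False)] = True
    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=j)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    alleles = [
        _PALINDROMIC_PAIRS[pal_idx[k]] if pal_mask[k] else _NON_PALINDROMIC_PAIRS[pair_idx[k]]
        for k in range(j)
    ]
    swap = rng.uniform(size=j) < scenario.swap_fraction

    ids = [f"rs{100001 + k}" for k in range(j)]
    block = max(1, scenario.ld_block_size)
    chroms, positions = [], []
    for k in range(j):
        b = k // block
        chroms.append(str(b % 22 + 1))
        positions.append(1_000_000 + (b // 22) * 25_000_000 + (k % block) * 50_000)

    def build(trait_id, betas, ses, n, swapped_view) -> SummaryDataset:
        recs = []
        pv = _pvals(betas, ses)
        for k in range(j):
            ea, oa = alleles[k]
            b, eaf = betas[k], maf[k]
            if swapped_view and swap[k] and not pal_mask[k]:
                ea, oa, b, eaf = oa, ea, -b, 1.0 - eaf
            recs.append(
                VariantAssociation(
                    snp_id=ids[k],
                    chrom=chroms[k],
                    pos=positions[k],
                    effect_allele=ea,
                    other_allele=oa,
                    eaf=float(eaf),
                    beta=float(b),
                    se=float(ses[k]),
                    pval=float(pv[k]),
                    n=float(n),
                )
            )
        return SummaryDataset.from_records(trait_id, recs)

    exposure = build("exposure", beta_exp, se_exp, scenario.n_exp, False)
    mediator = build("mediator", beta_med, se_med, scenario.n_med, True)
    outcome = build("outcome", beta_out, se_out, scenario.n_out, True)
    ld = LDMatrix(ids, _block_ld(j, block, scenario.ld_within_r2))

    truth = {
        "scenario": scenario.to_dict(),
        "seed": seed,
        "gamma": gamma.tolist(),
        "delta": delta.tolist(),
        "alpha": alpha.tolist(),
        "beta_all_true": scenario.beta_all_true,
        "prop_true": scenario.prop_true,
        "outlier_ids": outlier_ids,
    }
    return SyntheticStudy(exposure, mediator, outcome, ld, truth)


_PRESETS: dict[str, dict] = {
    # estimator-level scenarios: a single exposure-instrument block of
    # fixed size, no mediator genetics
    # no causal effects anywhere; instruments still exist for the exposure
    "null": {"n_snp_med": 0},
    # pure direct exposure->outcome effect at the scale of a modest
    # binary-outcome association (OR 1.17)
    "effect": {"n_snp_med": 0, "beta_direct": math.log(1.17)},
    # zero-mean horizontal pleiotropy (InSIDE holds)
    "balanced-pleiotropy": {"n_snp_med": 0, "pleiotropy_mean": 0.0, "pleiotropy_sd": 0.005},
    # systematic directional pleiotropy, detectable by the intercept test
    "directional-strong": {"n_snp_med": 0, "pleiotropy_mean": 0.01, "pleiotropy_sd": 0.005},
    # one instrument with its outcome effect displaced by 10 SE
    "single-outlier": {"n_snp_med": 0, "outlier_count": 1, "outlier_shift_se": 10.0},
    # exposure->mediator -0.19, mediator->outcome -0.05, direct 0.147:
    # total ~ ln(1.17) and mediated proportion ~ 6.1%
    "paper-mediation": {"beta_xm": -0.19, "beta_my": -0.05, "beta_direct": 0.147},
    # mediated and total effects of opposite sign (inconsistent mediation);
    # beta_my is kept small enough that mediator instruments are not
    # themselves outcome-associated at the selection threshold
    "suppression": {"beta_xm": 0.3, "beta_my": -0.05, "beta_direct": 0.05},
}


def preset(name: str) -> SimScenario:
    """Named, fixed scenario; see module docstring for the effect model."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    return SimScenario(**_PRESETS[name])


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the three TSV datasets, the LD matrix and the truth JSON."""
    from pathlib import Path

    from .sumstats import write_sumstats

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(study.exposure, out / "exposure.tsv")
    write_sumstats(study.mediator, out / "mediator.tsv")
    write_sumstats(study.outcome, out / "outcome.tsv")
    study.ld.write(out / "ld.tsv")
    (out / "truth.json").write_text(json.dumps(study.truth, indent=2))


def replicate(
    scenario: SimScenario,
    n_reps: int,
    analysis: str = "ivw",
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run a named pipeline stage over ``n_reps`` independent replicates.

    ``analysis`` is one of ``ivw``, ``egger-intercept``, ``presso``,
    ``mediation``.  The estimator-level analyses (``ivw``,
    ``egger-intercept``) analyze the full simulated instrument block, so
    the instrument count is fixed at the scenario's ``n_snp``; the
    pipeline-level analyses (``presso``, ``mediation``) run the instrument
    selection filters first, as they would on real data.  Pass
    ``selection=True/False`` to override.  Per-replicate seeds are split
    deterministically from ``seed``.  Failed replicates are recorded with
    ``ok=False`` rather than aborting the batch.  Use
    :func:`summarize_replicates` for rejection rates and coverage against
    the scenario truth.
    """
    from .pipeline import run_ivw_leg, run_presso_leg
    from .mediation import run_mediation

    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_reps)]
    if "selection" not in kwargs and analysis in ("ivw", "egger-intercept"):
        kwargs["selection"] = False
    rows = []
    for r, s in enumerate(rep_seeds):
        study = simulate_study(scenario, seed=s)
        row: dict = {"rep": r, "seed": s, "ok": True}
        try:
            if analysis == "ivw":
                est, nsel = run_ivw_leg(study.exposure, study.outcome, study.ld, **kwargs)
                row.update(
                    beta=est.beta, se=est.se, pval=est.pval,
                    ci_low=est.ci_low, ci_high=est.ci_high, n_snp=est.n_snp,
                )
            elif analysis == "egger-intercept":
                from .sensitivity import egger_intercept_test
                from .pipeline import harmonized_leg

                hd = harmonized_leg(study.exposure, study.outcome, study.ld, **kwargs)
                a, se_a, p_a = egger_intercept_test(hd)
                row.update(intercept=a, intercept_se=se_a, pval=p_a, n_snp=len(hd))
            elif analysis == "presso":
                # instruments are selected on exposure criteria alone: a
                # planted outlier of several outcome SEs would otherwise be
                # removed by the outcome-association filter before the
                # outlier test could ever see it
                from .selection import SelectionConfig

                cfg = kwargs.pop("config", None) or SelectionConfig(p_outcome_exclude=0.0)
                res = run_presso_leg(
                    study.exposure, study.outcome, study.ld, config=cfg, seed=s, **kwargs
                )
                row.update(
                    global_pval=res.global_pval,
                    n_outliers=len(res.outlier_ids),
                    outlier_ids=",".join(res.outlier_ids),
                    planted_recovered=bool(
                        set(study.truth["outlier_ids"]) <= set(res.outlier_ids)
                    ),
                )
            elif analysis == "mediation":
                kwargs.pop("selection", None)
                med = run_mediation(
                    study.exposure, study.mediator, study.outcome, study.ld, seed=s, **kwargs
                )
                row.update(
                    beta1=med.beta1, beta2=med.beta2, beta_all=med.beta_all,
                    beta12=med.beta12, prop_mediated=med.prop_mediated,
                    prop_abs=med.prop_abs,
                    direction_consistent=med.direction_consistent,
                )
            else:
                raise ConfigurationError(f"unknown analysis {analysis!r}")
        except ConfigurationError:
            raise
        except Exception as exc:  # per-rep failure is data, not fatal
            row["ok"] = False
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_replicates(
    table: pd.DataFrame, scenario: SimScenario, alpha: float = 0.05
) -> dict:
    """Mean/SD of estimates, rejection rate at ``alpha``, CI coverage of the
    scenario's true total effect (where the columns exist)."""
    ok = table[table["ok"]]
    out: dict = {"n_reps": len(table), "n_ok": len(ok)}
    if "beta" in ok:
        out["mean_beta"] = float(ok["beta"].mean())
        out["sd_beta"] = float(ok["beta"].std(ddof=1))
    if "pval" in ok:
        out["rejection_rate"] = float((ok["pval"] < alpha).mean())
    if {"ci_low", "ci_high"} <= set(ok.columns):
        truth = scenario.beta_all_true
        out["coverage"] = float(
            ((ok["ci_low"] <= truth) & (truth <= ok["ci_high"])).mean()
        )
    if "global_pval" in ok:
        out["global_rejection_rate"] = float((ok["global_pval"] < alpha).mean())
    if "planted_recovered" in ok:
        out["outlier_recovery_rate"] = float(ok["planted_recovered"].mean())
    if "prop_mediated" in ok:
        out["mean_prop_mediated"] = float(ok["prop_mediated"].mean())
        out["mean_prop_abs"] = float(ok["prop_abs"].mean())
    return out
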