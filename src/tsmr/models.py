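"""Model/Results front-end in the style of statsmodels.

:class:`MRModel` wraps a harmonized instrument set; ``fit()`` runs the
five-estimator battery and returns :class:`MRResults`, which carries the
estimates, exposes ``summary()``, the sensitivity battery, and minimal
diagnostic plots.  :class:`MediationModel` wraps the three trait datasets
of a two-step mediation design; ``fit()`` returns
:class:`MediationResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .estimators import MREstimate, estimate_all
from .mediation import MediationResult, run_mediation
from .selection import LDMatrix, SelectionConfig
from .sensitivity import (
    SensitivityReport,
    funnel_source,
    leave_one_out,
    scatter_source,
    sensitivity_report,
)
from .sumstats import HarmonizedDataset, SummaryDataset, harmonize


class MRModel:
    """Two-sample MR model for one exposure-outcome pair.

    Parameters
    ----------
    harmonized : HarmonizedDataset
        Per-SNP exposure/outcome effects on a shared effect allele.  Use
        :meth:`from_datasets` to harmonize two raw summary-statistics
        datasets, or :meth:`from_dataframe` for columns
        snp_id/beta_exp/se_exp/beta_out/se_out.
    """

    def __init__(self, harmonized: HarmonizedDataset):
        self.data = harmonized
        self.exposure_id = harmonized.exposure_id
        self.outcome_id = harmonized.outcome_id

    @classmethod
    def from_datasets(
        cls,
        exposure: SummaryDataset,
        outcome: SummaryDataset,
        drop_palindromic: bool = True,
    ) -> "MRModel":
        return cls(harmonize(exposure, outcome, drop_palindromic=drop_palindromic))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, exposure_id: str = "exposure", outcome_id: str = "outcome"
    ) -> "MRModel":
        return cls(HarmonizedDataset.from_frame(df, exposure_id, outcome_id))

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def fit(
        self,
        effects_model: str = "mre",
        n_boot: int = 1000,
        phi: float = 1.0,
        seed: int | None = None,
    ) -> "MRResults":
        estimates = estimate_all(
            self.data, effects_model=effects_model, n_boot=n_boot, phi=phi, seed=seed
        )
        return MRResults(self, estimates, seed=seed)


class MRResults:
    """Fitted five-method MR battery; IVW is the primary estimate."""

    def __init__(self, model: MRModel, estimates: dict[str, MREstimate], seed=None):
        self.model = model
        self.estimates = estimates
        self.seed = seed

    @property
    def primary(self) -> MREstimate:
        return self.estimates["IVW"]

    @property
    def beta(self) -> float:
        return self.primary.beta

    @property
    def se(self) -> float:
        return self.primary.se

    @property
    def pvalue(self) -> float:
        return self.primary.pval

    def conf_int(self) -> tuple[float, float]:
        return self.primary.ci_low, self.primary.ci_high

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates.values():
            row = {"exposure_id": self.model.exposure_id, "outcome_id": self.model.outcome_id}
            row.update(est.to_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> SimpleTable:
        """Forest-style table: per method the OR, 95% CI and p-value."""
        headers = ["method", "nSNP", "beta", "se", "OR", "95% CI", "p"]
        rows = []
        for est in self.estimates.values():
            lo, hi = est.or_ci
            rows.append(
                [
                    est.method,
                    str(est.n_snp),
                    f"{est.beta:.4f}",
                    f"{est.se:.4f}",
                    f"{est.odds_ratio:.3f}",
                    f"({lo:.3f}, {hi:.3f})",
                    f"{est.pval:.3g}",
                ]
            )
        title = f"Two-sample MR: {self.model.exposure_id} -> {self.model.outcome_id}"
        return SimpleTable(rows, headers=headers, title=title)

    def sensitivity(
        self, n_sim: int = 1000, significance: float = 0.05, seed: int | None = None
    ) -> SensitivityReport:
        return sensitivity_report(
            self.model.data,
            n_sim=n_sim,
            significance=significance,
            seed=self.seed if seed is None else seed,
        )

    def leave_one_out(self) -> pd.DataFrame:
        return leave_one_out(self.model.data)

    # -- minimal diagnostic plots (data tables are the primary artifact) --

    def plot_scatter(self, ax=None):
        """SNP effects on outcome vs exposure with the fitted IVW/Egger lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = scatter_source(self.model.data)
        ax.errorbar(
            df["beta_exp"], df["beta_out"],
            xerr=df["se_exp"], yerr=df["se_out"],
            fmt="o", ms=3, lw=0.7, alpha=0.8,
        )
        xs = np.linspace(0, df["beta_exp"].abs().max() * 1.05, 20)
        ax.plot(xs, self.beta * xs, label="IVW")
        if "MR-Egger" in self.estimates:
            eg = self.estimates["MR-Egger"]
            ax.plot(xs, eg.extras["intercept"] + eg.beta * xs, "--", label="MR-Egger")
        ax.set_xlabel(f"SNP effect on {self.model.exposure_id}")
        ax.set_ylabel(f"SNP effect on {self.model.outcome_id}")
        ax.legend()
        return ax

    def plot_funnel(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = funnel_source(self.model.data)
        ax.scatter(df["ratio"], 1.0 / df["se_ratio"], s=12)
        ax.axvline(self.beta, ls="--")
        ax.set_xlabel("per-SNP causal estimate")
        ax.set_ylabel("1 / SE")
        return ax

    def plot_forest(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        y = np.arange(len(df))[::-1]
        ax.errorbar(
            df["or"], y,
            xerr=[df["or"] - df["or_ci_low"], df["or_ci_high"] - df["or"]],
            fmt="s", capsize=3,
        )
        ax.axvline(1.0, color="grey", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(df["method"])
        ax.set_xlabel("odds ratio (95% CI)")
        return ax

    def plot_leave_one_out(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        loo = self.leave_one_out()
        y = np.arange(len(loo))[::-1]
        ax.errorbar(loo["beta"], y, xerr=1.96 * loo["se"], fmt="o", ms=3, capsize=2)
        ax.axvline(self.beta, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(loo["snp_id"], fontsize=6)
        ax.set_xlabel("IVW beta, one SNP omitted")
        return ax


class MediationModel:
    """Two-step MR mediation design over three trait datasets."""

    def __init__(
        self,
        exposure: SummaryDataset,
        mediator: SummaryDataset,
        outcome: SummaryDataset,
        ld: LDMatrix | None = None,
        selection: SelectionConfig | None = None,
    ):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.ld = ld
        self.selection = selection or SelectionConfig()

    def fit(
        self,
        seed: int | None = None,
        effects_model: str = "mre",
        full_battery: bool = False,
    ) -> "MediationResults":
        result = run_mediation(
            self.exposure,
            self.mediator,
            self.outcome,
            self.ld,
            self.selection,
            seed=seed,
            effects_model=effects_model,
            full_battery=full_battery,
        )
        return MediationResults(self, result)


class MediationResults:
    """Fitted mediation decomposition with a printable summary."""

    def __init__(self, model: MediationModel, result: MediationResult):
        self.model = model
        self.result = result

    def __getattr__(self, name):
        return getattr(self.__dict__["result"], name)

    def summary(self) -> SimpleTable:
        r = self.result
        rows = [
            ["beta1 (exposure->mediator)", f"{r.beta1:.4f}", f"{r.se1:.4f}"],
            ["beta2 (mediator->outcome)", f"{r.beta2:.4f}", f"{r.se2:.4f}"],
            ["beta_all (total)", f"{r.beta_all:.4f}", f"{r.se_all:.4f}"],
            ["beta12 (mediated)", f"{r.beta12:.4f}", f"{r.se12:.4f}"],
            ["beta_dir (direct)", f"{r.beta_dir:.4f}", f"{r.se_dir:.4f}"],
            ["mediated proportion (%)", f"{r.prop_mediated:.2f}", f"{r.se_prop:.2f}"],
            ["direction consistent", str(r.direction_consistent), ""],
        ]
        title = (
            f"Two-step MR mediation: {r.exposure_id} -> {r.mediator_id} -> {r.outcome_id}"
        )
        return SimpleTable(rows, headers=["quantity", "estimate", "se"], title=title)
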