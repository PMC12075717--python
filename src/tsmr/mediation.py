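"""Two-step MR mediation decomposition.

With β1 the exposure→mediator effect, β2 the mediator→outcome effect and
β_all the total exposure→outcome effect (each an IVW estimate from its own
instrument set), the mediated (indirect) effect is the product of
coefficients β12 = β1 × β2, the direct effect is β_dir = β_all − β12, and
the mediated proportion is β12/β_all × 100%.  The proportion is reported
signed; a mediated effect opposite in sign to the total effect
(inconsistent mediation / suppression) is flagged rather than silently
converted to a magnitude.  The SE of the product uses the first-order
delta method, sqrt(β1²·se2² + β2²·se1²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .exceptions import NoInstrumentsError
from .selection import LDMatrix, SelectionConfig
from .sumstats import SummaryDataset

Z95 = stats.norm.ppf(0.975)


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition with uncertainties.

    Invariant: ``beta_dir + beta12 == beta_all`` exactly by construction.
    """

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_all: float
    se_all: float
    beta12: float
    se12: float
    beta_dir: float
    se_dir: float
    prop_mediated: float        # signed, percent
    prop_abs: float
    se_prop: float              # percent, first-order delta
    ci12_low: float
    ci12_high: float
    direction_consistent: bool
    exposure_id: str = ""
    mediator_id: str = ""
    outcome_id: str = ""
    legs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "exposure_id", "mediator_id", "outcome_id",
                "beta1", "se1", "beta2", "se2", "beta_all", "se_all",
                "beta12", "se12", "beta_dir", "se_dir",
                "prop_mediated", "prop_abs", "se_prop",
                "ci12_low", "ci12_high", "direction_consistent",
            )
        }
        d["legs"] = {
            name: {m: est.to_row() for m, est in ests.items()}
            for name, ests in self.legs.items()
        }
        return d


def mediation_decompose(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    beta_all: float,
    se_all: float,
    exposure_id: str = "",
    mediator_id: str = "",
    outcome_id: str = "",
) -> MediationResult:
    """Decompose a total effect into mediated and direct components."""
    if beta_all == 0:
        raise ValueError("total effect is zero; mediated proportion undefined")
    for name, se in (("se1", se1), ("se2", se2), ("se_all", se_all)):
        if se <= 0:
            raise ValueError(f"{name} must be > 0")
    beta12 = beta1 * beta2
    se12 = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    beta_dir = beta_all - beta12
    se_dir = math.sqrt(se_all**2 + se12**2)
    prop = beta12 / beta_all * 100.0
    # delta-method SE of the ratio, legs treated as independent
    se_prop = 100.0 * math.sqrt(
        se12**2 / beta_all**2 + beta12**2 * se_all**2 / beta_all**4
    )
    return MediationResult(
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta_all=beta_all,
        se_all=se_all,
        beta12=beta12,
        se12=se12,
        beta_dir=beta_dir,
        se_dir=se_dir,
        prop_mediated=prop,
        prop_abs=abs(prop),
        se_prop=se_prop,
        ci12_low=beta12 - Z95 * se12,
        ci12_high=beta12 + Z95 * se12,
        # sign disagreement only counts as suppression when the mediated
        # effect is distinguishable from zero
        direction_consistent=(
            (beta12 > 0) == (beta_all > 0)
            or beta12 == 0
            or (beta12 - Z95 * se12) <= 0.0 <= (beta12 + Z95 * se12)
        ),
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
    )


def run_mediation(
    exposure_ds: SummaryDataset,
    mediator_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    seed: int | None = None,
    effects_model: str = "mre",
    full_battery: bool = False,
    n_boot: int = 1000,
) -> MediationResult:
    """Two-step MR: instrument each leg separately, estimate each with IVW,
    then decompose.

    Step 1 instruments the exposure against the mediator (β1); step 2
    instruments the mediator against the outcome (β2); the total leg
    instruments the exposure against the outcome (β_all).  With
    ``full_battery=True`` all five estimators are attached per leg (IVW
    still feeds the decomposition).
    """
    from .estimators import estimate_all, ivw
    from .pipeline import harmonized_leg

    legs_spec = [
        ("exposure->mediator", exposure_ds, mediator_ds),
        ("mediator->outcome", mediator_ds, outcome_ds),
        ("exposure->outcome", exposure_ds, outcome_ds),
    ]
    estimates = {}
    legs: dict = {}
    for name, exp, out in legs_spec:
        try:
            hd = harmonized_leg(exp, out, ld, config)
        except NoInstrumentsError as err:
            raise NoInstrumentsError(f"leg {name}: {err}") from None
        if full_battery:
            ests = estimate_all(hd, effects_model=effects_model, n_boot=n_boot, seed=seed)
        else:
            ests = {"IVW": ivw(hd, effects_model)}
        estimates[name] = ests["IVW"]
        legs[name] = ests

    b1, b2, ball = (
        estimates["exposure->mediator"],
        estimates["mediator->outcome"],
        estimates["exposure->outcome"],
    )
    result = mediation_decompose(
        b1.beta, b1.se, b2.beta, b2.se, ball.beta, ball.se,
        exposure_id=exposure_ds.trait_id,
        mediator_id=mediator_ds.trait_id,
        outcome_id=outcome_ds.trait_id,
    )
    result.legs = legs
    return result
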