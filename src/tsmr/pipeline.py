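"""Shared select -> harmonize -> estimate legs used by the mediation,
screening and replication layers."""

from __future__ import annotations

from .estimators import MREstimate, ivw
from .exceptions import NoInstrumentsError
from .selection import LDMatrix, SelectionConfig, select_instruments
from .sensitivity import PressoResult, mr_presso
from .sumstats import HarmonizedDataset, SummaryDataset, harmonize


def harmonized_leg(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    drop_palindromic: bool = True,
    selection: bool = True,
) -> HarmonizedDataset:
    """Select instruments from ``exposure``, then harmonize them against
    ``outcome``.  ``selection=False`` skips the filter pipeline and treats
    every exposure SNP as an instrument (estimator-level studies with a
    fixed instrument count).  Raises :class:`NoInstrumentsError` if nothing
    survives."""
    config = config or SelectionConfig()
    if selection:
        instruments, _ = select_instruments(exposure, outcome, ld, config)
    else:
        instruments = exposure
    if len(instruments) == 0:
        raise NoInstrumentsError(
            f"no instruments for {exposure.trait_id} -> {outcome.trait_id}"
        )
    hd = harmonize(instruments, outcome, drop_palindromic=drop_palindromic)
    if len(hd) == 0:
        raise NoInstrumentsError(
            f"no harmonized instruments for {exposure.trait_id} -> {outcome.trait_id}"
        )
    return hd


def run_ivw_leg(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    effects_model: str = "mre",
    selection: bool = True,
) -> tuple[MREstimate, int]:
    """One full IVW leg; returns the estimate and the instrument count."""
    hd = harmonized_leg(exposure, outcome, ld, config, selection=selection)
    return ivw(hd, effects_model), len(hd)


def run_presso_leg(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    n_sim: int = 1000,
    seed: int | None = None,
    selection: bool = True,
) -> PressoResult:
    """MR-PRESSO on the post-selection harmonized instrument set."""
    hd = harmonized_leg(exposure, outcome, ld, config, selection=selection)
    return mr_presso(hd, n_sim=n_sim, seed=seed)
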