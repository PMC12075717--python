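"""Instrument selection: significance filter, LD clumping, outcome-overlap
exclusion, exclusion lists, MAF and instrument-strength filters.

The pipeline applies, in order: genome-wide suggestive p-value filter
(p < 1e-5), greedy LD clumping (r² < 0.001 within ±10,000 kb), removal of
instruments associated with the outcome (p < 1e-5), a static exclusion
list (standing in for trait-lookup services such as LDtrait), a minor
allele frequency floor (MAF ≥ 0.01), and an instrument-strength floor
(F = (β/se)² > 10).  Order matters for clumping and is fixed; the
:class:`SelectionReport` partitions every candidate SNP into exactly one
disposition so the audit trail is reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .sumstats import SummaryDataset, VariantAssociation


@dataclass
class SelectionConfig:
    """Thresholds for the instrument-selection pipeline."""

    p_instrument: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    min_f: float = 10.0
    min_maf: float = 0.01
    p_outcome_exclude: float = 1e-5
    exclusion_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("p_instrument", "clump_kb", "min_f", "min_maf", "p_outcome_exclude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ConfigurationError("clump_r2 must lie in (0, 1]")
        self.exclusion_ids = frozenset(self.exclusion_ids)


class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over a set of SNPs."""

    def __init__(self, snp_ids: Iterable[str], r2: np.ndarray):
        self.snp_ids = list(snp_ids)
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ConfigurationError("LD matrix shape does not match snp_ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if (r2 < -1e-12).any() or (r2 > 1 + 1e-12).any():
            raise ConfigurationError("LD r2 values must lie in [0, 1]")
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, snp_ids: Iterable[str]) -> "LDMatrix":
        ids = list(snp_ids)
        return cls(ids, np.eye(len(ids)))

    @classmethod
    def read(cls, path) -> "LDMatrix":
        """Read either a square TSV (snp_ids as header and first column) or a
        long TSV with columns snp_a, snp_b, r2."""
        df = pd.read_csv(path, sep="\t")
        cols = [c.lower() for c in df.columns]
        if cols[:3] == ["snp_a", "snp_b", "r2"]:
            ids = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
            idx = {s: i for i, s in enumerate(ids)}
            mat = np.eye(len(ids))
            for a, b, r2 in df.itertuples(index=False):
                mat[idx[a], idx[b]] = r2
                mat[idx[b], idx[a]] = r2
            return cls(ids, mat)
        df = df.set_index(df.columns[0])
        return cls(list(df.index), df.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", index_label="snp_id"
        )


@dataclass
class SelectionReport:
    """Per-SNP disposition over the post-p-filter candidate set.

    Dispositions: ``kept``, ``failed-p``, ``clumped-out-by:<id>``,
    ``failed-f``, ``failed-maf``, ``outcome-associated``, ``excluded-list``.
    """

    dispositions: dict[str, str] = field(default_factory=dict)
    f_stats: dict[str, float] = field(default_factory=dict)
    final_ids: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.dispositions.values():
            key = d.split(":")[0]
            out[key] = out.get(key, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": s,
                "disposition": d,
                "f_stat": self.f_stats.get(s, float("nan")),
            }
            for s, d in self.dispositions.items()
        ]
        return pd.DataFrame(rows, columns=["snp_id", "disposition", "f_stat"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def filter_by_pvalue(ds: SummaryDataset, threshold: float = 1e-5) -> SummaryDataset:
    """Keep records with p strictly below ``threshold``."""
    return ds.subset(r.snp_id for r in ds if r.pval < threshold)


def f_statistic(assoc: VariantAssociation) -> float:
    """Single-SNP instrument-strength statistic (β/se)²."""
    if assoc.se <= 0:
        raise ValueError(f"{assoc.snp_id}: se must be positive")
    return (assoc.beta / assoc.se) ** 2


def clump(
    ds: SummaryDataset,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummaryDataset:
    """Greedy LD clumping.

    Repeatedly takes the remaining SNP with the smallest p-value (ties broken
    lexicographically by snp_id), keeps it as an index SNP, and removes all
    remaining SNPs on the same chromosome within ±``window_kb`` whose r² with
    it is at or above ``r2_threshold``.  Returns kept SNPs in the original
    dataset order.
    """
    kept, removed_by = _clump_with_log(ds, ld, r2_threshold, window_kb)
    return ds.subset(kept)


def _clump_with_log(
    ds: SummaryDataset, ld: LDMatrix, r2_threshold: float, window_kb: float
) -> tuple[list[str], dict[str, str]]:
    for r in ds:
        if r.snp_id not in ld:
            raise ConfigurationError(f"SNP {r.snp_id} absent from LD matrix")
    window_bp = window_kb * 1000.0
    remaining = {r.snp_id: r for r in ds}
    kept: list[str] = []
    removed_by: dict[str, str] = {}
    while remaining:
        index_id = min(remaining, key=lambda s: (remaining[s].pval, s))
        index = remaining.pop(index_id)
        kept.append(index_id)
        for other_id in list(remaining):
            other = remaining[other_id]
            if other.chrom != index.chrom:
                continue
            if abs(other.pos - index.pos) > window_bp:
                continue
            if ld.get(index_id, other_id) >= r2_threshold:
                remaining.pop(other_id)
                removed_by[other_id] = index_id
    kept_set = set(kept)
    ordered = [s for s in ds.snp_ids if s in kept_set]
    return ordered, removed_by


def filter_by_maf(ds: SummaryDataset, min_maf: float = 0.01) -> SummaryDataset:
    """Keep records with min(eaf, 1-eaf) >= ``min_maf``; missing eaf fails."""
    return ds.subset(
        r.snp_id for r in ds if r.maf is not None and r.maf >= min_maf
    )


def exclude_outcome_associated(
    instruments: SummaryDataset, outcome: SummaryDataset, threshold: float = 1e-5
) -> SummaryDataset:
    """Drop instruments whose p-value in the outcome GWAS is below
    ``threshold``; instruments absent from the outcome dataset are retained
    (they drop later at harmonization if still unmatched)."""
    keep = [
        r.snp_id
        for r in instruments
        if r.snp_id not in outcome or outcome[r.snp_id].pval >= threshold
    ]
    return instruments.subset(keep)


def apply_exclusion_list(
    instruments: SummaryDataset, exclusion_ids: Iterable[str]
) -> SummaryDataset:
    """Remove explicitly listed snp_ids (e.g. known outcome-trait variants)."""
    gone = set(exclusion_ids)
    return instruments.subset(r.snp_id for r in instruments if r.snp_id not in gone)


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset | None,
    ld: LDMatrix | None,
    config: SelectionConfig | None = None,
) -> tuple[SummaryDataset, SelectionReport]:
    """Run the full selection pipeline and return the final instrument set
    plus a report partitioning every candidate SNP.

    Stages, in order: p-filter -> clump -> outcome-association exclusion ->
    exclusion list -> MAF filter -> F filter.  ``ld=None`` treats all SNPs as
    independent (no clumping removals); ``outcome=None`` skips the
    outcome-association stage.
    """
    config = config or SelectionConfig()
    report = SelectionReport()

    stage0 = filter_by_pvalue(exposure, config.p_instrument)
    for r in exposure:
        if r.snp_id not in stage0:
            report.dispositions[r.snp_id] = "failed-p"

    if ld is not None:
        kept_ids, removed_by = _clump_with_log(stage0, ld, config.clump_r2, config.clump_kb)
        for snp, index_id in removed_by.items():
            report.dispositions[snp] = f"clumped-out-by:{index_id}"
        stage1 = stage0.subset(kept_ids)
    else:
        stage1 = stage0

    if outcome is not None:
        stage2 = exclude_outcome_associated(stage1, outcome, config.p_outcome_exclude)
        for r in stage1:
            if r.snp_id not in stage2:
                report.dispositions[r.snp_id] = "outcome-associated"
    else:
        stage2 = stage1

    stage3 = apply_exclusion_list(stage2, config.exclusion_ids)
    for r in stage2:
        if r.snp_id not in stage3:
            report.dispositions[r.snp_id] = "excluded-list"

    stage4 = filter_by_maf(stage3, config.min_maf)
    for r in stage3:
        if r.snp_id not in stage4:
            report.dispositions[r.snp_id] = "failed-maf"

    final_ids = []
    for r in stage4:
        f = f_statistic(r)
        report.f_stats[r.snp_id] = f
        if f > config.min_f:
            final_ids.append(r.snp_id)
            report.dispositions[r.snp_id] = "kept"
        else:
            report.dispositions[r.snp_id] = "failed-f"
    report.final_ids = final_ids
    return stage4.subset(final_ids), report
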