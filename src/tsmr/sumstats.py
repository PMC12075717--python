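"""GWAS summary-statistics containers, TSV I/O, and allele harmonization.

The central objects are :class:`SummaryDataset` (one trait's per-variant
association records) and :class:`HarmonizedDataset` (per-SNP exposure and
outcome effects aligned to a shared effect allele, the input to every MR
estimator).  Harmonization follows standard two-sample MR convention:
outcome records are re-oriented to the exposure's effect allele by jointly
swapping alleles, negating beta and complementing the effect-allele
frequency; palindromic variants (A/T, C/G), whose strand cannot be resolved
from alleles alone, are dropped by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import FormatError, HarmonizationError

VALID_ALLELES = frozenset("ACGT")

#: Canonical TSV column order for summary-statistics files.
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record for one trait.

    ``beta`` is the per-effect-allele effect on the trait (log odds for a
    binary trait); ``eaf`` and ``n`` may be ``None`` when the source file
    does not report them.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]: {self.eaf}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]: {self.pval}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; None if eaf missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryDataset:
    """Ordered collection of :class:`VariantAssociation` for one trait."""

    trait_id: str
    trait_name: str = ""
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        trait_id: str,
        records: Iterable[VariantAssociation],
        trait_name: str = "",
        metadata: dict | None = None,
    ) -> "SummaryDataset":
        out: dict[str, VariantAssociation] = {}
        for rec in records:
            if rec.snp_id in out:
                raise ValueError(f"duplicate snp_id {rec.snp_id!r} in {trait_id}")
            out[rec.snp_id] = rec
        return cls(trait_id, trait_name or trait_id, out, dict(metadata or {}))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> VariantAssociation:
        return self.records[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records)

    def subset(self, snp_ids: Iterable[str]) -> "SummaryDataset":
        """New dataset restricted to ``snp_ids``, preserving original order."""
        wanted = set(snp_ids)
        recs = {k: v for k, v in self.records.items() if k in wanted}
        return SummaryDataset(self.trait_id, self.trait_name, recs, dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(rec, c) for c in CANONICAL_COLUMNS} for rec in self
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")


@dataclass
class HarmonizedDataset:
    """Aligned exposure/outcome pairs plus a per-SNP disposition log.

    ``harmonization_log`` maps snp_id to ``(disposition, detail)`` where
    disposition is one of ``kept``, ``flipped``, ``dropped-palindromic``,
    ``dropped-allele-mismatch``, ``dropped-missing``.
    """

    exposure_id: str
    outcome_id: str
    pairs: list[HarmonizedPair] = field(default_factory=list)
    harmonization_log: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def drop(self, snp_ids: Iterable[str]) -> "HarmonizedDataset":
        """Copy without the listed SNPs (log untouched)."""
        gone = set(snp_ids)
        return HarmonizedDataset(
            self.exposure_id,
            self.outcome_id,
            [p for p in self.pairs if p.snp_id not in gone],
            dict(self.harmonization_log),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "snp_id", "effect_allele", "other_allele",
            "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out",
        ]
        return pd.DataFrame(
            [{c: getattr(p, c) for c in cols} for p in self.pairs], columns=cols
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, exposure_id: str = "exposure", outcome_id: str = "outcome"
    ) -> "HarmonizedDataset":
        pairs = []
        for row in df.itertuples(index=False):
            pairs.append(
                HarmonizedPair(
                    snp_id=str(row.snp_id),
                    effect_allele=getattr(row, "effect_allele", "A"),
                    other_allele=getattr(row, "other_allele", "G"),
                    beta_exp=float(row.beta_exp),
                    se_exp=float(row.se_exp),
                    beta_out=float(row.beta_out),
                    se_out=float(row.se_out),
                    eaf_exp=getattr(row, "eaf_exp", None),
                    eaf_out=getattr(row, "eaf_out", None),
                )
            )
        log = {p.snp_id: ("kept", "") for p in pairs}
        return cls(exposure_id, outcome_id, pairs, log)

    def write_log(self, path) -> None:
        rows = [
            {"snp_id": s, "disposition": d, "detail": detail}
            for s, (d, detail) in self.harmonization_log.items()
        ]
        pd.DataFrame(rows, columns=["snp_id", "disposition", "detail"]).to_csv(
            path, sep="\t", index=False
        )


#: Default column-name mapping for :func:`read_sumstats`.
DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in CANONICAL_COLUMNS}


def _parse_optional_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan", "."):
        return None
    return float(s)


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_name: str = "",
) -> SummaryDataset:
    """Read a tab-separated summary-statistics file.

    ``dialect`` maps canonical field names to the file's column names;
    unmapped optional fields (eaf, n, chrom, pos) are treated as missing.
    Rows whose mandatory fields cannot be parsed are dropped and counted in
    ``metadata['n_dropped_rows']``.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty summary-statistics file") from None
    for canon in _MANDATORY:
        if mapping[canon] not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {mapping[canon]!r} (for {canon})"
            )

    records: dict[str, VariantAssociation] = {}
    dropped = 0
    for _, row in df.iterrows():
        try:
            eaf = _parse_optional_float(row.get(mapping["eaf"]))
            n = _parse_optional_float(row.get(mapping["n"]))
            chrom = str(row.get(mapping["chrom"], "NA") or "NA")
            pos_raw = _parse_optional_float(row.get(mapping["pos"]))
            rec = VariantAssociation(
                snp_id=str(row[mapping["snp_id"]]),
                chrom=chrom,
                pos=int(pos_raw) if pos_raw is not None else 0,
                effect_allele=str(row[mapping["effect_allele"]]).upper(),
                other_allele=str(row[mapping["other_allele"]]).upper(),
                eaf=eaf,
                beta=float(row[mapping["beta"]]),
                se=float(row[mapping["se"]]),
                pval=float(row[mapping["pval"]]),
                n=n,
            )
        except (ValueError, TypeError, KeyError):
            dropped += 1
            continue
        records[rec.snp_id] = rec
    tid = trait_id or str(path)
    return SummaryDataset(
        tid, trait_name or tid, records, {"n_dropped_rows": dropped, "source": str(path)}
    )


def write_sumstats(ds: SummaryDataset, path) -> None:
    """Write a dataset as canonical TSV; missing values encoded ``NA``."""
    df = ds.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    for a in (effect_allele, other_allele):
        if a not in VALID_ALLELES:
            raise ValueError(f"invalid allele {a!r}")
    return _COMPLEMENT[effect_allele] == other_allele


def align_to_effect_allele(
    assoc: VariantAssociation, target_effect: str, target_other: str
) -> VariantAssociation:
    """Re-orient ``assoc`` so its effect allele is ``target_effect``.

    A swap negates beta and complements eaf; matching orientation is the
    identity.  Raises :class:`HarmonizationError` if the allele sets differ.
    """
    if (assoc.effect_allele, assoc.other_allele) == (target_effect, target_other):
        return assoc
    if (assoc.other_allele, assoc.effect_allele) == (target_effect, target_other):
        return replace(
            assoc,
            effect_allele=target_effect,
            other_allele=target_other,
            beta=-assoc.beta,
            eaf=None if assoc.eaf is None else 1.0 - assoc.eaf,
        )
    raise HarmonizationError(
        f"{assoc.snp_id}: allele set {{{assoc.effect_allele},{assoc.other_allele}}} "
        f"does not match target {{{target_effect},{target_other}}}"
    )


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    drop_palindromic: bool = True,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedDataset:
    """Intersect two datasets on snp_id and align outcome effects to the
    exposure's effect allele.

    Palindromic SNPs are dropped by default.  With
    ``drop_palindromic=False`` a palindromic SNP is kept only when both
    allele frequencies are far from 0.5 (outside
    ``0.5 ± palindromic_eaf_window``) and concordant, so the strand can be
    inferred; otherwise it is still dropped.
    """
    pairs: list[HarmonizedPair] = []
    log: dict[str, tuple[str, str]] = {}
    for snp_id, exp in exposure.records.items():
        if snp_id not in outcome:
            log[snp_id] = ("dropped-missing", "absent from outcome dataset")
            continue
        out = outcome[snp_id]
        if exp.chrom != "NA" and out.chrom != "NA" and (
            exp.chrom != out.chrom or (exp.pos and out.pos and exp.pos != out.pos)
        ):
            # builds differ between summary-stat releases; id match governs
            warnings.warn(
                f"{snp_id}: chrom/pos disagree between datasets "
                f"({exp.chrom}:{exp.pos} vs {out.chrom}:{out.pos})",
                stacklevel=2,
            )
        if is_palindromic(exp.effect_allele, exp.other_allele):
            if drop_palindromic:
                log[snp_id] = ("dropped-palindromic", f"{exp.effect_allele}/{exp.other_allele}")
                continue
            lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window
            if (
                exp.eaf is None
                or out.eaf is None
                or lo < exp.eaf < hi
                or lo < out.eaf < hi
                or (exp.eaf < 0.5) != (out.eaf < 0.5)
            ):
                log[snp_id] = ("dropped-palindromic", "strand not inferable from eaf")
                continue
        try:
            aligned = align_to_effect_allele(out, exp.effect_allele, exp.other_allele)
        except HarmonizationError:
            # try strand-complemented orientation before giving up
            comp_e, comp_o = _COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele]
            if {comp_e, comp_o} == {exp.effect_allele, exp.other_allele} and not is_palindromic(
                exp.effect_allele, exp.other_allele
            ):
                flipped = replace(out, effect_allele=comp_e, other_allele=comp_o)
                aligned = align_to_effect_allele(flipped, exp.effect_allele, exp.other_allele)
            else:
                log[snp_id] = (
                    "dropped-allele-mismatch",
                    f"exposure {exp.effect_allele}/{exp.other_allele} vs "
                    f"outcome {out.effect_allele}/{out.other_allele}",
                )
                continue
        swapped = out.effect_allele in (exp.other_allele, _COMPLEMENT[exp.other_allele])
        log[snp_id] = ("flipped", "") if swapped else ("kept", "")
        pairs.append(
            HarmonizedPair(
                snp_id=snp_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=aligned.beta,
                se_out=aligned.se,
                eaf_exp=exp.eaf,
                eaf_out=aligned.eaf,
            )
        )
    if not pairs and len(exposure) > 0:
        warnings.warn(
            f"harmonization of {exposure.trait_id} vs {outcome.trait_id} "
            "produced no pairs",
            stacklevel=2,
        )
    return HarmonizedDataset(exposure.trait_id, outcome.trait_id, pairs, log)
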