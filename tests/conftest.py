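"""Shared fixtures: hand-computed instrument sets and constructed datasets."""

from __future__ import annotations

import numpy as np
import pytest

from tsmr.sumstats import (
    HarmonizedDataset,
    HarmonizedPair,
    SummaryDataset,
    VariantAssociation,
)


def make_hd(bx, by, sy, sx=None, exposure_id="X", outcome_id="Y") -> HarmonizedDataset:
    """Harmonized dataset from effect arrays (se_exp defaults to 1e-6,
    effectively noise-free exposure betas)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, dtype=float)
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{i + 1}",
            effect_allele="A",
            other_allele="G",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
        )
        for i in range(len(bx))
    ]
    log = {p.snp_id: ("kept", "") for p in pairs}
    return HarmonizedDataset(exposure_id, outcome_id, pairs, log)


def make_variant(snp_id, beta=0.1, se=0.01, pval=1e-8, eaf=0.3, chrom="1",
                 pos=1_000_000, ea="A", oa="G", n=10_000.0) -> VariantAssociation:
    return VariantAssociation(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_dataset(trait_id, variants) -> SummaryDataset:
    return SummaryDataset.from_records(trait_id, variants)


@pytest.fixture
def hand_ivw_pair() -> HarmonizedDataset:
    """Two instruments with beta_X=(0.1,0.2), beta_Y=(0.05,0.10),
    se_Y=(0.01,0.01): the IVW slope is 0.5 with fixed SE sqrt(1/500)."""
    return make_hd([0.1, 0.2], [0.05, 0.10], [0.01, 0.01])


@pytest.fixture
def exact_linear_hd() -> HarmonizedDataset:
    """Four instruments lying exactly on beta_Y = 0.02 + 0.5 beta_X."""
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    return make_hd(bx, 0.02 + 0.5 * bx, [0.01, 0.02, 0.015, 0.01])


@pytest.fixture
def exact_origin_hd() -> HarmonizedDataset:
    """Five instruments exactly on beta_Y = 0.3 beta_X (no intercept): every
    estimator in the battery must return 0.3."""
    bx = np.array([0.1, 0.15, 0.2, 0.3, 0.4])
    return make_hd(bx, 0.3 * bx, [0.01, 0.02, 0.01, 0.015, 0.02])


@pytest.fixture
def cochran_hand_hd() -> HarmonizedDataset:
    """Two instruments with ratios 0 and 1 and equal IVW weights 100
    (beta_X=1, se_Y=0.1): IVW slope 0.5 and Q = 50."""
    return make_hd([1.0, 1.0], [0.0, 1.0], [0.1, 0.1])


def random_hd(rng: np.random.Generator, j: int = 8) -> HarmonizedDataset:
    bx = rng.normal(0.1, 0.05, j)
    bx[np.abs(bx) < 1e-3] = 0.05
    sy = rng.uniform(0.005, 0.05, j)
    by = 0.4 * bx + rng.normal(0, sy)
    sx = rng.uniform(0.001, 0.01, j)
    return make_hd(bx, by, sy, sx)
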