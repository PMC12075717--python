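"""Instrument-selection filters, LD clumping, and the pipeline audit trail."""

import itertools

import numpy as np
import pytest

from tsmr.exceptions import ConfigurationError
from tsmr.selection import (
    LDMatrix,
    SelectionConfig,
    apply_exclusion_list,
    clump,
    exclude_outcome_associated,
    f_statistic,
    filter_by_maf,
    filter_by_pvalue,
    select_instruments,
)

from conftest import make_dataset, make_variant


class TestSimpleFilters:
    def test_pvalue_filter_is_strict(self):
        ds = make_dataset("t", [
            make_variant("rs1", pval=1e-6),
            make_variant("rs2", pval=1e-5),
            make_variant("rs3", pval=1e-4),
        ])
        kept = filter_by_pvalue(ds, 1e-5)
        assert kept.snp_ids == ["rs1"]

    def test_pvalue_filter_threshold_one_keeps_all(self):
        ds = make_dataset("t", [make_variant("rs1", pval=0.99), make_variant("rs2")])
        assert len(filter_by_pvalue(ds, 1.0)) == 2
        assert len(filter_by_pvalue(make_dataset("t", []), 1e-5)) == 0

    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.01, 100.0), (0.0, 0.05, 0.0), (0.0316, 0.01, 9.9856)],
    )
    def test_f_statistic_arithmetic(self, beta, se, expected):
        f = f_statistic(make_variant("rs1", beta=beta, se=se, pval=0.5))
        assert f == pytest.approx(expected, abs=1e-9)

    def test_weak_instrument_fails_default_floor(self):
        f = f_statistic(make_variant("rs1", beta=0.0316, se=0.01, pval=1e-6))
        assert f < 10.0

    @pytest.mark.parametrize("eaf,kept", [(0.005, False), (0.5, True), (0.995, False),
                                          (0.01, True), (None, False)])
    def test_maf_filter_symmetry_and_missing(self, eaf, kept):
        ds = make_dataset("t", [make_variant("rs1", eaf=eaf)])
        assert (len(filter_by_maf(ds, 0.01)) == 1) is kept

    def test_outcome_associated_instruments_removed(self):
        instruments = make_dataset("X", [
            make_variant("rs1"), make_variant("rs2"), make_variant("rs3"),
        ])
        outcome = make_dataset("Y", [
            make_variant("rs1", pval=1e-7),
            make_variant("rs2", pval=0.5),
        ])
        kept = exclude_outcome_associated(instruments, outcome, 1e-5)
        # rs1 removed; rs2 kept; rs3 absent from outcome and retained here
        assert kept.snp_ids == ["rs2", "rs3"]

    def test_exclusion_list_removes_known_outcome_variants(self):
        ds = make_dataset("X", [make_variant("rs3184504"), make_variant("rs1446585"),
                                make_variant("rs42")])
        assert apply_exclusion_list(ds, {"rs3184504"}).snp_ids == ["rs1446585", "rs42"]
        assert apply_exclusion_list(ds, {"rs1446585"}).snp_ids == ["rs3184504", "rs42"]
        assert apply_exclusion_list(ds, set()).snp_ids == ds.snp_ids


def _greedy_oracle(records, ld, r2_threshold, window_bp):
    """Independent clumping oracle: enumerate every maximal conflict-free
    subset (maximal cliques of the complement of the conflict graph) and
    pick the lexicographically first under the (p, snp_id) vertex order —
    which is what greedy index selection produces."""
    import networkx as nx

    rec = {r.snp_id: r for r in records}

    def conflict(a, b):
        ra, rb = rec[a], rec[b]
        return (
            ra.chrom == rb.chrom
            and abs(ra.pos - rb.pos) <= window_bp
            and ld.get(a, b) >= r2_threshold
        )

    g = nx.Graph()
    g.add_nodes_from(rec)
    g.add_edges_from(
        (a, b) for a, b in itertools.combinations(rec, 2) if conflict(a, b)
    )
    maximal_valid = nx.find_cliques(nx.complement(g))
    key = lambda s: sorted((rec[i].pval, i) for i in s)  # noqa: E731
    return set(min(maximal_valid, key=key))


class TestClumping:
    def test_hand_worked_three_snp_case(self):
        # s2 is in LD with the better s1; s3 is independent of both
        ds = make_dataset("t", [
            make_variant("s1", pval=1e-8, pos=1_000_000),
            make_variant("s2", pval=1e-6, pos=1_100_000),
            make_variant("s3", pval=1e-7, pos=5_000_000),
        ])
        r2 = np.array([[1, 0.5, 0.0005], [0.5, 1, 0.0005], [0.0005, 0.0005, 1]])
        ld = LDMatrix(["s1", "s2", "s3"], r2)
        kept = clump(ds, ld, r2_threshold=0.001, window_kb=10_000)
        assert kept.snp_ids == ["s1", "s3"]

    def test_independent_snps_all_kept(self):
        ds = make_dataset("t", [make_variant(f"s{i}", pos=i * 10**6) for i in range(5)])
        kept = clump(ds, LDMatrix.identity(ds.snp_ids), 0.001, 10_000)
        assert kept.snp_ids == ds.snp_ids

    def test_perfect_ld_keeps_smaller_p(self):
        ds = make_dataset("t", [
            make_variant("a", pval=1e-6, pos=100),
            make_variant("b", pval=1e-9, pos=100),
        ])
        ld = LDMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert clump(ds, ld, 0.001, 10_000).snp_ids == ["b"]

    def test_snp_missing_from_ld_raises(self):
        ds = make_dataset("t", [make_variant("a"), make_variant("b")])
        with pytest.raises(ConfigurationError, match="b"):
            clump(ds, LDMatrix.identity(["a"]), 0.001, 10_000)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for trial in range(200):
            j = int(rng.integers(2, 13))
            ids = [f"s{k:02d}" for k in range(j)]
            # random LD with clusters of elevated r2
            raw = rng.uniform(0, 1, (j, j))
            r2 = np.where(rng.uniform(size=(j, j)) < 0.4, raw, raw * 0.001)
            r2 = np.triu(r2, 1)
            r2 = r2 + r2.T + np.eye(j)
            r2 = np.clip(r2, 0, 1)
            np.fill_diagonal(r2, 1.0)
            ld = LDMatrix(ids, r2)
            chroms = rng.choice(["1", "2"], j)
            ds = make_dataset("t", [
                make_variant(ids[k], pval=float(rng.uniform(1e-12, 1e-4)),
                             chrom=str(chroms[k]),
                             pos=int(rng.integers(1, 3 * 10**7)))
                for k in range(j)
            ])
            kept = clump(ds, ld, 0.05, window_kb=10_000)
            oracle = _greedy_oracle(list(ds), ld, 0.05, 10_000 * 1000)
            assert set(kept.snp_ids) == oracle, f"trial {trial}"
            # kept set is conflict-free
            for a, b in itertools.combinations(kept.snp_ids, 2):
                ra, rb = ds[a], ds[b]
                if ra.chrom == rb.chrom and abs(ra.pos - rb.pos) <= 10**7:
                    assert ld.get(a, b) < 0.05


def twenty_snp_fixture():
    """20 candidate SNPs with two planted failures per filter and ten clean
    survivors; expected dispositions are returned alongside.

    The two F-filter failures carry reported p-values from a different
    association model than their beta/se (otherwise any SNP passing the
    p-filter would have F > 19 under a Wald p and could never fail F > 10).
    """
    strong = dict(beta=0.1, se=0.01, pval=1e-8, eaf=0.3)  # F = 100
    v, expected = [], {}

    for i, sid in enumerate(["pfail1", "pfail2"]):
        v.append(make_variant(sid, pval=1e-4, pos=10**6 * (40 + i), beta=0.1, se=0.01))
        expected[sid] = "failed-p"
    v.append(make_variant("idx1", pos=1_000_000, **strong))
    expected["idx1"] = "kept"
    for i, sid in enumerate(["clump1", "clump2"]):
        v.append(make_variant(sid, pval=1e-6, pos=1_100_000 + i * 1000,
                              beta=0.1, se=0.015, eaf=0.3))
        expected[sid] = "clumped-out-by:idx1"
    for i, sid in enumerate(["outassoc1", "outassoc2"]):
        v.append(make_variant(sid, pos=10**6 * (50 + i), **strong))
        expected[sid] = "outcome-associated"
    for i, sid in enumerate(["raremaf1", "raremaf2"]):
        v.append(make_variant(sid, pos=10**6 * (70 + i), beta=0.1, se=0.01,
                              pval=1e-8, eaf=0.005))
        expected[sid] = "failed-maf"
    for i, sid in enumerate(["weakf1", "weakf2"]):
        v.append(make_variant(sid, pos=10**6 * (80 + i), beta=0.03, se=0.01,
                              pval=1e-6, eaf=0.3))
        expected[sid] = "failed-f"
    for i in range(9):
        sid = f"clean{i}"
        v.append(make_variant(sid, pos=10**6 * (100 + i), **strong))
        expected[sid] = "kept"

    exposure = make_dataset("X", v)
    outcome = make_dataset("Y", [
        make_variant("outassoc1", pval=1e-7),
        make_variant("outassoc2", pval=1e-9),
        make_variant("idx1", pval=0.4),
    ])
    assert len(v) == 20
    r2 = np.eye(20)
    ids = exposure.snp_ids
    for sid in ("clump1", "clump2"):
        a, b = ids.index("idx1"), ids.index(sid)
        r2[a, b] = r2[b, a] = 0.8
    ld = LDMatrix(ids, r2)
    config = SelectionConfig()
    return exposure, outcome, ld, config, expected


class TestSelectionPipeline:
    def test_planted_dispositions_recovered_exactly(self):
        exposure, outcome, ld, config, expected = twenty_snp_fixture()
        final, report = select_instruments(exposure, outcome, ld, config)
        assert report.dispositions == expected
        assert len(final) == 10
        assert set(final.snp_ids) == {s for s, d in expected.items() if d == "kept"}

    def test_dispositions_partition_the_input(self):
        exposure, outcome, ld, config, _ = twenty_snp_fixture()
        _, report = select_instruments(exposure, outcome, ld, config)
        assert set(report.dispositions) == set(exposure.snp_ids)
        kept = [s for s, d in report.dispositions.items() if d == "kept"]
        assert sorted(kept) == sorted(report.final_ids)
        counts = report.counts()
        assert sum(counts.values()) == len(exposure)

    def test_all_pass_returns_clumped_set(self):
        ds = make_dataset("X", [
            make_variant(f"s{i}", pos=i * 10**6, beta=0.1, se=0.01, pval=1e-8)
            for i in range(5)
        ])
        final, report = select_instruments(ds, None, LDMatrix.identity(ds.snp_ids),
                                           SelectionConfig())
        assert final.snp_ids == ds.snp_ids

    def test_nothing_passes_pfilter_gives_empty_set(self):
        ds = make_dataset("X", [make_variant("s1", pval=0.5)])
        final, report = select_instruments(ds, None, None, SelectionConfig())
        assert len(final) == 0
        assert report.dispositions == {"s1": "failed-p"}

    def test_maf_and_f_filters_commute(self):
        rng = np.random.default_rng(5)
        ds = make_dataset("X", [
            make_variant(f"s{i}", beta=float(rng.normal(0, 0.1)),
                         se=float(rng.uniform(0.005, 0.05)),
                         eaf=float(rng.uniform(0.001, 0.999)), pval=1e-8)
            for i in range(30)
        ])
        from tsmr.selection import f_statistic as F

        def f_filter(d):
            return d.subset(r.snp_id for r in d if F(r) > 10)

        a = filter_by_maf(f_filter(ds), 0.01).snp_ids
        b = f_filter(filter_by_maf(ds, 0.01)).snp_ids
        assert a == b


class TestLDMatrixIO:
    def test_square_round_trip(self, tmp_path):
        ids = ["a", "b", "c"]
        r2 = np.array([[1, 0.2, 0.0], [0.2, 1, 0.5], [0.0, 0.5, 1]])
        LDMatrix(ids, r2).write(tmp_path / "ld.tsv")
        back = LDMatrix.read(tmp_path / "ld.tsv")
        assert back.snp_ids == ids
        np.testing.assert_allclose(back.r2, r2)

    def test_long_format(self, tmp_path):
        p = tmp_path / "ld_long.tsv"
        p.write_text("snp_a\tsnp_b\tr2\na\tb\t0.3\n")
        ld = LDMatrix.read(p)
        assert ld.get("a", "b") == pytest.approx(0.3)
        assert ld.get("a", "a") == 1.0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))  # asymmetric
        with pytest.raises(ConfigurationError):
            LDMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 1.0]]))  # r2 > 1
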