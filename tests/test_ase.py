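import numpy as np
import pandas as pd
import pytest

import triadseq as tq
from triadseq.ase import SNP_COLUMNS, validate_snp_table


def snp_table(rows):
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


class TestSnpRatio:
    @pytest.mark.parametrize(
        "r0,r1,expected", [(10, 0, 0.0), (10, 10, 0.5), (0, 10, 1.0)]
    )
    def test_endpoint_semantics(self, r0, r1, expected):
        assert tq.snp_ratio(r0, r1) == expected

    def test_zero_total_untestable(self):
        with pytest.raises(tq.ValidationError):
            tq.snp_ratio(0, 0)


class TestCallAseGenes:
    def test_two_skewed_snps_called(self):
        snps = snp_table(
            [
                ("H", "1", 100, "gA", 20, 0),
                ("H", "1", 200, "gA", 20, 0),
            ]
        )
        res = tq.ASEModel(snps).fit()
        row = res.table.loc[("H", "gA")]
        assert bool(row["is_ase"])
        assert row["direction"] == "toward_allele0"
        assert row["ase_level"] == 0.0

    def test_balanced_snps_not_called(self):
        snps = snp_table(
            [
                ("H", "1", 100, "gA", 10, 10),
                ("H", "1", 200, "gA", 10, 10),
            ]
        )
        assert not tq.ASEModel(snps).fit().table["is_ase"].any()

    def test_single_snp_gene_excluded_by_min_snps(self):
        snps = snp_table([("H", "1", 100, "gA", 50, 0)])
        assert not tq.ASEModel(snps).fit().table["is_ase"].any()

    def test_discordant_snps_not_called(self):
        snps = snp_table(
            [
                ("H", "1", 100, "gA", 30, 0),
                ("H", "1", 200, "gA", 0, 30),
            ]
        )
        res = tq.ASEModel(snps).fit()
        assert not res.table["is_ase"].any()  # opposite sides of 0.5

    def test_gene_level_p_weighted_by_depth(self):
        snps = snp_table(
            [
                ("H", "1", 100, "gA", 0, 90),   # P = 1, 90 reads
                ("H", "1", 200, "gA", 10, 0),   # P = 0, 10 reads
            ]
        )
        res = tq.ASEModel(snps).fit()
        assert res.table.loc[("H", "gA"), "ase_level"] == pytest.approx(0.9)
        pooled = tq.ASEModel(snps, aggregation="pooled").fit()
        assert pooled.table.loc[("H", "gA"), "ase_level"] == pytest.approx(0.9)

    def test_single_snp_gene_level_equals_snp_level(self):
        snps = snp_table([("H", "1", 100, "gA", 13, 37)])
        res = tq.ASEModel(snps).fit()
        assert res.table.loc[("H", "gA"), "ase_level"] == pytest.approx(37 / 50)

    def test_snp_order_invariance(self):
        rows = [
            ("H", "1", 100, "gA", 5, 45),
            ("H", "1", 200, "gA", 10, 40),
            ("H", "1", 300, "gA", 2, 48),
        ]
        a = tq.ASEModel(snp_table(rows)).fit().table
        b = tq.ASEModel(snp_table(rows[::-1])).fit().table
        assert (a == b).all().all()

    def test_bh_family_is_per_hybrid(self):
        rows = [
            ("H1", "1", 100, "gA", 20, 0),
            ("H1", "1", 200, "gA", 20, 0),
            ("H2", "2", 100, "gB", 10, 10),
            ("H2", "2", 200, "gB", 10, 10),
        ]
        res = tq.ASEModel(snp_table(rows)).fit()
        sub = res.snp_table
        # H1's q must be unaffected by H2's null SNPs: q == p within family of 2
        h1 = sub[sub["hybrid_id"] == "H1"]
        assert np.allclose(h1["q"], h1["p"])

    def test_relaxed_rule_uses_pooled_gene_test(self):
        # 3 shallow concordant SNPs: none individually significant
        # (each 8/10, p = 0.109), but the pooled 24/30 imbalance is
        rows = [
            ("H", "1", 100, "gA", 2, 8),
            ("H", "1", 200, "gA", 2, 8),
            ("H", "1", 300, "gA", 2, 8),
        ]
        strict = tq.ASEModel(snp_table(rows)).fit()
        relaxed = tq.ASEModel(snp_table(rows), rule="relaxed").fit()
        assert not strict.table["is_ase"].any()
        assert relaxed.table["is_ase"].all()

    def test_zero_read_snps_dropped(self):
        rows = [
            ("H", "1", 100, "gA", 0, 0),
            ("H", "1", 200, "gA", 20, 0),
            ("H", "1", 300, "gA", 20, 0),
        ]
        res = tq.ASEModel(snp_table(rows)).fit()
        assert res.table.loc[("H", "gA"), "n_snps_total"] == 2


class TestValidation:
    def test_duplicate_position_rejected(self):
        rows = [("H", "1", 100, "gA", 1, 1), ("H", "1", 100, "gA", 2, 2)]
        with pytest.raises(tq.ValidationError, match="duplicate"):
            validate_snp_table(snp_table(rows))

    def test_inconsistent_gene_assignment_rejected(self):
        rows = [("H1", "1", 100, "gA", 1, 1), ("H2", "1", 100, "gB", 2, 2)]
        with pytest.raises(tq.ValidationError, match="multiple genes"):
            validate_snp_table(snp_table(rows))

    def test_tsv_round_trip(self, tmp_path):
        rows = [("H", "1", 100, "gA", 5, 45), ("H", "1", 200, "gA", 10, 40)]
        path = tmp_path / "snps.tsv"
        tq.write_snp_counts(snp_table(rows), path)
        back = tq.read_snp_counts(path)
        assert (back == snp_table(rows)).all().all()

    def test_minimal_vcf_reader(self, tmp_path):
        vcf = tmp_path / "ase.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tH1\n"
            "1\t100\t.\tA\tG\t.\tPASS\tGENE=gA\tGT:AD\t0/1:12,38\n"
            "1\t200\t.\tC\tT\t.\tPASS\tGENE=gA\tGT:AD\t0/1:5,45\n"
        )
        df = tq.read_vcf_allele_counts(vcf, hybrid_id="H1")
        assert list(df["reads_allele0"]) == [12, 5]
        assert list(df["reads_allele1"]) == [38, 45]
        assert set(df["gene_id"]) == {"gA"}


class TestSummariesAndOverlap:
    @pytest.mark.parametrize(
        "n_ase,n_analyzed,pct", [(2263, 17563, 12.89), (2352, 16059, 14.65), (0, 10, 0.0)]
    )
    def test_ratio_percentages(self, n_ase, n_analyzed, pct):
        assert tq.ase_summary(n_ase, n_analyzed).ratio_pct == pct

    def test_zero_denominator_rejected(self):
        with pytest.raises(tq.ValidationError):
            tq.ase_summary(0, 0)

    def test_reported_overlap_counts(self):
        both = {f"b{i}" for i in range(161)}
        ase_h1 = both | {f"h{i}" for i in range(125)}
        ase_h2 = both | {f"c{i}" for i in range(100)}
        degs = ase_h1 | ase_h2 | {f"d{i}" for i in range(500)}
        ov = tq.ase_deg_overlap(ase_h1, ase_h2, degs)
        assert ov.to_dict() == {"both": 161, "only_h1": 125, "only_h2": 100}

    def test_disjoint_and_identical_sets(self):
        degs = {"a", "b", "c"}
        assert tq.ase_deg_overlap({"a"}, {"b"}, degs).both == frozenset()
        ov = tq.ase_deg_overlap({"a", "b"}, {"a", "b"}, degs)
        assert ov.only_h1 == frozenset() and ov.only_h2 == frozenset()

    def test_overlap_restricted_to_degs(self):
        ov = tq.ase_deg_overlap({"a", "x"}, {"a", "y"}, {"a"})
        assert ov.to_dict() == {"both": 1, "only_h1": 0, "only_h2": 0}
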