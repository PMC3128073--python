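"""SNP-to-gene assignment: window rule, ties, exclusions, LD extension."""

import numpy as np
import pytest

import genewise as gw

from conftest import make_dataset, random_dataset


def snp(sid, chrom, pos):
    return gw.SnpRecord(snp_id=sid, chrom=chrom, pos=pos)


def gene(gid, chrom, start, end):
    return gw.GeneAnnotation(gene_id=gid, symbol=gid, chrom=chrom, start=start, end=end)


class TestAssignSnps:
    def test_snp_within_40kb_upstream_assigned(self):
        g = gene("A", "chr1", 100_000, 110_000)
        s = snp("rs1", "chr1", 100_000 - 39_999)
        amap = gw.assign_snps([s], [g], window_bp=40_000)
        assert amap.gene_to_snps == {"A": ["rs1"]}

    def test_snp_beyond_window_unassigned(self):
        g = gene("A", "chr1", 100_000, 110_000)
        s = snp("rs1", "chr1", 100_000 - 40_001)
        amap = gw.assign_snps([s], [g], window_bp=40_000)
        assert amap.gene_to_snps == {}

    def test_closest_gene_wins(self):
        a = gene("A", "chr1", 100_000, 110_000)
        b = gene("B", "chr1", 130_000, 140_000)
        s = snp("rs1", "chr1", 112_000)  # 2kb past A, 18kb before B
        amap = gw.assign_snps([s], [a, b], window_bp=40_000)
        assert amap.snp_to_genes["rs1"] == ["A"]

    def test_equidistant_tie_broken_alphabetically(self):
        a = gene("A", "chr1", 100_000, 110_001)
        b = gene("B", "chr1", 120_000, 130_000)
        s = snp("rs1", "chr1", 115_000)  # 5000 bp from A's last base and B's start
        amap = gw.assign_snps([s], [b, a], window_bp=40_000)
        assert amap.snp_to_genes["rs1"] == ["A"]

    def test_mhc_style_exclusion_removes_snps_and_genes(self):
        region = gw.GenomicRegion.from_ucsc("chr6:25,930,839-33,495,825")
        inside_snp = snp("rs_in", "chr6", 30_000_000)
        outside_snp = snp("rs_out", "chr6", 40_000_000)
        inside_gene = gene("HLA", "chr6", 29_990_000, 30_010_000)
        outside_gene = gene("FAR", "chr6", 39_990_000, 40_010_000)
        amap = gw.assign_snps(
            [inside_snp, outside_snp], [inside_gene, outside_gene],
            window_bp=40_000, exclude=[region],
        )
        assert amap.gene_to_snps == {"FAR": ["rs_out"]}

    def test_region_string_is_one_based_inclusive(self):
        region = gw.GenomicRegion.from_ucsc("chr6:101-200")
        assert (region.start, region.end) == (100, 200)
        assert region.contains("chr6", 100) and region.contains("chr6", 199)
        assert not region.contains("chr6", 99) and not region.contains("chr6", 200)

    def test_gene_order_independence(self, rng):
        genes = [
            gene(f"G{i}", "chr1", int(s), int(s) + 5_000)
            for i, s in enumerate(rng.integers(0, 500_000, 30))
        ]
        snps = [snp(f"rs{j}", "chr1", int(p)) for j, p in enumerate(rng.integers(0, 550_000, 200))]
        fwd = gw.assign_snps(snps, genes)
        rev = gw.assign_snps(snps, genes[::-1])
        assert fwd.to_frame().equals(rev.to_frame())

    def test_base_assignment_is_a_partial_function(self, rng):
        genes = [gene(f"G{i}", "chr1", i * 100_000, i * 100_000 + 10_000) for i in range(10)]
        snps = [snp(f"rs{j}", "chr1", int(p)) for j, p in enumerate(rng.integers(0, 1_000_000, 300))]
        amap = gw.assign_snps(snps, genes)
        assert int(amap.n_per_gene.sum()) == amap.n_assigned_snps
        assert all(len(v) == 1 for v in amap.snp_to_genes.values())


class TestLdPairs:
    def test_duplicated_column_in_perfect_ld(self, rng):
        col = rng.binomial(2, 0.4, 100).astype(float)
        d = np.column_stack([col, col, rng.binomial(2, 0.4, 100)])
        data = make_dataset(d, [1] * 50 + [0] * 50)
        ld = gw.compute_ld_pairs(data, r2_min=0.8)
        pairs = set(zip(ld.pairs.snp_a, ld.pairs.snp_b))
        assert ("snp000", "snp001") in pairs
        assert ld.pairs.loc[
            (ld.pairs.snp_a == "snp000") & (ld.pairs.snp_b == "snp001"), "r2"
        ].iloc[0] == pytest.approx(1.0)

    def test_independent_snps_low_r2(self, rng):
        d = rng.binomial(2, 0.3, size=(3000, 2)).astype(float)
        data = make_dataset(d, [1] * 1500 + [0] * 1500)
        ld = gw.compute_ld_pairs(data, r2_min=0.01)
        assert len(ld.pairs) == 0

    def test_monomorphic_snp_contributes_no_pairs(self, rng):
        d = np.column_stack([np.ones(60), rng.binomial(2, 0.4, 60)]).astype(float)
        data = make_dataset(d, [1] * 30 + [0] * 30)
        ld = gw.compute_ld_pairs(data, r2_min=0.0)
        assert len(ld.pairs) == 0

    def test_pairs_outside_window_skipped(self, rng):
        col = rng.binomial(2, 0.4, 100).astype(float)
        d = np.column_stack([col, col])
        data = make_dataset(d, [1] * 50 + [0] * 50, spacing=2_000_000)
        ld = gw.compute_ld_pairs(data, r2_min=0.8, max_window_bp=1_000_000)
        assert len(ld.pairs) == 0

    def test_missing_handled_pairwise_complete(self, rng):
        col = rng.binomial(2, 0.4, 200).astype(float)
        other = col.copy()
        other[:5] = np.nan  # still perfect LD on the shared samples
        d = np.column_stack([col, other])
        data = make_dataset(d, [1] * 100 + [0] * 100)
        ld = gw.compute_ld_pairs(data, r2_min=0.8)
        assert len(ld.pairs) == 1
        assert ld.pairs.r2.iloc[0] == pytest.approx(1.0)


class TestLdExtension:
    def base_map(self):
        frame = gw.AssignmentMap.from_frame(
            __import__("pandas").DataFrame(
                {"gene_id": ["A", "B"], "snp_id": ["s", "x"], "source": ["window", "window"]}
            )
        )
        return frame

    def ld(self, rows):
        import pandas as pd

        return gw.LdPairs(pairs=pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]))

    def test_empty_ld_is_identity(self):
        base = self.base_map()
        out = gw.extend_assignment_ld(base, self.ld([]))
        assert out.to_frame().equals(base.to_frame())

    def test_unassigned_snp_added_and_original_kept(self):
        base = self.base_map()
        out = gw.extend_assignment_ld(base, self.ld([("s", "t", 0.9)]))
        assert out.gene_to_snps["A"] == ["s", "t"]
        src = out.pairs.set_index(["gene_id", "snp_id"])["source"]
        assert src[("A", "t")] == "ld"
        assert src[("A", "s")] == "window"

    def test_single_step_no_transitive_closure(self):
        base = self.base_map()
        # s--t and t--u: u is in LD only with the newly added t, so u stays out
        out = gw.extend_assignment_ld(base, self.ld([("s", "t", 0.9), ("t", "u", 0.95)]))
        assert out.gene_to_snps["A"] == ["s", "t"]

    def test_snp_may_join_multiple_genes(self):
        base = self.base_map()
        out = gw.extend_assignment_ld(base, self.ld([("s", "x", 0.85)]))
        assert sorted(out.snp_to_genes["x"]) == ["A", "B"]
        assert sorted(out.snp_to_genes["s"]) == ["A", "B"]

    def test_extension_is_monotone_on_simulated_data(self):
        cfg = gw.SimulationConfig(
            n_cases=100, n_controls=100, n_genes=40, n_founder_haplotypes=6, seed=5
        )
        data, genes, _ = gw.simulate_cohort(cfg)
        base = gw.assign_snps(data.snps, genes)
        ld = gw.compute_ld_pairs(data, r2_min=0.8)
        ext = gw.extend_assignment_ld(base, ld)
        n_base = base.n_per_gene
        n_ext = ext.n_per_gene
        assert all(n_ext[g] >= n_base[g] for g in n_base.index)
        assert n_ext.sum() > n_base.sum()  # 6 founders give dense LD
        assert n_ext.mean() > n_base.mean()
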