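"""Synthetic cohort generator: LD structure, gene-size skew, planted effects."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest

import genewise as gw
from genewise.association import trend_stats_matrix
from genewise.simulate import _draw_gene_sizes


class TestHaplotypeBlocks:
    def test_two_founders_give_perfect_within_block_ld(self):
        cfg = gw.SimulationConfig(n_founder_haplotypes=2, seed=1)
        rng = np.random.default_rng(1)
        blocks = gw.simulate_haplotype_blocks(cfg, rng, n_snps=200)
        for blk in blocks:
            founders = blk["founders"].astype(float)
            seg = founders.std(axis=0) > 0
            cols = founders[:, seg]
            if cols.shape[1] < 2:
                continue
            r = np.corrcoef(cols.T)
            assert np.allclose(r**2, 1.0, atol=1e-12)

    def test_large_founder_pool_kills_ld(self):
        cfg = gw.SimulationConfig(
            n_cases=400, n_controls=400, n_founder_haplotypes=1000, n_genes=40, seed=2
        )
        data, _, _ = gw.simulate_cohort(cfg)
        ld = gw.compute_ld_pairs(data, r2_min=0.05, max_window_bp=50_000)
        # with 1000 founders almost no same-block pair stays above r2=0.05
        n_snps = data.n_snps
        assert len(ld.pairs) < 0.01 * n_snps * 8

    def test_cross_block_r2_near_zero(self):
        cfg = gw.SimulationConfig(n_cases=500, n_controls=500, n_founder_haplotypes=4, seed=3)
        rng = np.random.default_rng(3)
        blocks = gw.simulate_haplotype_blocks(cfg, rng, n_snps=60)
        # draw individuals and correlate SNPs from different blocks
        from genewise.simulate import _genotype_batch

        assert len(blocks) >= 2
        D = _genotype_batch(blocks, 4000, rng)
        offsets = np.concatenate([[0], np.cumsum([b["founders"].shape[1] for b in blocks])])
        # one segregating SNP from each of the first two blocks that have one
        seg = []
        for i in range(len(blocks)):
            for j in range(blocks[i]["founders"].shape[1]):
                if D[:, offsets[i] + j].std() > 0:
                    seg.append(offsets[i] + j)
                    break
            if len(seg) == 2:
                break
        assert len(seg) == 2, "no two blocks with segregating SNPs"
        r2 = np.corrcoef(D[:, seg[0]], D[:, seg[1]])[0, 1] ** 2
        assert r2 < 0.01

    def test_degenerate_beta_params_rejected(self):
        with pytest.raises(ValueError):
            gw.SimulationConfig(maf_beta_params=(0.0, 1.0))


class TestGeneSizes:
    def test_fig1_like_skew(self):
        cfg = gw.SimulationConfig(n_genes=5000, seed=4)
        sizes = _draw_gene_sizes(cfg, np.random.default_rng(4))
        assert (sizes < 10).mean() >= 0.70
        assert (sizes > 50).sum() > 0
        assert sizes.min() >= 1


class TestSimulateCohort:
    def test_null_config_is_calibrated(self):
        """Null trend statistics are marginally chi2(1): tail fractions,
        lambda, and a coarse KS on block-thinned statistics.

        SNPs within an LD block are correlated, so statistics are thinned
        to roughly one per block before testing, and the lambda band is
        +-3 SE of the median over the effective sample.
        """
        pooled = []
        for seed in (11, 12, 13):
            cfg = gw.SimulationConfig(n_cases=400, n_controls=400, n_genes=400, seed=seed)
            data, genes, truth = gw.simulate_cohort(cfg)
            assert truth == set()
            T, mono = trend_stats_matrix(data.dosages, data.is_case)
            pooled.append(T[~mono][::8])  # ~ one statistic per block
        T = np.concatenate(pooled)
        assert abs((T > 1.0).mean() - 0.317) < 0.05
        assert abs((T > chi2.ppf(0.95, 1)).mean() - 0.05) < 0.03
        lam = gw.lambda_median(T).lambda_median
        assert 0.89 < lam < 1.11
        # the genotype lattice leaves small atoms, so only gross departures
        # from the chi-square shape are rejected here
        assert kstest(T, chi2(1).cdf).pvalue > 1e-4

    def test_planted_causal_snp_has_power(self):
        # single causal SNP, OR 1.5: mean trend statistic over replicates
        # must exceed the null mean of 1
        stats = []
        for seed in range(200):
            cfg = gw.SimulationConfig(
                n_cases=100, n_controls=100, n_genes=4, seed=seed,
                causal_genes=(gw.CausalGene(gene_index=0, n_snps=1, odds_ratio=1.5),),
            )
            data, genes, truth = gw.simulate_cohort(cfg)
            amap = gw.assign_snps(data.snps, genes)
            assoc, _ = gw.snp_association_table(data, gc_mode="none")
            sub = assoc[assoc.snp_id.isin(amap.gene_to_snps[next(iter(truth))])]
            stats.append(sub["T_raw"].max())
        assert np.mean(stats) > 1.5

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = gw.SimulationConfig(n_cases=50, n_controls=50, n_genes=20, seed=6)
        d1, g1, t1 = gw.simulate_cohort(cfg)
        d2, g2, t2 = gw.simulate_cohort(cfg)
        np.testing.assert_array_equal(d1.dosages, d2.dosages)
        assert d1.snps == d2.snps and g1 == g2 and t1 == t2

    def test_assignment_recovers_simulated_gene_membership(self):
        cfg = gw.SimulationConfig(n_cases=50, n_controls=50, n_genes=30, seed=7)
        data, genes, _ = gw.simulate_cohort(cfg)
        amap = gw.assign_snps(data.snps, genes, window_bp=cfg.window_bp)
        assert amap.n_assigned_snps == data.n_snps
        assert len(amap.genes) == len(genes)

    def test_impossible_quota_raises(self):
        cfg = gw.SimulationConfig(
            n_cases=500, n_controls=5, n_genes=3, prevalence=0.001, seed=8
        )
        with pytest.raises(RuntimeError, match="quota"):
            gw.simulate_cohort(cfg)


class TestFixtureRoundTrip:
    def test_files_round_trip_through_readers(self, tmp_path):
        from genewise import io as gio

        cfg = gw.SimulationConfig(
            n_cases=30, n_controls=30, n_genes=10, missing_rate=0.02, seed=9
        )
        cfg = gw.with_planted_signal(cfg, 2)
        data, genes, truth = gw.simulate_cohort(cfg)
        paths = gw.write_fixture(data, genes, truth, tmp_path)
        back = gio.read_genotypes_vcf(paths["vcf"], paths["phenotypes"])
        assert back.snps == data.snps
        assert back.samples == data.samples
        np.testing.assert_array_equal(back.dosages, data.dosages)
        np.testing.assert_array_equal(back.phenotype, data.phenotype)
        bed = gio.read_genes_bed(paths["bed"])
        assert bed == genes
        with open(paths["truth"]) as fh:
            truth_back = {line.strip() for line in fh}
        assert truth_back == truth
        assert truth_back <= {g.gene_id for g in bed}

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = gw.with_planted_signal(gw.SimulationConfig(n_genes=25, seed=10), 3)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert gw.SimulationConfig.from_yaml(path) == cfg
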