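"""LOOCV, random-seed degree-bias diagnostics and GWAS validation."""

import numpy as np
import pandas as pd
import pytest

from netprio import (
    Network,
    RankTable,
    SeedSet,
    confirmed_gene_metrics,
    degree_rank_association,
    gwas_validate,
    loocv,
    map_snps_to_genes,
    random_seed_experiment,
)
from netprio.evaluation import read_gene_regions
from netprio.prioritizers import DegreePrioritizer, RWRPrioritizer, RWRHPrioritizer

from conftest import random_connected_net


class TestLOOCV:
    def test_degree_baseline_folds_are_seed_independent(self):
        net = random_connected_net(np.random.default_rng(0), 30)
        seeds = SeedSet(tuple(net.nodes[:10]))
        res = loocv(DegreePrioritizer(), net, seeds)
        assert len(res.ranks) == 10
        # Each fold's rank must equal the gene's rank in the global degree ordering
        # with the other seeds removed - recompute directly.
        from netprio import degree_baseline, rank_scores

        for gene in seeds.ids:
            table = rank_scores(degree_baseline(net),
                                exclude=[s for s in seeds.ids if s != gene])
            assert res.ranks[gene] == table.ranks[gene]

    def test_median_uses_midpoint_for_even_fold_count(self):
        net = random_connected_net(np.random.default_rng(1), 40)
        seeds = SeedSet(tuple(net.nodes[:4]))
        res = loocv(RWRPrioritizer(), net, seeds)
        vals = sorted(res.ranks)
        assert res.median == pytest.approx((vals[1] + vals[2]) / 2)

    def test_hetero_fold_removes_and_restores_association(self, hetero_fixture):
        hnet, disease, seeds, _ = hetero_fixture
        before = hnet.gda.toarray().copy()
        di = hnet.disease_index(disease)
        seen = {}

        def hook(gene, fold_net):
            gi = hnet.gene_net.node_index[gene]
            seen[gene] = fold_net.gda.toarray()[gi, di]
            # only the held-out association is removed
            diff = before.copy()
            diff[gi, di] = 0.0
            assert np.array_equal(fold_net.gda.toarray(), diff)

        loocv(RWRHPrioritizer(), hnet, seeds, disease, fold_hook=hook)
        assert all(v == 0.0 for v in seen.values())
        assert np.array_equal(hnet.gda.toarray(), before)  # bitwise restored

    def test_failed_fold_marked_na_and_flagged(self):
        class Broken(DegreePrioritizer):
            name = "broken"

            def rank(self, seeds, disease=None, exclude=None):
                raise RuntimeError("boom")

        net = random_connected_net(np.random.default_rng(2), 20)
        res = loocv(Broken(), net, SeedSet(tuple(net.nodes[:3])))
        assert res.n_na == 3 and res.params["partial_failure"]

    def test_single_seed_rejected(self):
        net = random_connected_net(np.random.default_rng(3), 10)
        with pytest.raises(ValueError, match="at least 2"):
            loocv(DegreePrioritizer(), net, SeedSet((net.nodes[0],)))

    def test_report_frame_preserves_na(self):
        net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        res = loocv(DegreePrioritizer(), net, SeedSet(("a", "b")))
        frame = res.to_frame()
        assert list(frame.index[-2:]) == ["Median", "Mean"]


class TestRandomSeedExperiment:
    def test_executes_exact_trial_count(self):
        net = random_connected_net(np.random.default_rng(4), 25)
        res = random_seed_experiment(DegreePrioritizer(), net, n_trials=3,
                                     seeds_per_trial=5, rng_seed=0)
        assert res.n_trials == 3
        assert res.rank_matrix.shape == (3, net.n)

    def test_star_hub_median_rank_is_one_under_rwr(self):
        net = Network.from_edges([("hub", f"l{i}") for i in range(20)])
        res = random_seed_experiment(RWRPrioritizer(), net, n_trials=10,
                                     seeds_per_trial=3, rng_seed=1)
        assert res.median_ranks["hub"] == 1.0

    def test_reproducible_under_seed(self):
        net = random_connected_net(np.random.default_rng(5), 25)
        kw = dict(n_trials=4, seeds_per_trial=5, rng_seed=9)
        a = random_seed_experiment(RWRPrioritizer(), net, **kw)
        b = random_seed_experiment(RWRPrioritizer(), net, **kw)
        assert a.rank_matrix.equals(b.rank_matrix)

    def test_too_few_nodes_rejected(self, triangle):
        with pytest.raises(ValueError):
            random_seed_experiment(DegreePrioritizer(), triangle, seeds_per_trial=10)


class TestDegreeRankAssociation:
    def _result(self, net, median_ranks):
        mat = pd.DataFrame([median_ranks.reindex(list(net.nodes))])
        from netprio import RandomSeedResult

        return RandomSeedResult("x", mat, 1, 0)

    def test_perfect_degree_order_gives_minus_one(self):
        net = random_connected_net(np.random.default_rng(6), 40)
        deg = pd.Series(net.degree, index=list(net.nodes))
        ranks = deg.rank(ascending=False, method="average")
        rho, _, binned = degree_rank_association(self._result(net, ranks), net)
        assert rho == pytest.approx(-1.0)
        assert len(binned) == 10

    def test_shuffled_ranks_uncorrelated(self):
        net = random_connected_net(np.random.default_rng(7), 1000, p=0.008)
        rng = np.random.default_rng(0)
        ranks = pd.Series(rng.permutation(net.n) + 1.0, index=list(net.nodes))
        rho, _, _ = degree_rank_association(self._result(net, ranks), net)
        assert abs(rho) < 0.1

    def test_constant_ranks_undefined(self):
        net = random_connected_net(np.random.default_rng(8), 20)
        ranks = pd.Series(1.0, index=list(net.nodes))
        rho, pval, _ = degree_rank_association(self._result(net, ranks), net)
        assert np.isnan(rho)


class TestSNPMapping:
    REGIONS = pd.DataFrame([
        {"gene": "GENE1", "chrom": "1", "start": 5000, "end": 6000},
        {"gene": "GENE2", "chrom": "1", "start": 5500, "end": 7000},
        {"gene": "GENE3", "chrom": "2", "start": 5000, "end": 6000},
    ])

    def _gwas(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "pvalue"])

    def test_flank_boundary_inclusive(self):
        gwas = self._gwas([("rs1", "1", 4001, 0.5), ("rs2", "1", 3999, 0.5),
                           ("rs3", "1", 7000, 0.5)])
        hit = map_snps_to_genes(gwas, self.REGIONS, flank=1000)
        assert list(hit["GENE1"]["snp"]) == ["rs1", "rs3"]
        assert "rs2" not in set(hit["GENE1"]["snp"])

    def test_overlapping_genes_share_snp(self):
        gwas = self._gwas([("rs1", "1", 5600, 0.5)])
        hit = map_snps_to_genes(gwas, self.REGIONS, flank=0)
        assert "rs1" in set(hit["GENE1"]["snp"]) and "rs1" in set(hit["GENE2"]["snp"])

    def test_chromosome_must_match(self):
        gwas = self._gwas([("rs1", "2", 5500, 0.5)])
        hit = map_snps_to_genes(gwas, self.REGIONS, flank=0)
        assert "GENE1" not in hit and "GENE3" in hit

    def test_bed_conversion_to_one_based(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("1\t4999\t6000\tGENE1\n")
        regions = read_gene_regions(bed)
        assert regions.loc[0, "start"] == 5000 and regions.loc[0, "end"] == 6000


def _rank_table(genes):
    return RankTable(pd.Series(np.arange(1.0, len(genes) + 1), index=genes))


class TestGWASValidate:
    def _setup(self, n_genes=40, planted=5, rng_seed=0):
        from netprio import generate_gwas_fixture, make_gene_regions

        genes = [f"G{i:03d}" for i in range(n_genes)]
        regions = make_gene_regions(genes)
        enriched = genes[:planted]
        gwas = generate_gwas_fixture(regions, enriched, n_snps_per_gene=8,
                                     effect_p=1e-8, rng_seed=rng_seed)
        return genes, regions, gwas, enriched

    def test_bh_textbook_example(self):
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(adj, 0.04)

    def test_planted_genes_exactly_validated(self):
        genes, regions, gwas, enriched = self._setup()
        res = gwas_validate(_rank_table(genes), gwas, regions, top_n=40, fdr=0.05)
        assert sorted(res.validated_genes) == sorted(enriched)

    def test_fdr_zero_validates_nothing(self):
        genes, regions, gwas, _ = self._setup()
        res = gwas_validate(_rank_table(genes), gwas, regions, top_n=40, fdr=0.0)
        assert res.n_validated == 0

    def test_fdr_one_validates_every_gene_with_a_snp(self):
        genes, regions, gwas, _ = self._setup()
        res = gwas_validate(_rank_table(genes), gwas, regions, top_n=40, fdr=1.0)
        assert res.n_validated == res.n_genes_tested

    def test_adjusted_p_not_below_raw(self):
        genes, regions, gwas, _ = self._setup(rng_seed=3)
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(gwas["pvalue"].to_numpy(), method="fdr_bh")
        assert (adj >= gwas["pvalue"].to_numpy() - 1e-15).all()

    def test_top_n_larger_than_universe_rejected(self):
        genes, regions, gwas, _ = self._setup()
        with pytest.raises(ValueError, match="top_n"):
            gwas_validate(_rank_table(genes), gwas, regions, top_n=100)


class TestConfirmedGeneMetrics:
    def test_seven_confirmed_in_hundred_gene_universe(self):
        genes = [f"g{i}" for i in range(100)]
        table = _rank_table(genes)
        med, hits, hit_list = confirmed_gene_metrics(table, genes[:7], top_frac=0.1)
        assert med == 4.0 and hits == 7
        assert hit_list == genes[:7]

    def test_unranked_confirmed_gene_excluded(self):
        table = _rank_table(["a", "b", "c"])
        med, hits, hit_list = confirmed_gene_metrics(table, ["a", "zz"], top_frac=0.5)
        assert med == 1.0 and hit_list == ["a"]

    def test_empty_confirmed_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confirmed_gene_metrics(_rank_table(["a"]), [])

    def test_degree_baseline_hits_match_hand_count(self):
        net = Network.from_edges(
            [("hub", f"l{i}") for i in range(9)] + [("l0", "l1")])
        from netprio import degree_baseline, rank_scores

        table = rank_scores(degree_baseline(net))
        med, hits, hit_list = confirmed_gene_metrics(table, ["hub", "l5"], top_frac=0.1)
        assert hits == 1 and hit_list == ["hub"]
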