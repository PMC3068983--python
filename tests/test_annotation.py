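import numpy as np
import pytest

from tfret.annotation import (
    CONSTITUTIVE,
    DISTAL,
    GeneIndex,
    assign_cluster,
    assign_cluster_nearest_gene,
    gained_sites_per_gene,
    lift_tss_orthologs,
    tss_site_profile,
)
from tfret.intervals_io import CEBPA, PPARG, GeneRecord, GenomicInterval
from tfret.orthology import ChainBlock, ChainSet, OrthologyChain
from conftest import make_site


def gene(gid, tss, cluster=None, chrom="chr1", strand="+"):
    return GeneRecord(gid, chrom, tss, strand, cluster)


class TestAssignCluster:
    def test_closest_clustered_gene_wins(self, cfg):
        # site midpoint 500,000: non-cluster TSS at 10 kb, cluster-2 TSS at 60 kb
        site = make_site("chr1", 499_900, 500_100)
        genes = [gene("g1", 510_000, None), gene("g2", 560_000, 2)]
        assert assign_cluster(site, genes, cfg) == 2
        # the nearest-gene variant disagrees here by design
        assert assign_cluster_nearest_gene(site, genes, cfg) == CONSTITUTIVE

    def test_only_unclustered_nearby_is_cluster_5(self, cfg):
        site = make_site("chr1", 499_900, 500_100)
        assert assign_cluster(site, [gene("g1", 540_000, None)], cfg) == CONSTITUTIVE

    def test_no_tss_within_100kb_is_cluster_6(self, cfg):
        site = make_site("chr1", 499_900, 500_100)
        assert assign_cluster(site, [gene("g1", 650_000, 4)], cfg) == DISTAL

    def test_boundary_inclusive_and_tie_break(self, cfg):
        site = make_site("chr1", 499_900, 500_100)  # midpoint 500,000
        assert assign_cluster(site, [gene("g1", 600_000, 1)], cfg) == 1  # exactly 100 kb
        # equidistant clustered genes: smaller TSS coordinate wins
        genes = [gene("a", 490_000, 3), gene("b", 510_000, 4)]
        assert assign_cluster(site, genes, cfg) == 3

    def test_every_site_gets_exactly_one_label(self, cfg):
        rng = np.random.default_rng(0)
        genes = [gene(f"g{i}", int(t), int(c) if c else None)
                 for i, (t, c) in enumerate(zip(rng.integers(0, 10**6, 40),
                                                rng.integers(0, 5, 40)))]
        index = GeneIndex(genes)
        sites = [make_site("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 10**6, 100)]
        labels = [assign_cluster(s, index, cfg) for s in sites]
        assert all(l in (1, 2, 3, 4, 5, 6) for l in labels)
        # shrinking the window never rescues a distal site
        import dataclasses
        tight = dataclasses.replace(cfg, cluster_window=50_000)
        for s, l in zip(sites, labels):
            if l == DISTAL:
                assert assign_cluster(s, index, tight) == DISTAL


def identity_chains(length=1_000_000):
    block = ChainBlock(GenomicInterval("chr1", 0, length), GenomicInterval("chr1", 0, length))
    return ChainSet([OrthologyChain("c", [block])])


class TestTssOrthologs:
    def test_pairing_within_5kb(self, cfg):
        mouse = [gene("m1", 10_000, 3)]
        human = [gene("h1", 13_000)]
        pairs, tally = lift_tss_orthologs(mouse, identity_chains(), human, cfg)
        assert len(pairs) == 1 and pairs[0].human_gene.gene_id == "h1"
        assert pairs[0].inherited_cluster == 3
        assert tally == {"unlifted": 0, "no_nearby_gene": 0}

    def test_beyond_5kb_discarded(self, cfg):
        pairs, tally = lift_tss_orthologs(
            [gene("m1", 10_000, 3)], identity_chains(), [gene("h1", 16_000)], cfg
        )
        assert not pairs and tally["no_nearby_gene"] == 1

    def test_unliftable_flank_discarded(self, cfg):
        chains = ChainSet([OrthologyChain("c", [
            ChainBlock(GenomicInterval("chr1", 500_000, 600_000),
                       GenomicInterval("chr1", 500_000, 600_000))])])
        pairs, tally = lift_tss_orthologs(
            [gene("m1", 10_000, 3)], chains, [gene("h1", 10_000)], cfg
        )
        assert not pairs and tally["unlifted"] == 1

    def test_tally_partition(self, cfg):
        rng = np.random.default_rng(1)
        mouse = [gene(f"m{i}", int(t), 1) for i, t in
                 enumerate(rng.integers(100, 2_000_000, 50))]
        human = [gene(f"h{i}", int(t)) for i, t in
                 enumerate(rng.integers(100, 1_000_000, 30))]
        pairs, tally = lift_tss_orthologs(mouse, identity_chains(), human, cfg)
        assert len(pairs) + tally["unlifted"] + tally["no_nearby_gene"] == len(mouse)


class TestTssProfile:
    def test_single_gene_bins(self, cfg):
        g = [gene("g", 500_000)]
        sites = [make_site("chr1", 404_900, 405_100, PPARG),   # tss - 95 kb -> bin 0
                 make_site("chr1", 504_900, 505_100, PPARG)]   # tss + 5 kb -> bin 10
        prof = tss_site_profile(g, sites, cfg)
        assert prof.shape == (20,)
        assert prof[0] == 1 and prof[10] == 1 and prof.sum() == 2

    def test_strand_orientation_flips_bins(self, cfg):
        g = [gene("g", 500_000, strand="-")]
        sites = [make_site("chr1", 404_900, 405_100, PPARG)]  # upstream on + = downstream on -
        prof = tss_site_profile(g, sites, cfg)
        assert prof[19] == 1

    def test_mean_across_genes(self, cfg):
        genes = [gene("g1", 500_000), gene("g2", 800_000)]
        sites = [make_site("chr1", 504_900, 505_100, PPARG),
                 make_site("chr1", 804_900, 805_100, PPARG)]
        prof = tss_site_profile(genes, sites, cfg)
        assert prof[10] == 1.0

    def test_empty_gene_list_errors(self, cfg):
        with pytest.raises(ValueError):
            tss_site_profile([], [], cfg)

    def test_uniform_sites_flat_profile(self, cfg):
        rng = np.random.default_rng(2)
        genes = [gene(f"g{i}", int(t)) for i, t in
                 enumerate(rng.integers(200_000, 9_800_000, 200))]
        density = 2.0  # sites per 10 kb
        n = int(density * 1000)  # over 10 Mb
        sites = [make_site("chr1", int(s), int(s) + 100, PPARG, site_id=f"s{i}")
                 for i, s in enumerate(rng.integers(0, 10_000_000, n))]
        prof = tss_site_profile(genes, sites, cfg)
        se = np.sqrt(density / 200)
        assert np.all(np.abs(prof - density) < 3 * se + 0.2)


class TestGainedSites:
    def test_counts_within_50kb(self, cfg):
        g = gene("g", 500_000, 4)
        sp = [make_site("chr1", 509_900, 510_100, species="human", site_id="a"),
              make_site("chr1", 559_900, 560_100, species="human", site_id="b")]
        counts, hists = gained_sites_per_gene([g], sp, cfg)
        assert counts["g"] == 1
        assert hists[4].sum() == pytest.approx(1.0)

    def test_gene_with_none(self, cfg):
        counts, hists = gained_sites_per_gene([gene("g", 500_000, 2)], [], cfg)
        assert counts["g"] == 0
        assert list(hists[2]) == [1.0]
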