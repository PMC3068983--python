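import pytest

from tfret.intervals_io import CEBPA, AnalysisConfig, GenomicInterval
from tfret.orthology import (
    AMBIGUOUS,
    BELOW_MIN_MATCH,
    FAILED_RECIPROCAL,
    MAPPED,
    UNALIGNED,
    ChainBlock,
    ChainSet,
    OrthologyChain,
    lift_interval,
    read_block_tsv,
    read_chain_file,
    reciprocal_map,
    write_chain_file,
)
from conftest import make_site


def identity_chainset(length=1_000_000, chrom="chr1", chain_id="c1"):
    block = ChainBlock(GenomicInterval(chrom, 0, length), GenomicInterval(chrom, 0, length))
    return ChainSet([OrthologyChain(chain_id, [block])])


def two_block_chainset():
    blocks = [
        ChainBlock(GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 0, 100)),
        ChainBlock(GenomicInterval("chr1", 150, 250), GenomicInterval("chr1", 300, 400)),
    ]
    return ChainSet([OrthologyChain("c1", blocks)])


class TestLiftInterval:
    def test_identity_chain_maps_verbatim(self):
        res = lift_interval(identity_chainset(), GenomicInterval("chr1", 100, 400), 0.1)
        assert res.status == MAPPED
        assert res.span == GenomicInterval("chr1", 100, 400)

    def test_span_runs_first_to_last_covered_base(self):
        # covered 100/150 bases; first covered base 50 -> 50, last 199 -> 349
        res = lift_interval(two_block_chainset(), GenomicInterval("chr1", 50, 200), 0.1)
        assert res.status == MAPPED
        assert res.span == GenomicInterval("chr1", 50, 350)

    def test_gap_between_blocks_is_unaligned(self):
        res = lift_interval(two_block_chainset(), GenomicInterval("chr1", 105, 145), 0.1)
        assert res.status == UNALIGNED

    def test_low_coverage_is_below_min_match(self):
        # 5 of 150 bases covered = 3.3% < 10%
        blocks = [ChainBlock(GenomicInterval("chr1", 0, 105), GenomicInterval("chr1", 0, 105))]
        chains = ChainSet([OrthologyChain("c1", blocks)])
        res = lift_interval(chains, GenomicInterval("chr1", 100, 250), 0.1)
        assert res.status == BELOW_MIN_MATCH

    def test_two_covering_chains_is_ambiguous(self):
        dup = ChainSet(
            [
                OrthologyChain("a", [ChainBlock(GenomicInterval("chr1", 0, 1000),
                                                GenomicInterval("chr1", 0, 1000))]),
                OrthologyChain("b", [ChainBlock(GenomicInterval("chr1", 0, 1000),
                                                GenomicInterval("chr1", 5000, 6000))]),
            ]
        )
        assert lift_interval(dup, GenomicInterval("chr1", 100, 200), 0.1).status == AMBIGUOUS


class TestReciprocalMap:
    def test_identity_both_ways(self, cfg):
        chains = identity_chainset()
        site = make_site("chr1", 100, 400)
        m = reciprocal_map(chains, chains, site, cfg)
        assert m.status == MAPPED and m.back_overlap_frac == 1.0
        assert m.human_span == site.interval

    def test_shifted_back_image_fails_reciprocal(self, cfg):
        fwd = identity_chainset(chain_id="fwd")
        # reverse chains place the back image 80% off the original
        rev = ChainSet(
            [OrthologyChain("rev", [ChainBlock(GenomicInterval("chr1", 0, 10_000),
                                               GenomicInterval("chr1", 80, 10_080))])]
        )
        m = reciprocal_map(fwd, rev, make_site("chr1", 100, 200), cfg)
        assert m.status == FAILED_RECIPROCAL
        assert m.back_overlap_frac == pytest.approx(0.2)

    def test_back_lift_to_other_chromosome_fails(self, cfg):
        fwd = identity_chainset(chain_id="fwd")
        rev = ChainSet(
            [OrthologyChain("rev", [ChainBlock(GenomicInterval("chr1", 0, 10_000),
                                               GenomicInterval("chr9", 0, 10_000))])]
        )
        m = reciprocal_map(fwd, rev, make_site("chr1", 100, 200), cfg)
        assert m.status == FAILED_RECIPROCAL

    def test_forward_failure_status_passes_through(self, cfg):
        empty = ChainSet([])
        m = reciprocal_map(empty, empty, make_site("chr1", 100, 200), cfg)
        assert m.status == UNALIGNED and m.human_span is None


class TestChainIO:
    def test_round_trip(self, tmp_path):
        blocks = [
            ChainBlock(GenomicInterval("chrA", 10, 110), GenomicInterval("chrB", 0, 100)),
            ChainBlock(GenomicInterval("chrA", 160, 260), GenomicInterval("chrB", 130, 230)),
        ]
        chain = OrthologyChain("1", blocks)
        path = tmp_path / "t.chain"
        write_chain_file(path, [chain], {"chrA": 1000}, {"chrB": 1000})
        loaded = read_chain_file(path)
        assert len(loaded.chains) == 1
        assert loaded.chains[0].blocks == blocks

    def test_negative_strand_query(self, tmp_path):
        # one 100-base block, query on the minus strand of a 1000-base chrom
        path = tmp_path / "neg.chain"
        path.write_text("chain 100 chrA 1000 + 100 200 chrB 1000 - 300 400 7\n100\n\n")
        chains = read_chain_file(path)
        block = chains.chains[0].blocks[0]
        # reverse-strand coords [300,400) on a 1000 chrom = forward [600,700)
        assert block.tgt == GenomicInterval("chrB", 600, 700)
        res = chains.lift(GenomicInterval("chrA", 100, 110), 0.1)
        assert res.status == MAPPED
        # first base 100 maps to forward position 699, base 109 to 690
        assert res.span == GenomicInterval("chrB", 690, 700)

    def test_block_tsv(self, tmp_path):
        path = tmp_path / "blocks.tsv"
        path.write_text(
            "src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\tchain_id\n"
            "chr1\t0\t100\tchr1\t0\t100\tc1\n"
            "chr1\t150\t250\tchr1\t300\t400\tc1\n"
        )
        chains = read_block_tsv(path)
        res = chains.lift(GenomicInterval("chr1", 50, 200), 0.1)
        assert res.span == GenomicInterval("chr1", 50, 350)


def test_mapping_is_deterministic(cfg):
    chains = two_block_chainset()
    site = make_site("chr1", 40, 220)
    runs = [reciprocal_map(chains, ChainSet([
        OrthologyChain("r", [ChainBlock(b.tgt, b.src) for b in chains.chains[0].blocks])
    ]), site, cfg) for _ in range(3)]
    assert all(m.status == runs[0].status and m.human_span == runs[0].human_span for m in runs)
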