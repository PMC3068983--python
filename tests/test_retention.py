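import numpy as np
import pytest

from tfret.intervals_io import CEBPA, PPARG, GenomicInterval, SiteIndex, TagTrack
from tfret.orthology import MAPPED, MappedSite
from tfret.retention import (
    RandomExpectation,
    binary_retention,
    count_tags_in_window,
    detect_turnover,
    enrichment_log2fc,
    human_specific_sites,
    log2_fold_change,
    quartile_bins,
    window_width_75th,
)
from conftest import make_site


def mapped(span_start, span_end, chrom="chr1", factor=CEBPA):
    site = make_site(chrom, span_start, span_end, factor)
    return MappedSite(site, MAPPED, GenomicInterval(chrom, span_start, span_end), 1.0)


class TestBinaryRetention:
    def test_overlap_of_lifted_span(self, cfg):
        m = mapped(1000, 1200)
        flag, hits = binary_retention(m, [make_site("chr1", 1150, 1500, species="human")], cfg)
        assert flag and len(hits) == 1  # 50/200 = 25% of the span

    def test_vice_versa_human_site_fraction(self, cfg):
        # 15 nt: 7.5% of the 200 nt span but 15% of the 100 nt human site
        m = mapped(1000, 1200)
        flag, _ = binary_retention(m, [make_site("chr1", 1185, 1285, species="human")], cfg)
        assert flag

    def test_exact_ten_percent_is_not_retained(self, cfg):
        # overlap 20 = exactly 10% of both the 200 nt span and 200 nt site
        m = mapped(1000, 1200)
        flag, _ = binary_retention(m, [make_site("chr1", 1180, 1380, species="human")], cfg)
        assert not flag

    def test_unmapped_input_is_an_error(self, cfg):
        site = make_site("chr1", 0, 100)
        with pytest.raises(ValueError):
            binary_retention(MappedSite(site, "unaligned"), [], cfg)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force(self, cfg, seed):
        from tfret.intervals_io import overlap_length

        rng = np.random.default_rng(seed)
        spans = [mapped(int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 50_000, 100), rng.integers(50, 500, 100))]
        human = [make_site("chr1", int(s), int(s) + int(w), species="human", site_id=f"h{i}")
                 for i, (s, w) in enumerate(zip(rng.integers(0, 50_000, 100),
                                                rng.integers(50, 500, 100)))]
        index = SiteIndex(human)
        for m in spans:
            expected = any(
                overlap_length(m.human_span, h.interval) > 0.1 * m.human_span.width
                or overlap_length(m.human_span, h.interval) > 0.1 * h.width
                for h in human
            )
            assert binary_retention(m, index, cfg)[0] == expected


class TestTurnover:
    def test_within_ten_kb(self, cfg):
        m = mapped(49_900, 50_100)  # midpoint 50,000
        near = [make_site("chr1", 57_900, 58_100, species="human")]  # midpoint 58,000
        assert detect_turnover(m, near, cfg)

    def test_beyond_ten_kb(self, cfg):
        m = mapped(49_900, 50_100)
        far = [make_site("chr1", 60_900, 61_100, species="human")]  # midpoint 61,000
        assert not detect_turnover(m, far, cfg)

    def test_exactly_ten_kb_inclusive(self, cfg):
        m = mapped(49_900, 50_100)
        edge = [make_site("chr1", 59_900, 60_100, species="human")]  # midpoint 60,000
        assert detect_turnover(m, edge, cfg)


def test_human_specific_sites_exclude_matched(cfg):
    spans = [GenomicInterval("chr1", 1000, 1300)]
    matched = make_site("chr1", 1100, 1400, species="human", site_id="hm")
    unmatched = make_site("chr1", 9000, 9300, species="human", site_id="hu")
    specific = human_specific_sites([matched, unmatched], spans, cfg)
    assert specific == [unmatched]


class TestWindowWidth:
    def test_linear_interpolation(self):
        sites = [make_site("chr1", 0, w, species="human") for w in (100, 200, 300, 400)]
        assert window_width_75th(sites) == 325

    def test_constant_widths(self):
        sites = [make_site("chr1", i * 1000, i * 1000 + 300, species="human") for i in range(5)]
        assert window_width_75th(sites) == 300

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            window_width_75th([])

    def test_paper_defaults_stored_in_config(self, cfg):
        assert cfg.enrich_window_cebpa == 520
        assert cfg.enrich_window_pparg == 605


class TestCountTags:
    def test_even_width_window(self):
        track = TagTrack({"chr1": np.array([10, 50, 90])})
        assert count_tags_in_window(track, "chr1", 50, 80) == 2  # window [10, 90)

    def test_odd_width_extends_right(self):
        track = TagTrack({"chr1": np.array([10, 50, 90])})
        assert count_tags_in_window(track, "chr1", 50, 81) == 3  # window [10, 91)

    def test_missing_chromosome_is_zero(self):
        assert count_tags_in_window(TagTrack(), "chr1", 50, 80) == 0


class TestEnrichment:
    def test_log2_arithmetic(self):
        assert log2_fold_change(31, 3.0) == 3.0
        assert log2_fold_change(0, 1.0) == -1.0

    def test_window_too_large_for_genome(self):
        with pytest.raises(ValueError):
            RandomExpectation(TagTrack(), 1000, {"chr1": 500}, 10, seed=0)

    def test_adding_tags_never_decreases_log2fc(self, cfg):
        rng = np.random.default_rng(4)
        genome = {"chr1": 1_000_000}
        base = np.sort(rng.integers(0, 1_000_000, 2000))
        m = mapped(499_900, 500_100)
        track1 = TagTrack({"chr1": base})
        exp = RandomExpectation(track1, 520, genome, 500, seed=1)
        v1 = enrichment_log2fc(m, track1, exp, cfg)
        extra = np.concatenate([base, rng.integers(499_800, 500_200, 20)])
        track2 = TagTrack({"chr1": extra})
        # same null, more tags in the site window
        v2 = enrichment_log2fc(m, track2, exp, cfg)
        assert v2 >= v1

    def test_expectation_is_seed_deterministic(self):
        rng = np.random.default_rng(5)
        track = TagTrack({"chr1": np.sort(rng.integers(0, 100_000, 500))})
        a = RandomExpectation(track, 200, {"chr1": 100_000}, 300, seed=9)
        b = RandomExpectation(track, 200, {"chr1": 100_000}, 300, seed=9)
        assert a.expected == b.expected


class TestQuartileBins:
    def test_eight_values(self):
        labels = quartile_bins([1, 2, 3, 4, 5, 6, 7, 8])
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_uneven_sizes_larger_first(self):
        labels = quartile_bins([10, 20, 30, 40, 50, 60])
        assert [list(labels).count(k) for k in (1, 2, 3, 4)] == [2, 2, 1, 1]

    def test_ties_split_by_stable_order(self):
        labels = quartile_bins([5.0] * 6)
        assert list(labels) == [1, 1, 2, 2, 3, 4]

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            quartile_bins([1, 2, 3])
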