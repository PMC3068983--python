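from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from tfret.intervals_io import GenomicInterval
from tfret.orthology import MAPPED, MappedSite
from tfret.retention import FateRecord, LOST, RETAINED
from tfret.stats_report import (
    benjamini_hochberg,
    crosstab_retention,
    fisher_exact_2x2,
    mapped_percentage,
    mapping_summary,
    violin_summary,
    wilcoxon_rank_sum,
)
from conftest import make_site


def fisher_oracle(a, b, c, d):
    """Exact-rational hypergeometric enumeration (probability ordering)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    total = comb(n, c1)
    weights = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), total)
        for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    }
    p_obs = weights[a]
    return float(sum(w for w in weights.values() if w <= p_obs))


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[5, 0], [0, 5]], 2 / 252),
            ([[2, 4], [3, 6]], 1.0),           # odds ratio 1: maximal-probability table
            ([[1, 9], [11, 3]], 0.0027594561852),
        ],
    )
    def test_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-6)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_transpose_and_row_swap_invariance(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, rel=1e-9)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 40, size=4)
            ours = fisher_exact_2x2([[a, b], [c, d]])
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6)


class TestWilcoxon:
    def test_exact_small_sample(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5]) == 1.0

    def test_approximation_close_to_exact_at_n30(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x, y = rng.normal(size=30), rng.normal(size=30)
            approx = wilcoxon_rank_sum(x, y)
            exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert abs(approx - exact) < 0.02

    def test_ties_midranks_match_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, size=40).astype(float)
        y = rng.integers(0, 5, size=35).astype(float)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(ref, abs=1e-6)


def fake_record(fate, group):
    site = make_site("chr1", 100, 300, site_id=f"{fate}{group}{np.random.randint(1e9)}")
    m = MappedSite(site, MAPPED, GenomicInterval("chr1", 100, 300), 1.0)
    retained_as = frozenset({"CEBPA"}) if fate == RETAINED else frozenset()
    rec = FateRecord(site, m, fate, retained_as)
    rec.group = group
    return rec


class TestCrosstab:
    def test_counts_and_table(self):
        fates = [fake_record(RETAINED, "A")] * 3 + [fake_record(LOST, "A")] * 2 \
            + [fake_record(RETAINED, "B")] * 1 + [fake_record(LOST, "B")] * 4
        ct = crosstab_retention(fates, lambda r: r.group, (("A",), ("B",)))
        assert ct.counts.loc["A", "frac_retained"] == pytest.approx(0.6)
        assert ct.counts.loc["B", "frac_retained"] == pytest.approx(0.2)
        assert ct.table == [[3, 2], [1, 4]]

    def test_all_retained_p_one(self):
        fates = [fake_record(RETAINED, g) for g in "AABB"]
        with pytest.warns(UserWarning):  # zero not-retained margin
            ct = crosstab_retention(fates, lambda r: r.group, (("A",), ("B",)))
        assert ct.fisher_p == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        fates = [fake_record(RETAINED if rng.random() < 0.4 else LOST,
                             "A" if rng.random() < 0.5 else "B") for _ in range(60)]
        ct1 = crosstab_retention(fates, lambda r: r.group, (("A",), ("B",)))
        shuffled = list(fates)
        rng.shuffle(shuffled)
        ct2 = crosstab_retention(shuffled, lambda r: r.group, (("A",), ("B",)))
        assert ct1.table == ct2.table and ct1.fisher_p == ct2.fisher_p

    def test_empty_comparison_group_errors(self):
        fates = [fake_record(RETAINED, "A")]
        with pytest.raises(ValueError):
            crosstab_retention(fates, lambda r: r.group, (("A",), ("Z",)))


class TestViolin:
    def test_quantiles_linear_interpolation(self):
        summaries, _ = violin_summary({"g": list(range(1, 101))})
        s = summaries[0]
        assert s.median == 50.5 and s.quartile25 == 25.75 and s.quartile75 == 75.25

    def test_single_value(self):
        s = violin_summary({"g": [7.0]})[0][0]
        assert s.median == s.quartile25 == s.quartile75 == 7.0

    def test_contrast_p_attached(self):
        _, p = violin_summary({"a": [1, 2, 3], "b": [4, 5, 6]}, (("a",), ("b",)))
        assert p == pytest.approx(0.1)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_hinges_ordered(self, values):
        s = violin_summary({"g": values})[0][0]
        assert s.quartile25 <= s.median <= s.quartile75


class TestMappedPercentage:
    def test_printed_counts(self):
        assert mapped_percentage(3481, 2176) == 62.5

    def test_summary_frame(self):
        df = mapping_summary({"PPARG": 3481, "CEBPA": 8688}, {"PPARG": 2176, "CEBPA": 4899})
        assert df.set_index("factor").loc["PPARG", "mapped_pct"] == 62.5

    def test_zero_detected_errors(self):
        with pytest.raises(ValueError):
            mapped_percentage(0, 0)


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.02, 0.04, 0.8]
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)
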