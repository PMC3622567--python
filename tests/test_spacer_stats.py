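"""Whisker outliers, correlation statistics and subset profiles."""
import math

import numpy as np
import pytest
from scipy import stats as sps

from acedyad.dyad_scan import per_gene_counts, scan_hits
from acedyad.spacer_stats import (
    best_window_per_width,
    common_peaks,
    p_from_t,
    pearson_r,
    percentile_outliers,
    subset_profile,
    t_from_r,
    window_correlations,
)
from conftest import make_promoter_set


class TestPercentileOutliers:
    def test_single_extreme_value_is_peak(self):
        # thirty bulk values in [1,5]; the 90th-percentile whisker sits at the
        # bulk maximum, so only the value 100 lies strictly above it
        counts = [1.0, 2.0, 3.0, 4.0, 5.0] * 6 + [100.0]
        out = percentile_outliers(counts)
        assert out.peaks == {30}
        assert 30 not in out.dips

    def test_constant_vector_has_no_outliers(self):
        out = percentile_outliers([7.0] * 31)
        assert out.peaks == set() and out.dips == set()

    def test_shift_invariance_and_negation_duality(self, rng):
        x = rng.poisson(20, size=31).astype(float)
        a = percentile_outliers(x)
        b = percentile_outliers(x + 1000.0)
        assert a.peaks == b.peaks and a.dips == b.dips
        neg = percentile_outliers(-x)
        assert neg.peaks == a.dips and neg.dips == a.peaks

    def test_inclusive_linear_interpolation(self):
        # For [0,10,20,...,100] the 90th percentile (type 7) is 90; only 100 exceeds.
        x = list(range(0, 101, 10))
        out = percentile_outliers(x, 10, 90)
        assert out.high_value == 90.0 and out.low_value == 10.0
        assert out.peaks == {10} and out.dips == {0}

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            percentile_outliers([1, 2, 3])

    def test_common_peaks_intersection(self):
        base = [1.0] * 30
        a = percentile_outliers(base + [50.0])
        b = percentile_outliers([50.0] + base)
        assert common_peaks({"x": a, "y": b}) == set()
        assert common_peaks({"x": a, "z": a}) == {30}


class TestPearson:
    def test_perfect_linear_relations(self):
        x = [1, 2, 3, 4, 5]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_textbook_sum_formula(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 8]
        n = len(x)
        sx, sy = sum(x), sum(y)
        sxy = sum(a * b for a, b in zip(x, y))
        sxx = sum(a * a for a in x)
        syy = sum(b * b for b in y)
        expected = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx * sx) * (n * syy - sy * sy)
        )
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCorrelationTests:
    def test_published_worked_values(self):
        # r = 0.974 over 6 consecutive spacer lengths gives t = 8.599
        assert t_from_r(0.974, 6) == pytest.approx(8.599, abs=1e-3)
        # r = 0.934 over 9 lengths: 6.921 when computed from the unrounded r
        assert t_from_r(0.934, 9) == pytest.approx(6.921, abs=1e-2)
        assert p_from_t(8.599, 4) == pytest.approx(0.0010, abs=5e-5)

    def test_trivial_values(self):
        assert t_from_r(0.0, 10) == 0.0
        assert p_from_t(0.0, 7) == 1.0

    def test_t_table_quantile_round_trip(self):
        # classical two-sided 5% critical value of t with 4 df
        assert p_from_t(2.776, 4) == pytest.approx(0.050, abs=5e-4)

    def test_infinite_statistic_at_unit_correlation(self):
        assert math.isinf(t_from_r(1.0, 6))
        assert p_from_t(t_from_r(-1.0, 6), 4) == 0.0

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(-0.99, 0.99, 21)
        ts = [t_from_r(r, 8) for r in rs]
        assert all(a < b for a, b in zip(ts, ts[1:]))
        assert t_from_r(0.5, 20) > t_from_r(0.5, 5)

    def test_agrees_with_scipy_pearson_test(self, rng):
        # p_from_t(t_from_r(r, n), n-2) is the standard correlation test
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.8, size=12)
        res = sps.pearsonr(x, y)
        r = pearson_r(x, y)
        assert r == pytest.approx(res.statistic, abs=1e-12)
        assert p_from_t(t_from_r(r, 12), 10) == pytest.approx(res.pvalue, rel=1e-9)


class TestWindowCorrelations:
    def test_enumeration_count_for_31_length_profiles(self, rng):
        a = rng.poisson(20, 31).astype(float) + np.arange(31)
        b = rng.poisson(20, 31).astype(float) + np.arange(31)
        ws = window_correlations(a, b, min_width=6)
        assert len(ws) == sum(31 - k + 1 for k in range(6, 32)) == 351
        full = [w for w in ws if w.width == 31]
        assert len(full) == 1 and full[0].df == 29

    def test_proportional_profiles_give_unit_r_everywhere(self, rng):
        a = rng.uniform(1, 10, 31)
        ws = window_correlations(a, 3 * a, min_width=6)
        assert all(w.r == pytest.approx(1.0) for w in ws)

    def test_exhaustive_enumeration_on_length_8(self):
        a = [1.0, 3, 2, 5, 4, 7, 6, 9]
        b = [2.0, 2, 3, 6, 5, 8, 6, 8]
        ws = window_correlations(a, b, min_width=6)
        assert {(w.start_N, w.width) for w in ws} == {
            (0, 6), (1, 6), (2, 6), (0, 7), (1, 7), (0, 8)
        }
        for w in ws:
            assert w.r == pytest.approx(
                pearson_r(a[w.start_N : w.start_N + w.width],
                          b[w.start_N : w.start_N + w.width])
            )

    def test_zero_variance_window_skipped(self):
        a = [1.0] * 6 + [1, 2, 3, 4, 5, 6]
        b = list(range(12))
        ws = window_correlations(a, b, min_width=6)
        assert all(not (w.start_N == 0 and w.width == 6) for w in ws)

    def test_scaling_leaves_r_unchanged(self, rng):
        a = rng.uniform(1, 10, 31)
        b = rng.uniform(1, 10, 31)
        raw = window_correlations(a, b)
        scaled = window_correlations(a * 1000 / 7, b * 1000 / 13)
        for u, v in zip(raw, scaled):
            assert u.r == pytest.approx(v.r, abs=1e-12)

    def test_best_window_per_width(self, rng):
        a = rng.uniform(1, 10, 31)
        b = rng.uniform(1, 10, 31)
        ws = window_correlations(a, b)
        best = best_window_per_width(ws)
        for width, w in best.items():
            assert w.r == max(x.r for x in ws if x.width == width)


class TestSubsetProfile:
    @pytest.fixture
    def scanned(self):
        pset = make_promoter_set(
            {"g1": "ACGTACGT", "g2": "ACGTAACGTA", "g3": "TTTTTTTT"}
        )
        hits = scan_hits(pset, "ACGT")
        return per_gene_counts(hits), set(pset.entries)

    def test_full_subset_equals_full_profile(self, scanned):
        per_gene, genes = scanned
        prof = subset_profile(per_gene, sorted(genes), scanned_genes=genes)
        assert prof.counts[0] == 1 and prof.counts[1] == 1
        assert prof.n_promoters == 3

    def test_zero_hit_subset_is_zero_vector(self, scanned):
        per_gene, genes = scanned
        prof = subset_profile(per_gene, ["g3"], scanned_genes=genes)
        assert prof.counts.sum() == 0 and prof.n_promoters == 1

    def test_manual_tally_on_three_gene_toy(self, scanned):
        per_gene, genes = scanned
        prof = subset_profile(per_gene, ["g1", "g3"], scanned_genes=genes)
        assert prof.counts[0] == 1 and prof.counts.sum() == 1
        assert prof.n_promoters == 2

    def test_unknown_gene_skipped_with_reduced_n(self, scanned):
        per_gene, genes = scanned
        prof = subset_profile(per_gene, ["g1", "nope"], scanned_genes=genes)
        assert prof.n_promoters == 1 and prof.counts[0] == 1
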