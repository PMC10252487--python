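import itertools
import math

import numpy as np
import pytest

from chiprn.errors import DataError, DegenerateInputError
from chiprn.genome import GenomeAssembly, GenomicInterval, LocusSet, constant_track
from chiprn.normalize import ReplicateSet
from chiprn.stats import (
    aggregate_bins,
    distribution_summary,
    mann_whitney_enrichment,
    mann_whitney_from_groups,
    replicate_correlation,
    signal_efficiency_correlation,
)

from conftest import make_track, random_track


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def u_by_pair_counting(x, y):
    """U for group x counted pair by pair (wins + half-ties)."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else 0.5 if xi == yj else 0.0
    return u


def exact_p_by_enumeration(x, y):
    """Two-sided exact p: enumerate every assignment of the pooled values."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = u_by_pair_counting(x, y)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in combo]
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_by_pair_counting(grp, rest)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def tukey_oracle(values):
    """High/low outlier counts from hand-rolled quartiles (sort + interpolate)."""
    s = np.sort(values)
    n = len(s)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return int((values > q3 + 1.5 * iqr).sum()), int((values < q1 - 1.5 * iqr).sum())


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregateBins:
    def test_rebins_by_mean(self):
        asm = GenomeAssembly(("chrI",), (400,), bin_size=50)
        t = make_track(asm, {"chrI": [1, 3, 5, 7, 2, 4, 6, 8]})
        values, index = aggregate_bins(t, 200)
        np.testing.assert_array_equal(values, [4.0, 5.0])
        np.testing.assert_array_equal(index.start, [0, 200])

    def test_partial_trailing_group(self):
        asm = GenomeAssembly(("chrI",), (300,), bin_size=50)
        t = make_track(asm, {"chrI": [1, 1, 1, 1, 10, 20]})
        values, _ = aggregate_bins(t, 200)
        np.testing.assert_array_equal(values, [1.0, 15.0])

    def test_fully_masked_group_stays_nan(self):
        asm = GenomeAssembly(("chrI",), (200,), bin_size=50)
        t = make_track(asm, {"chrI": [np.nan, np.nan, 2.0, 4.0]},
                       state=("ratio_normalized",))
        values, _ = aggregate_bins(t, 100)
        assert np.isnan(values[0]) and values[1] == 3.0


# ---------------------------------------------------------------------------
# distribution summary
# ---------------------------------------------------------------------------

class TestDistributionSummary:
    def test_constant_track_has_no_outliers(self, asm):
        s = distribution_summary(constant_track(asm, 2.0), agg_bin=100)
        assert s.iqr == 0
        assert s.outlier_count_high == s.outlier_count_low == 0

    def test_single_high_outlier_hand_case(self):
        asm = GenomeAssembly(("chrI",), (250,), bin_size=50)
        t = make_track(asm, {"chrI": [1, 2, 3, 4, 100]})
        s = distribution_summary(t, agg_bin=50)
        # hand Tukey: Q1=2, Q3=4, IQR=2, fences (-1, 7) -> only 100 is out
        assert s.outlier_count_high == 1
        assert s.outlier_count_low == 0

    @pytest.mark.parametrize("seed", range(50))
    def test_outlier_counts_match_hand_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 60))
        asm = GenomeAssembly(("chrI",), (n * 50,), bin_size=50)
        values = rng.lognormal(0, 1, size=n).round(3)
        t = make_track(asm, {"chrI": values})
        s = distribution_summary(t, agg_bin=50)
        hi, lo = tukey_oracle(values)
        assert (s.outlier_count_high, s.outlier_count_low) == (hi, lo)

    def test_outlier_rule_invariant_under_positive_scaling(self, asm, rng):
        t = random_track(asm, rng, integer=False, low=0, high=10)
        s1 = distribution_summary(t, agg_bin=100)
        scaled = t.with_values({c: v * 7.5 for c, v in t.values.items()})
        s2 = distribution_summary(scaled, agg_bin=100)
        assert (s1.outlier_count_high, s1.outlier_count_low) == (
            s2.outlier_count_high, s2.outlier_count_low
        )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_tied_groups(self):
        res = mann_whitney_from_groups([2, 2], [2, 2])
        assert res.u_statistic == 2.0
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_separated_groups_exact_p(self):
        res = mann_whitney_from_groups([4, 5], [1, 2, 3])
        assert res.u_statistic == 6.0
        assert res.p_value == pytest.approx(exact_p_by_enumeration([4, 5], [1, 2, 3]))
        assert res.direction == "over"
        assert res.method == "exact"

    @pytest.mark.parametrize("n", range(2, 9))
    def test_matches_enumeration_for_all_splits(self, n):
        """Every (n1, n2) split of pooled values with ties, n <= 8."""
        rng = np.random.default_rng(n)
        for n1 in range(1, n):
            for _ in range(3):
                pooled = rng.integers(0, 4, size=n).astype(float)
                x, y = pooled[:n1], pooled[n1:]
                res = mann_whitney_from_groups(x, y)
                assert res.u_statistic == pytest.approx(u_by_pair_counting(x, y))
                assert res.p_value == pytest.approx(exact_p_by_enumeration(x, y))

    def test_all_set_above_background_is_over_enriched(self):
        res = mann_whitney_from_groups([10, 11, 12], [1, 2, 3])
        assert res.direction == "over"
        assert res.p_value < 0.2  # exact floor for 3v3

    def test_large_groups_use_asymptotic_method(self, rng):
        x = rng.normal(1, 1, 300)
        y = rng.normal(0, 1, 3000)
        res = mann_whitney_from_groups(x, y)
        assert res.method == "asymptotic"
        assert res.p_value < 0.01 and res.direction == "over"


class TestMannWhitneyEnrichment:
    @pytest.fixture
    def enriched(self, asm):
        vals = {"chrI": np.ones(20), "chrII": np.ones(10)}
        vals["chrI"][4:8] = 9.0
        return make_track(asm, vals)

    def test_partition_covers_all_bins(self, enriched, asm):
        loci = LocusSet("roi", [GenomicInterval("chrI", 200, 400)])
        res = mann_whitney_enrichment(enriched, loci, agg_bin=50)
        assert res.n_set + res.n_background == asm.total_bins
        assert res.direction == "over"

    def test_one_bp_overlap_counts(self, enriched):
        # interval covering 1 bp of bin 4 only
        loci = LocusSet("roi", [GenomicInterval("chrI", 249, 250)])
        res = mann_whitney_enrichment(enriched, loci, agg_bin=50)
        assert res.n_set == 1

    def test_no_overlap_is_an_error_naming_the_set(self, enriched):
        loci = LocusSet("offgenome", [GenomicInterval("chrII", 490, 500)])
        # chrII has 10 bins; interval overlaps the last -> shrink to a set
        # that truly misses: use an aggregated bin fully masked instead
        res = mann_whitney_enrichment(enriched, loci, agg_bin=50)
        assert res.n_set == 1
        empty = LocusSet("empty_set", [])
        with pytest.raises(DegenerateInputError, match="empty_set"):
            mann_whitney_enrichment(enriched, empty, agg_bin=50)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

class TestReplicateCorrelation:
    def test_identical_replicates(self, asm, rng):
        t = random_track(asm, rng)
        mat = replicate_correlation(ReplicateSet([t, t.copy()]))
        np.testing.assert_allclose(mat.values, 1.0)

    def test_opposite_trend(self):
        asm = GenomeAssembly(("chrI",), (150,), bin_size=50)
        a = make_track(asm, {"chrI": [1, 2, 3]})
        b = make_track(asm, {"chrI": [3, 2, 1]})
        mat = replicate_correlation(ReplicateSet([a, b]))
        assert mat.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, asm, rng):
        a, b = random_track(asm, rng), random_track(asm, rng)
        mat = replicate_correlation(ReplicateSet([a, b]))
        x, y = a.flatten(), b.flatten()
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert mat.iloc[0, 1] == pytest.approx(r)

    def test_zero_variance_reported_missing_with_warning(self, asm, rng):
        a = random_track(asm, rng)
        b = constant_track(asm, 3.0)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            mat = replicate_correlation(ReplicateSet([a, b]))
        assert np.isnan(mat.iloc[0, 1])


def spearman_oracle(x, y):
    """Exhaustive rank formula (no ties): rho = 1 - 6*sum(d^2)/(n(n^2-1))."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n ** 2 - 1))


class TestSignalEfficiencyCorrelation:
    def _origins(self, signals, efficiencies):
        return LocusSet(
            "origins",
            [
                GenomicInterval("chrI", 100 * i, 100 * i + 50, score=float(e))
                for i, e in enumerate(efficiencies)
            ],
        ), signals

    def test_monotone_identity(self):
        asm = GenomeAssembly(("chrI",), (1000,), bin_size=50)
        vals = np.arange(20.0)
        t = make_track(asm, {"chrI": vals})
        origins = LocusSet(
            "o", [GenomicInterval("chrI", i * 50, i * 50 + 50, score=float(i))
                  for i in range(0, 20, 4)]
        )
        res = signal_efficiency_correlation(t, origins, flank=20)
        assert res.rho == pytest.approx(1.0)

    def test_matches_exhaustive_rank_formula(self):
        rng = np.random.default_rng(5)
        asm = GenomeAssembly(("chrI",), (5000,), bin_size=50)
        vals = np.zeros(100)
        centers = [5, 25, 45, 65, 85]
        signals = rng.permutation([1.0, 2.0, 3.0, 4.0, 5.0])
        for c, s in zip(centers, signals):
            vals[c] = s
        t = make_track(asm, {"chrI": vals})
        effs = [3.0, 1.0, 5.0, 2.0, 4.0]
        origins = LocusSet(
            "o", [GenomicInterval("chrI", c * 50, c * 50 + 50, score=e)
                  for c, e in zip(centers, effs)]
        )
        res = signal_efficiency_correlation(t, origins, flank=100)
        assert res.rho == pytest.approx(spearman_oracle(signals, np.array(effs)))
        assert res.n == 5

    def test_constant_efficiencies_undefined(self):
        asm = GenomeAssembly(("chrI",), (1000,), bin_size=50)
        t = make_track(asm, {"chrI": np.arange(20.0)})
        origins = LocusSet(
            "o", [GenomicInterval("chrI", i * 50, i * 50 + 50, score=1.0)
                  for i in range(0, 20, 4)]
        )
        with pytest.warns(RuntimeWarning, match="undefined"):
            res = signal_efficiency_correlation(t, origins, flank=20)
        assert np.isnan(res.rho)

    def test_too_few_scored_origins(self):
        asm = GenomeAssembly(("chrI",), (1000,), bin_size=50)
        t = make_track(asm, {"chrI": np.arange(20.0)})
        origins = LocusSet("o", [GenomicInterval("chrI", 0, 50, score=1.0)])
        with pytest.raises(DegenerateInputError, match=">= 3"):
            signal_efficiency_correlation(t, origins)
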