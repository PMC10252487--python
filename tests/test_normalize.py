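import numpy as np
import pytest

from chiprn.errors import (
    ConfigError,
    DataError,
    DegenerateInputError,
    StateError,
)
from chiprn.genome import GenomeAssembly, constant_track
from chiprn.normalize import (
    ReplicateSet,
    RNConfig,
    average_replicates,
    counts_normalize,
    ratio_normalize,
    run_rn_pipeline,
    scale_normalize,
    smooth_track,
)

from conftest import make_track, random_track


def smooth_oracle(v, k):
    """Brute-force centered windowed mean with shrink-to-available edges."""
    h = k // 2
    n = len(v)
    return np.array([np.mean(v[max(0, i - h): min(n, i + h + 1)]) for i in range(n)])


@pytest.fixture
def line_asm():
    """Single 2500 bp chromosome -> 50 bins."""
    return GenomeAssembly(("chrI",), (2500,), bin_size=50)


class TestCountsNormalize:
    def test_forced_scale_factors(self, asm):
        r1 = make_track(asm, {"chrI": np.full(20, 4.0), "chrII": np.full(10, 2.0)})  # 100
        r2 = make_track(asm, {"chrI": np.full(20, 12.0), "chrII": np.full(10, 6.0)})  # 300
        out = counts_normalize(ReplicateSet([r1, r2]), target_total=200)
        np.testing.assert_allclose(out.tracks[0].values["chrI"], 8.0)  # x2
        np.testing.assert_allclose(out.tracks[1].values["chrII"], 4.0)  # x2/3
        for t in out:
            assert t.total == pytest.approx(200)

    def test_replicate_at_target_unchanged(self, asm, rng):
        t = random_track(asm, rng)
        out = counts_normalize(ReplicateSet([t]), target_total=t.total)
        for c in asm.chrom_names:
            np.testing.assert_array_equal(out.tracks[0].values[c], t.values[c])

    def test_default_target_preserves_mean_total(self, asm, rng):
        reps = ReplicateSet([random_track(asm, rng, low=1) for _ in range(3)])
        mean_total = np.mean([t.total for t in reps])
        out = counts_normalize(reps)
        for t in out:
            assert t.total == pytest.approx(mean_total)

    def test_relative_bin_ratios_preserved(self, asm, rng):
        t = random_track(asm, rng, low=1)
        out = counts_normalize(ReplicateSet([t]), target_total=123.4)
        r = np.corrcoef(t.flatten(), out.tracks[0].flatten())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_replicate_rejected(self, asm):
        t = constant_track(asm, 0.0)
        with pytest.raises(DegenerateInputError, match="zero total"):
            counts_normalize(ReplicateSet([t]), target_total=100)


class TestSmoothTrack:
    def test_constant_track_unchanged(self, asm):
        out = smooth_track(constant_track(asm, 3.0), window=250)
        for c in asm.chrom_names:
            np.testing.assert_array_equal(out.values[c], 3.0)

    def test_window_equal_to_bin_is_identity(self, asm, rng):
        t = random_track(asm, rng)
        out = smooth_track(t, window=50)
        for c in asm.chrom_names:
            np.testing.assert_array_equal(out.values[c], t.values[c])

    def test_impulse_k3(self):
        asm = GenomeAssembly(("chrI",), (250,), bin_size=50)
        t = make_track(asm, {"chrI": [0, 0, 10, 0, 0]})
        out = smooth_track(t, window=150)
        np.testing.assert_allclose(
            out.values["chrI"], [0, 10 / 3, 10 / 3, 10 / 3, 0]
        )

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("window", [150, 500, 1050])
    def test_matches_brute_force_oracle(self, line_asm, seed, window):
        rng = np.random.default_rng(seed)
        t = random_track(line_asm, rng)
        k = round(window / 50)
        k += k % 2 == 0  # even windows widen by one bin
        out = smooth_track(t, window=window)
        np.testing.assert_array_equal(
            out.values["chrI"], smooth_oracle(t.values["chrI"], k)
        )

    def test_window_below_bin_size_rejected(self, asm, rng):
        with pytest.raises(ConfigError, match="smaller than the bin size"):
            smooth_track(random_track(asm, rng), window=10)


class TestScaleNormalize:
    def test_constant_track_becomes_ones(self, asm):
        out = scale_normalize(constant_track(asm, 5.0), percentile=20)
        np.testing.assert_array_equal(out.flatten(), 1.0)

    def test_matches_sort_and_interpolate_oracle(self):
        asm = GenomeAssembly(("chrI",), (500,), bin_size=50)
        values = np.arange(1.0, 11.0)
        t = make_track(asm, {"chrI": values})
        # independent oracle: sorted order statistics, linear interpolation at
        # rank position p/100 * (n-1)
        pos = 0.20 * 9
        lo, frac = int(pos), pos - int(pos)
        expected_bg = np.sort(values)[lo] * (1 - frac) + np.sort(values)[lo + 1] * frac
        out = scale_normalize(t, percentile=20)
        np.testing.assert_allclose(out.values["chrI"], values / expected_bg)

    def test_output_percentile_is_one(self, asm, rng):
        t = random_track(asm, rng, low=1, integer=False)
        out = scale_normalize(t, percentile=20)
        assert np.percentile(out.flatten(), 20) == pytest.approx(1.0, abs=1e-9)

    def test_zero_background_rejected(self, asm):
        vals = {"chrI": np.zeros(20), "chrII": np.zeros(10)}
        vals["chrII"][-1] = 1.0
        with pytest.raises(DegenerateInputError, match="20"):
            scale_normalize(make_track(asm, vals), percentile=20)


class TestAverageReplicates:
    def test_forced_arithmetic(self):
        asm = GenomeAssembly(("chrI",), (100,), bin_size=50)
        r1 = make_track(asm, {"chrI": [1, 3]})
        r2 = make_track(asm, {"chrI": [3, 5]})
        out = average_replicates(ReplicateSet([r1, r2]))
        np.testing.assert_array_equal(out.values["chrI"], [2.0, 4.0])

    def test_order_invariant(self, asm, rng):
        reps = [random_track(asm, rng) for _ in range(3)]
        a = average_replicates(ReplicateSet(reps))
        b = average_replicates(ReplicateSet(reps[::-1]))
        for c in asm.chrom_names:
            np.testing.assert_array_equal(a.values[c], b.values[c])

    def test_mixed_states_rejected(self, asm, rng):
        r1 = random_track(asm, rng)
        r2 = random_track(asm, rng, state=("counts_normalized",))
        with pytest.raises(StateError, match="mixed"):
            ReplicateSet([r1, r2])


NORM_STATE = ("counts_normalized", "smoothed", "scale_normalized", "averaged")


class TestRatioNormalize:
    def test_self_ratio_is_one(self, asm, rng):
        t = random_track(asm, rng, low=1, state=NORM_STATE)
        out = ratio_normalize(t, t, RNConfig())
        np.testing.assert_array_equal(out.flatten(), 1.0)

    def test_pseudocount_formula(self, asm):
        ctrl = make_track(asm, {c: np.ones(asm.n_bins(c)) for c in asm.chrom_names},
                          state=NORM_STATE)
        exp = make_track(asm, {c: np.full(asm.n_bins(c), 2.0) for c in asm.chrom_names},
                         state=NORM_STATE)
        out = ratio_normalize(exp, ctrl, RNConfig(pseudocount=0.01))
        np.testing.assert_allclose(out.flatten(), 2.01 / 1.01)

    def test_low_control_bins_masked(self, asm):
        vals = {c: np.ones(asm.n_bins(c)) for c in asm.chrom_names}
        vals["chrI"] = vals["chrI"].copy()
        vals["chrI"][4] = 0.05
        ctrl = make_track(asm, vals, state=NORM_STATE)
        exp = make_track(asm, {c: np.ones(asm.n_bins(c)) for c in asm.chrom_names},
                         state=NORM_STATE)
        out = ratio_normalize(exp, ctrl, RNConfig(control_floor=0.1))
        assert np.isnan(out.values["chrI"][4])
        assert np.isfinite(out.values["chrI"][5])
        assert out.is_ratio_normalized

    def test_unnormalized_control_rejected(self, asm, rng):
        exp = random_track(asm, rng, state=NORM_STATE)
        ctrl = random_track(asm, rng)
        with pytest.raises(StateError, match="scale_normalized"):
            ratio_normalize(exp, ctrl, RNConfig())

    def test_assembly_mismatch_rejected(self, asm, rng):
        other = GenomeAssembly(("chrI",), (1000,), bin_size=50)
        exp = random_track(asm, rng, state=NORM_STATE)
        ctrl = random_track(other, rng, state=NORM_STATE)
        with pytest.raises(DataError, match="assembly"):
            ratio_normalize(exp, ctrl, RNConfig())


class TestRunRnPipeline:
    def test_identical_sides_give_unit_track(self, asm, rng):
        reps = [random_track(asm, rng, low=5) for _ in range(3)]
        res = run_rn_pipeline(ReplicateSet(reps), ReplicateSet(reps), RNConfig())
        rn = res.rn.flatten()
        np.testing.assert_allclose(rn[~np.isnan(rn)], 1.0)

    def test_single_replicate_each_side(self, asm, rng):
        res = run_rn_pipeline(
            ReplicateSet([random_track(asm, rng, low=5)]),
            ReplicateSet([random_track(asm, rng, low=5)]),
            RNConfig(),
        )
        assert res.rn.is_ratio_normalized

    def test_bit_identical_determinism(self, asm, rng):
        exp = [random_track(asm, rng, low=5) for _ in range(2)]
        ctrl = [random_track(asm, rng, low=5) for _ in range(2)]
        a = run_rn_pipeline(ReplicateSet(exp), ReplicateSet(ctrl), RNConfig())
        b = run_rn_pipeline(ReplicateSet(exp), ReplicateSet(ctrl), RNConfig())
        for c in asm.chrom_names:
            np.testing.assert_array_equal(a.rn.values[c], b.rn.values[c])

    def test_non_raw_input_rejected(self, asm, rng):
        pre = ReplicateSet([random_track(asm, rng, state=("smoothed",))])
        raw = ReplicateSet([random_track(asm, rng, low=5)])
        with pytest.raises(StateError, match="raw"):
            run_rn_pipeline(pre, raw, RNConfig())

    def test_logs_scale_factors_and_backgrounds(self, asm, rng):
        exp = ReplicateSet([random_track(asm, rng, low=5, sample_id="e1")])
        ctrl = ReplicateSet([random_track(asm, rng, low=5, sample_id="c1")])
        res = run_rn_pipeline(exp, ctrl, RNConfig())
        assert set(res.scale_factors) == {"e1", "c1"}
        assert all(v > 0 for v in res.background_values.values())


def test_rnconfig_validation():
    with pytest.raises(ConfigError):
        RNConfig(background_percentile=0)
    with pytest.raises(ConfigError):
        RNConfig(pseudocount=0)
    with pytest.raises(ConfigError):
        RNConfig(smooth_window=-100)
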