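import numpy as np
import pytest

from chiprn.genome import BinnedTrack, GenomeAssembly, TrackMeta


@pytest.fixture
def asm():
    """Tiny two-chromosome assembly: chrI 1000 bp (20 bins), chrII 500 bp (10)."""
    return GenomeAssembly(("chrI", "chrII"), (1000, 500), bin_size=50)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_track(assembly, per_chrom, state=(), sample_id="t"):
    """Build a BinnedTrack from per-chromosome value lists."""
    values = {
        c: np.asarray(per_chrom[c], dtype=float) for c in assembly.chrom_names
    }
    return BinnedTrack(assembly, values, TrackMeta(sample_id=sample_id, state=tuple(state)))


def random_track(assembly, rng, state=(), low=0, high=50, integer=True,
                 sample_id="rand"):
    """Random non-negative track (integer-valued by default, so windowed
    sums are exact in float64)."""
    values = {}
    for c in assembly.chrom_names:
        n = assembly.n_bins(c)
        if integer:
            values[c] = rng.integers(low, high, size=n).astype(float)
        else:
            values[c] = rng.uniform(low, high, size=n)
    return BinnedTrack(assembly, values, TrackMeta(sample_id=sample_id, state=tuple(state)))
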