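"""Feature-centered signal matrices, telomere-distance profiles, and
peak-vs-reference classification with Venn overlaps.

These are the read-outs used to judge a normalization: heatmap/metaprofile
matrices centered on loci of interest (origins, gene classes), signal as a
function of distance to the nearest chromosome end (telomere-associated
enrichment), and assignment of called peaks to categorized reference sets
such as replication origins (confirmed > likely > dubious).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genome import BinnedTrack, GenomicInterval, LocusSet, PeakSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature-centered matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Signal across centered windows, one row per feature.

    Columns run left-to-right across a window of ``width`` bp centered on
    each feature midpoint at track bin resolution; rows of minus-strand
    features are flipped so columns always run 5'->3'. Features whose window
    leaves the chromosome are dropped (recorded in ``n_dropped``).
    """

    matrix: np.ndarray  # (n_features, width // bin_size)
    feature_labels: list[str]
    width: int
    bin_size: int
    n_dropped: int = 0

    @property
    def mean_profile(self) -> np.ndarray:
        """Column-wise mean signal across features (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)

    @property
    def positions(self) -> np.ndarray:
        """Column center offsets in bp relative to the feature midpoint."""
        n = self.matrix.shape[1]
        return (np.arange(n) - n // 2) * self.bin_size + self.bin_size // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.feature_labels, columns=self.positions)


def feature_matrix(track: BinnedTrack, loci: LocusSet, width: int = 5000) -> FeatureMatrix:
    """Extract the signal across ``width`` bp windows centered on each locus.

    The window is centered on the bin containing the interval midpoint and
    spans ``width / bin_size`` bins. Rows keep the order of ``loci``.
    """
    w = track.assembly.bin_size
    if width <= 0 or width % w != 0 or (width // w) % 2 != 0:
        raise ConfigError(
            f"width {width} must be a positive even multiple of bin size {w}"
        )
    cols = width // w
    half = cols // 2
    rows, labels = [], []
    n_dropped = 0
    for i, iv in enumerate(loci):
        v = track.values[iv.chrom]
        center = iv.midpoint // w
        lo, hi = center - half, center + half
        if lo < 0 or hi > v.size:
            n_dropped += 1
            logger.warning(
                "feature_matrix: %s window [%d, %d) leaves %s; row dropped",
                loci.name, lo * w, hi * w, iv.chrom,
            )
            continue
        row = v[lo:hi]
        if iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        labels.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
    matrix = np.vstack(rows) if rows else np.empty((0, cols))
    return FeatureMatrix(
        matrix=matrix, feature_labels=labels, width=width, bin_size=w,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# telomere-distance profile
# ---------------------------------------------------------------------------

def telomere_distance_profile(
    track: BinnedTrack, highlight: LocusSet | None = None
) -> pd.DataFrame:
    """Per-bin distance to the nearest chromosome end, with the bin's signal.

    Distance is measured from the bin midpoint: ``min(mid, length - mid)``.
    When ``highlight`` is given, a boolean column marks bins overlapping it
    (used to flag known loci on the profile).
    """
    asm = track.assembly
    w = asm.bin_size
    frames = []
    for chrom in asm.chrom_names:
        v = track.values[chrom]
        length = asm.length_of(chrom)
        starts = np.arange(v.size) * w
        mids = np.minimum(starts + w // 2, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": starts,
                    "distance": np.minimum(mids, length - mids),
                    "signal": v,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if highlight is not None:
        out["highlighted"] = highlight.bin_overlap_mask(asm)
    return out


# ---------------------------------------------------------------------------
# peak classification against categorized references
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Peaks assigned to exactly one reference category each.

    ``counts`` maps every priority category plus "other" to the number of
    peaks whose highest-priority overlap is that category; they always sum
    to ``total``.
    """

    counts: dict[str, int]
    total: int
    assignments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise DataError("overlap category counts do not sum to total")

    def fraction(self, category: str) -> float:
        return self.counts.get(category, 0) / self.total if self.total else 0.0


def _category_intervals(
    references: list[LocusSet],
) -> dict[str, list[GenomicInterval]]:
    """Pool reference intervals by category (interval label, else set name)."""
    by_cat: dict[str, list[GenomicInterval]] = {}
    seen_in: dict[str, str] = {}
    for ref in references:
        cats_here = set()
        for iv in ref:
            cat = iv.category if iv.category is not None else ref.name
            cats_here.add(cat)
            by_cat.setdefault(cat, []).append(iv)
        for cat in cats_here:
            if cat in seen_in and seen_in[cat] != ref.name:
                raise DataError(
                    f"category {cat!r} appears in both {seen_in[cat]!r} and {ref.name!r}"
                )
            seen_in[cat] = ref.name
    return by_cat


def classify_peak_overlaps(
    peaks: PeakSet | LocusSet,
    references: list[LocusSet],
    priority: list[str],
) -> OverlapReport:
    """Assign each peak to the highest-priority overlapped reference category.

    Overlap is >=1 bp intersection. A peak overlapping several categories is
    counted once, under the earliest category in ``priority`` (e.g. a peak on
    both a confirmed and a dubious origin counts as confirmed); peaks
    overlapping nothing are "other".
    """
    by_cat = _category_intervals(references)
    missing = set(by_cat) - set(priority)
    if missing:
        raise ConfigError(
            f"priority list does not cover reference categories: {sorted(missing)}"
        )
    items = list(peaks) if isinstance(peaks, LocusSet) else list(peaks.peaks)
    counts = {cat: 0 for cat in priority}
    counts["other"] = 0
    assignments = []
    for p in items:
        label = "other"
        for cat in priority:
            if any(
                iv.chrom == p.chrom and iv.start < p.end and p.start < iv.end
                for iv in by_cat.get(cat, ())
            ):
                label = cat
                break
        counts[label] += 1
        assignments.append(label)
    return OverlapReport(counts=counts, total=len(items), assignments=assignments)


# ---------------------------------------------------------------------------
# Venn overlaps between interval sets
# ---------------------------------------------------------------------------

def _as_locus_set(s: PeakSet | LocusSet, fallback: str) -> LocusSet:
    return s if isinstance(s, LocusSet) else s.to_locus_set(name=fallback)


def venn_overlap(sets: list[PeakSet | LocusSet]) -> dict[str, dict[str, int]]:
    """Venn region counts for 2-3 interval sets.

    Interval sets of different element counts share no common universe, so
    counts are reported per perspective: for each set, every element is
    assigned its membership region (the subset of set names whose intervals
    it intersects, itself included), and regions are tallied in units of
    that set's elements. Region keys are "&"-joined set names in input
    order; per set, region counts sum to the set size.
    """
    if not (2 <= len(sets) <= 3):
        raise ConfigError(f"venn_overlap supports 2-3 sets, got {len(sets)}")
    loci = [_as_locus_set(s, f"set{i + 1}") for i, s in enumerate(sets)]
    names = [ls.name for ls in loci]
    if len(set(names)) != len(names):
        raise DataError(f"venn_overlap: duplicate set names {names}")
    report: dict[str, dict[str, int]] = {}
    for i, ls in enumerate(loci):
        regions: dict[str, int] = {}
        for iv in ls:
            members = [
                names[j]
                for j, other in enumerate(loci)
                if j == i
                or any(
                    o.chrom == iv.chrom and o.start < iv.end and iv.start < o.end
                    for o in other
                )
            ]
            key = "&".join(members)
            regions[key] = regions.get(key, 0) + 1
        report[names[i]] = regions
    return report
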