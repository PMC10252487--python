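"""Core in-memory containers: assembly, binned signal tracks, locus and peak sets.

Coordinates are 0-based half-open throughout (BED convention). A track stores
one float64 vector per chromosome with one entry per fixed-width bin; bin ``i``
covers ``[i*w, (i+1)*w)`` (the last bin of a chromosome may be truncated by the
chromosome end). Missing (masked) bins are carried as NaN and are only legal on
ratio-normalized tracks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import CoordinateError, DataError, StateError

#: Normalization stages a track can have passed through, in pipeline order.
STATES = (
    "raw",
    "counts_normalized",
    "smoothed",
    "scale_normalized",
    "averaged",
    "ratio_normalized",
)


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome names/lengths plus the fixed bin width used for coverage.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Length in bp of each chromosome, parallel to ``chrom_names``.
    bin_size
        Width of a coverage bin in bp (50 by default, matching the upstream
        windowing of aligned reads).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 50

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise DataError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise DataError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise DataError(f"bin_size must be > 0, got {self.bin_size}")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise DataError(f"chromosome {name} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length_of(chrom) / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)


@dataclass(frozen=True)
class TrackMeta:
    """Provenance of a signal track: sample identity and normalization state.

    ``state`` is the ordered tuple of normalization stages already applied
    (empty tuple = raw counts).
    """

    sample_id: str = ""
    antibody: str = ""
    condition: str = ""
    state: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for s in self.state:
            if s not in STATES:
                raise StateError(f"unknown normalization state {s!r}")

    def with_stage(self, stage: str) -> "TrackMeta":
        return replace(self, state=self.state + (stage,))


class BinnedTrack:
    """Fixed-width binned genome signal: one float vector per chromosome."""

    def __init__(
        self,
        assembly: GenomeAssembly,
        values: dict[str, np.ndarray],
        meta: TrackMeta | None = None,
    ) -> None:
        self.assembly = assembly
        self.meta = meta or TrackMeta()
        self.values: dict[str, np.ndarray] = {}
        if set(values) != set(assembly.chrom_names):
            missing = set(assembly.chrom_names) - set(values)
            extra = set(values) - set(assembly.chrom_names)
            raise DataError(
                f"track chromosomes do not match assembly (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        for chrom in assembly.chrom_names:
            v = np.asarray(values[chrom], dtype=np.float64)
            if v.ndim != 1 or v.size != assembly.n_bins(chrom):
                raise DataError(
                    f"{chrom}: expected {assembly.n_bins(chrom)} bins, got shape {v.shape}"
                )
            self.values[chrom] = v
        self._validate_values()

    def _validate_values(self) -> None:
        ratio = self.is_ratio_normalized
        for chrom, v in self.values.items():
            if np.isinf(v).any():
                raise DataError(f"{chrom}: non-finite (inf) values")
            if np.isnan(v).any() and not ratio:
                raise StateError(
                    f"{chrom}: masked (NaN) bins are only allowed on ratio-normalized tracks"
                )
            if not ratio and (v < 0).any():
                raise DataError(f"{chrom}: negative values on a non-ratio track")

    # -- state ------------------------------------------------------------
    @property
    def state(self) -> tuple[str, ...]:
        return self.meta.state

    def has_stage(self, stage: str) -> bool:
        return stage in self.meta.state

    @property
    def is_ratio_normalized(self) -> bool:
        return "ratio_normalized" in self.meta.state

    def require_stage(self, stage: str, op: str) -> None:
        if not self.has_stage(stage):
            raise StateError(
                f"{op}: track {self.meta.sample_id!r} must be {stage} "
                f"(state={list(self.meta.state)})"
            )

    # -- views ------------------------------------------------------------
    def flatten(self) -> np.ndarray:
        """All bin values concatenated in assembly chromosome order."""
        return np.concatenate([self.values[c] for c in self.assembly.chrom_names])

    @property
    def total(self) -> float:
        return float(np.nansum(self.flatten()))

    def mask(self) -> np.ndarray:
        """Boolean vector (flattened): True where the bin is masked."""
        return np.isnan(self.flatten())

    def with_values(
        self, values: dict[str, np.ndarray], stage: str | None = None
    ) -> "BinnedTrack":
        """New track with replaced values, optionally recording one more stage."""
        meta = self.meta.with_stage(stage) if stage else self.meta
        return BinnedTrack(self.assembly, values, meta)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.assembly, {c: v.copy() for c, v in self.values.items()}, self.meta
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BinnedTrack({self.meta.sample_id!r}, {len(self.values)} chromosomes, "
            f"{self.assembly.total_bins} bins, state={list(self.meta.state)})"
        )


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval with optional strand, category label and score."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    category: str | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise DataError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class LocusSet:
    """Named collection of genomic intervals (origins, tRNAs, hyperChIPable...).

    ``categories`` optionally declares the allowed vocabulary of per-interval
    category labels (e.g. confirmed/likely/dubious for replication origins).
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.categories is not None:
            vocab = set(self.categories)
            for iv in self.intervals:
                if iv.category is not None and iv.category not in vocab:
                    raise DataError(
                        f"{self.name}: category {iv.category!r} not in declared "
                        f"vocabulary {sorted(vocab)}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def bin_overlap_mask(self, assembly: GenomeAssembly) -> np.ndarray:
        """Flattened boolean vector: True for bins with >=1 bp overlap."""
        per_chrom = {
            c: np.zeros(assembly.n_bins(c), dtype=bool) for c in assembly.chrom_names
        }
        w = assembly.bin_size
        for iv in self.intervals:
            if iv.chrom not in per_chrom:
                raise CoordinateError(
                    f"{self.name}: interval on unknown chromosome {iv.chrom!r}"
                )
            n = per_chrom[iv.chrom].size
            lo = iv.start // w
            hi = min(math.ceil(iv.end / w), n)
            per_chrom[iv.chrom][lo:hi] = True
        return np.concatenate([per_chrom[c] for c in assembly.chrom_names])


@dataclass(frozen=True)
class Peak:
    """A called peak; summit is an offset in bp from ``start``."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    q_value: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(f"invalid peak {self.chrom}:{self.start}-{self.end}")
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise DataError(f"q-value {self.q_value} outside [0, 1]")

    @property
    def summit_pos(self) -> int:
        return self.start + self.summit


@dataclass
class PeakSet:
    """Called peaks from an external caller (MACS narrowPeak) or the naive caller."""

    peaks: list[Peak] = field(default_factory=list)
    source: str = "external-caller"

    def __post_init__(self) -> None:
        if self.source not in ("external-caller", "naive"):
            raise DataError(f"unknown peak source {self.source!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def to_locus_set(self, name: str = "peaks") -> LocusSet:
        return LocusSet(
            name=name,
            intervals=[
                GenomicInterval(p.chrom, p.start, p.end, score=p.score, name=p.name)
                for p in self.peaks
            ],
        )


def constant_track(
    assembly: GenomeAssembly, value: float, meta: TrackMeta | None = None
) -> BinnedTrack:
    """Convenience constructor: every bin set to ``value``."""
    return BinnedTrack(
        assembly,
        {c: np.full(assembly.n_bins(c), float(value)) for c in assembly.chrom_names},
        meta,
    )
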