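"""Readers/writers for the text formats the pipeline touches.

Supported dialects: two-column chrom-sizes TSV, 4-column binned coverage
(chrom/start/end/value at the assembly bin width), BED3/BED4/BED6 locus sets
(4th column read as a category label, 6-column files as name/score/strand),
ENCODE 10-column narrowPeak, and bedGraph output. All coordinates 0-based
half-open.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np

from .errors import CoordinateError, FormatError
from .genome import (
    BinnedTrack,
    GenomeAssembly,
    GenomicInterval,
    LocusSet,
    Peak,
    PeakSet,
    TrackMeta,
)

logger = logging.getLogger(__name__)


def _data_lines(path: str | Path):
    """Yield (line_number, fields) skipping blanks, comments and track lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def read_chrom_sizes(path: str | Path, bin_size: int = 50) -> GenomeAssembly:
    """Read a two-column <chrom>\\t<length> table into a GenomeAssembly."""
    names: list[str] = []
    lengths: list[int] = []
    for lineno, f in _data_lines(path):
        if len(f) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(f)}")
        try:
            length = int(f[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer length {f[1]!r}") from None
        names.append(f[0])
        lengths.append(length)
    return GenomeAssembly(tuple(names), tuple(lengths), bin_size=bin_size)


def read_coverage_bins(
    path: str | Path, assembly: GenomeAssembly, meta: TrackMeta | None = None
) -> BinnedTrack:
    """Read a 4-column binned coverage file into a BinnedTrack.

    Records must sit on the assembly's bin grid with width ``bin_size`` (the
    final bin of a chromosome may be truncated by the chromosome end). Bins
    absent from the file are set to 0; records on chromosomes not in the
    assembly are rejected rather than dropped, to catch genome-build
    mismatches early.
    """
    w = assembly.bin_size
    lengths = assembly.lengths
    values = {
        c: np.zeros(assembly.n_bins(c), dtype=np.float64) for c in assembly.chrom_names
    }
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(f)}")
        chrom = f[0]
        if chrom not in lengths:
            raise CoordinateError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start, end, value = int(f[1]), int(f[2]), float(f[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinates/value") from None
        if start >= lengths[chrom]:
            raise CoordinateError(
                f"{path}:{lineno}: start {start} beyond end of {chrom} ({lengths[chrom]} bp)"
            )
        if start % w != 0:
            raise FormatError(
                f"{path}:{lineno}: start {start} not on the {w} bp bin grid"
            )
        expected_end = min(start + w, lengths[chrom])
        if end != expected_end:
            raise FormatError(
                f"{path}:{lineno}: record width {end - start} != bin size {w}"
            )
        if not math.isfinite(value):
            raise FormatError(f"{path}:{lineno}: non-finite value")
        values[chrom][start // w] = value
    return BinnedTrack(assembly, values, meta)


def read_locus_set(
    path: str | Path, assembly: GenomeAssembly, name: str | None = None
) -> LocusSet:
    """Read BED3/BED4/BED6 into a LocusSet.

    The 4th column (BED "name") is stored as the interval's category; the 5th
    as a numeric score when parseable; the 6th as strand. Intervals running
    past the chromosome end are clipped with a logged warning; zero-length or
    inverted intervals are a parse error.
    """
    label = name if name is not None else Path(path).stem
    lengths = assembly.lengths
    intervals: list[GenomicInterval] = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(f)}")
        chrom = f[0]
        if chrom not in lengths:
            raise CoordinateError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise FormatError(
                f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
            )
        if start >= lengths[chrom]:
            raise CoordinateError(
                f"{path}:{lineno}: interval starts beyond end of {chrom}"
            )
        if end > lengths[chrom]:
            logger.warning(
                "%s:%d: interval %s:%d-%d clipped to chromosome end (%d bp)",
                path, lineno, chrom, start, end, lengths[chrom],
            )
            end = lengths[chrom]
        category = f[3] if len(f) >= 4 else None
        score: float | None = None
        if len(f) >= 5:
            try:
                score = float(f[4])
            except ValueError:
                score = None
        strand = f[5] if len(f) >= 6 else None
        if strand not in (None, "+", "-", "."):
            raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
        intervals.append(
            GenomicInterval(chrom, start, end, strand=strand, category=category,
                            score=score, name=category)
        )
    return LocusSet(name=label, intervals=intervals)


def read_narrowpeak(path: str | Path) -> PeakSet:
    """Read ENCODE 10-column narrowPeak output (e.g. from MACS).

    Column 9 is -log10(q); -1 (unavailable) maps to a missing q-value.
    Column 10 is the summit offset from start; -1 maps to the interval
    midpoint.
    """
    peaks: list[Peak] = []
    for lineno, f in _data_lines(path):
        if len(f) != 10:
            raise FormatError(
                f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(f)}"
            )
        chrom, name = f[0], f[3]
        try:
            start, end = int(f[1]), int(f[2])
            signal, neglog_q = float(f[6]), float(f[8])
            summit = int(f[9])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed numeric field") from None
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        q_value = None if neglog_q < 0 else 10.0 ** (-neglog_q)
        if summit < 0:
            summit = (end - start) // 2
        peaks.append(
            Peak(chrom, start, end, summit=summit, score=signal,
                 q_value=q_value, name=name)
        )
    return PeakSet(peaks=peaks, source="external-caller")


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write a track as bedGraph, one record per unmasked bin.

    Masked (NaN) bins are omitted entirely — never written as "nan" — so a
    round trip through :func:`read_coverage_bins` reproduces the unmasked
    values exactly.
    """
    asm = track.assembly
    w = asm.bin_size
    with open(path, "w") as fh:
        for chrom in asm.chrom_names:
            length = asm.length_of(chrom)
            v = track.values[chrom]
            for i in np.flatnonzero(~np.isnan(v)):
                start = int(i) * w
                fh.write(f"{chrom}\t{start}\t{min(start + w, length)}\t{v[i]:.17g}\n")


def write_locus_set(loci: LocusSet, path: str | Path) -> None:
    """Write a LocusSet as BED (6 columns when strand/score present)."""
    with open(path, "w") as fh:
        for iv in loci.intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.category is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.category if iv.category is not None else ".")
            if iv.score is not None or iv.strand is not None:
                cols.append(f"{iv.score:.17g}" if iv.score is not None else "0")
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")
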