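"""Peak calling: a naive threshold caller plus the pinned external MACS interface.

The naive caller exists so that synthetic end-to-end tests (and quick looks at
RN output) need no external binary: it reports maximal runs of unmasked bins
at or above a signal threshold, optionally bridging short sub-threshold gaps,
and drops runs below a minimum width. It makes no statistical claim — for
real data the documented MACS invocation is the peak caller of record.
"""
from __future__ import annotations

import logging
import shutil
import subprocess
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .errors import ChipRnError, ConfigError, StateError
from .genome import BinnedTrack, Peak, PeakSet

logger = logging.getLogger(__name__)

#: Pinned MACS2 settings for yeast ChIP-seq: effective genome size 1.24e7,
#: no shifting model, 100 bp extension, q-value cutoff 0.05.
MACS_GENOME_SIZE = 1.24e7
MACS_EXTSIZE = 100
MACS_QVALUE = 5e-2


def naive_call_peaks(
    track: BinnedTrack,
    threshold: float,
    min_width: int = 100,
    merge_gap: int = 0,
) -> PeakSet:
    """Call peaks as maximal runs of bins with signal >= ``threshold``.

    Masked bins break runs (no enrichment claim without control coverage).
    Runs separated by an unmasked sub-threshold gap shorter than
    ``merge_gap`` bp are merged; merged runs narrower than ``min_width`` bp
    are discarded. The summit is the leftmost maximum bin of the run
    (offset to the bin center); the score is the run maximum.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be > 0, got {threshold}")
    if not (track.has_stage("ratio_normalized") or track.has_stage("scale_normalized")):
        raise StateError(
            "naive_call_peaks expects a scale- or ratio-normalized track "
            "(threshold is in background units)"
        )
    w = track.assembly.bin_size
    peaks: list[Peak] = []
    for chrom in track.assembly.chrom_names:
        v = track.values[chrom]
        above = (~np.isnan(v)) & (v >= threshold)
        masked = np.isnan(v)
        # maximal runs of above-threshold bins
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        runs = list(zip(edges[::2], edges[1::2]))  # [start_bin, end_bin)
        # merge across short unmasked sub-threshold gaps
        merged: list[list[int]] = []
        for s, e in runs:
            if merged:
                gap_lo, gap_hi = merged[-1][1], s
                gap_bp = (gap_hi - gap_lo) * w
                if gap_bp < merge_gap and not masked[gap_lo:gap_hi].any():
                    merged[-1][1] = e
                    continue
            merged.append([s, e])
        for s, e in merged:
            if (e - s) * w < min_width:
                continue
            seg = v[s:e]
            with np.errstate(invalid="ignore"):
                summit_bin = int(np.nanargmax(seg))
            score = float(seg[summit_bin])
            length = track.assembly.length_of(chrom)
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=s * w,
                    end=min(e * w, length),
                    summit=summit_bin * w + w // 2,
                    score=score,
                )
            )
    return PeakSet(peaks=peaks, source="naive")


def find_local_maxima(
    track: BinnedTrack,
    chrom: str,
    start: int,
    end: int,
    prominence: float = 0.5,
    min_height: float = 0.0,
) -> list[tuple[int, float]]:
    """Resolved local maxima of the signal within a region.

    Returns (position bp at bin center, value) for local maxima within
    ``[start, end)`` whose topographic prominence is at least ``prominence``
    signal units — small noise wiggles on a smoothed plateau do not count as
    separate peaks. Used e.g. to verify that two nearby binding arrays stay
    resolved after smoothing.
    """
    w = track.assembly.bin_size
    v = track.values[chrom]
    lo, hi = max(start // w, 0), min(-(-end // w), v.size)
    seg = v[lo:hi]
    idx, _ = find_peaks(seg, prominence=prominence, height=min_height or None)
    return [(int((lo + i) * w + w // 2), float(seg[i])) for i in idx]


def peak_centroid(
    track: BinnedTrack,
    chrom: str,
    center: int,
    radius: int = 500,
    baseline: float = 1.0,
) -> float:
    """Signal-weighted center of mass of above-baseline signal near ``center``.

    A flat-topped (smoothed) peak has a noisy argmax but a stable centroid,
    so this is the preferred position estimator for resolved peaks. Returns
    the position in bp; falls back to ``center`` if nothing exceeds the
    baseline.
    """
    w = track.assembly.bin_size
    v = track.values[chrom]
    lo = max((center - radius) // w, 0)
    hi = min(-(-(center + radius) // w), v.size)
    seg = v[lo:hi]
    weights = np.clip(np.nan_to_num(seg, nan=baseline) - baseline, 0, None)
    if weights.sum() <= 0:
        return float(center)
    pos = (np.arange(lo, hi) * w) + w / 2
    return float(np.average(pos, weights=weights))


def macs_command(
    treatment: str | Path,
    control: str | Path | None = None,
    name: str = "sample",
    outdir: str | Path = ".",
) -> list[str]:
    """The pinned MACS2 command line for yeast ChIP-seq peak calling."""
    cmd = [
        "macs2", "callpeak",
        "-t", str(treatment),
        "-n", name,
        "--outdir", str(outdir),
        "-g", f"{MACS_GENOME_SIZE:g}",
        "--nomodel",
        "--extsize", str(MACS_EXTSIZE),
        "-q", f"{MACS_QVALUE:g}",
    ]
    if control is not None:
        cmd += ["-c", str(control)]
    return cmd


def run_macs(
    treatment: str | Path,
    control: str | Path | None = None,
    name: str = "sample",
    outdir: str | Path = ".",
) -> Path:
    """Run MACS2 with the pinned settings; returns the narrowPeak path.

    Shells out only when the ``macs2`` executable is on PATH; otherwise
    raises with the exact command to run elsewhere.
    """
    cmd = macs_command(treatment, control, name, outdir)
    if shutil.which("macs2") is None:
        raise ChipRnError(
            "macs2 executable not found on PATH; run this command where MACS2 "
            f"(2.2.x) is installed:\n  {' '.join(cmd)}"
        )
    logger.info("running: %s", " ".join(cmd))
    subprocess.run(cmd, check=True)
    return Path(outdir) / f"{name}_peaks.narrowPeak"
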