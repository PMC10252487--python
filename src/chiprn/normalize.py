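"""Ratio normalization (RN) of ChIP-seq coverage by a decoy-control track.

ChIP-seq signal contains substantial non-specific enrichment ("hyperChIPable"
loci) that survives the usual input or untagged controls because it is tied to
the immunoprecipitation itself. The remedy implemented here: perform a
parallel IP in a strain expressing only an epitope-tagged decoy protein (or a
DNA-binding mutant of the target), process both tracks identically, and divide
the experimental track by the control track bin-by-bin. Shared non-specific
enrichment cancels to ~1 while target-specific binding is retained.

Pipeline order (fixed contract):

    counts_normalize -> smooth_track -> scale_normalize -> average_replicates
    -> ratio_normalize

Scale normalization divides by a low percentile of the genome-wide bin
distribution (default 20th) taken to represent unenriched background, so after
this stage "background" is 1.0 in every sample and the RN ratio is directly
interpretable as fold enrichment over control.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError, DegenerateInputError, StateError
from .genome import BinnedTrack, GenomeAssembly, TrackMeta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RNConfig:
    """Parameters of the RN pipeline.

    smooth_window
        Width in bp of the centered moving-average window (default 500).
        Converted to an odd bin count; see :func:`smooth_track`.
    background_percentile
        Percentile (0-100, exclusive) of all genome bins used as the
        background scaling value (default 20).
    pseudocount
        Added to numerator and denominator of the ratio; guards against
        division blow-up at near-zero control bins (default 0.01, in
        background units where background = 1.0).
    control_floor
        Minimum control value, as a fraction of the control background level
        1.0, below which the ratio is considered unsupported and the bin is
        masked (default 0.1).
    target_total
        Genome-wide total each replicate is scaled to in counts
        normalization. None (default) = mean of the replicate totals.
    """

    smooth_window: int = 500
    background_percentile: float = 20.0
    pseudocount: float = 0.01
    control_floor: float = 0.1
    target_total: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.background_percentile < 100.0):
            raise ConfigError(
                f"background_percentile must be in (0, 100), got {self.background_percentile}"
            )
        if self.smooth_window <= 0:
            raise ConfigError(f"smooth_window must be > 0, got {self.smooth_window}")
        if self.pseudocount <= 0:
            raise ConfigError(f"pseudocount must be > 0, got {self.pseudocount}")
        if self.control_floor < 0:
            raise ConfigError(f"control_floor must be >= 0, got {self.control_floor}")


@dataclass
class ReplicateSet:
    """Replicate tracks of one sample: same assembly, same normalization state."""

    tracks: list[BinnedTrack]

    def __post_init__(self) -> None:
        if not self.tracks:
            raise DataError("ReplicateSet requires at least one track")
        asm = self.tracks[0].assembly
        state = self.tracks[0].state
        for t in self.tracks[1:]:
            if t.assembly != asm:
                raise DataError("replicates are on different assemblies")
            if t.state != state:
                raise StateError(
                    f"replicates in mixed normalization states: "
                    f"{list(state)} vs {list(t.state)}"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def assembly(self) -> GenomeAssembly:
        return self.tracks[0].assembly

    @property
    def state(self) -> tuple[str, ...]:
        return self.tracks[0].state


def counts_normalize(
    reps: ReplicateSet, target_total: float | None = None
) -> ReplicateSet:
    """Scale each replicate so its genome-wide sum equals ``target_total``.

    With ``target_total=None`` the mean of the replicate totals is used, so
    the set's total signal is conserved. Per-track relative bin values are
    unchanged (pure rescaling).
    """
    totals = [t.total for t in reps]
    for t, tot in zip(reps, totals):
        if tot <= 0:
            raise DegenerateInputError(
                f"replicate {t.meta.sample_id!r} has zero total signal"
            )
    if target_total is None:
        target_total = float(np.mean(totals))
    if target_total <= 0:
        raise ConfigError(f"target_total must be > 0, got {target_total}")
    out = []
    for t, tot in zip(reps, totals):
        factor = target_total / tot
        logger.info(
            "counts_normalize: %s total=%.6g scale=%.6g", t.meta.sample_id, tot, factor
        )
        out.append(
            t.with_values(
                {c: v * factor for c, v in t.values.items()}, stage="counts_normalized"
            )
        )
    return ReplicateSet(out)


def _window_bins(window: int, bin_size: int) -> int:
    """Convert a bp window to an odd bin count (centered windows need odd k)."""
    if window < bin_size:
        raise ConfigError(
            f"smooth window {window} bp is smaller than the bin size {bin_size} bp"
        )
    k = max(1, round(window / bin_size))
    if k % 2 == 0:
        k += 1
        logger.info(
            "smooth_track: window %d bp = %d bins (even); widened to %d bins "
            "for a centered window", window, k - 1, k,
        )
    return k


def smooth_track(track: BinnedTrack, window: int) -> BinnedTrack:
    """Centered moving-average smoothing with shrink-to-available edges.

    Output bin ``i`` is the arithmetic mean of input bins
    ``[i - k//2, i + k//2]`` intersected with the chromosome, where ``k`` is
    the window converted to an odd bin count. No padding is used, so no
    signal is fabricated at chromosome ends (the window simply shrinks).
    """
    k = _window_bins(window, track.assembly.bin_size)
    h = k // 2
    out: dict[str, np.ndarray] = {}
    for chrom, v in track.values.items():
        n = v.size
        if k == 1 or n == 1:
            out[chrom] = v.copy()
            continue
        cum = np.concatenate(([0.0], np.cumsum(v)))
        idx = np.arange(n)
        lo = np.maximum(idx - h, 0)
        hi = np.minimum(idx + h + 1, n)
        out[chrom] = (cum[hi] - cum[lo]) / (hi - lo)
    return track.with_values(out, stage="smoothed")


def scale_normalize(track: BinnedTrack, percentile: float = 20.0) -> BinnedTrack:
    """Divide every bin by the given percentile of all genome bins.

    The percentile (linear interpolation between order statistics, computed
    over all bins including zeros) estimates the unenriched background level;
    after this stage the configured percentile of the track equals 1.0.
    """
    if not (0.0 < percentile < 100.0):
        raise ConfigError(f"percentile must be in (0, 100), got {percentile}")
    flat = track.flatten()
    background = float(np.percentile(flat, percentile))
    if background <= 0:
        raise DegenerateInputError(
            f"the {percentile:g}th percentile of {track.meta.sample_id!r} is "
            f"{background:g}; cannot scale-normalize (too many zero bins)"
        )
    logger.info(
        "scale_normalize: %s p%g=%.6g", track.meta.sample_id, percentile, background
    )
    return track.with_values(
        {c: v / background for c, v in track.values.items()}, stage="scale_normalized"
    )


def average_replicates(reps: ReplicateSet) -> BinnedTrack:
    """Per-bin arithmetic mean across replicates (order-invariant)."""
    first = reps.tracks[0]
    out = {
        c: np.mean([t.values[c] for t in reps.tracks], axis=0)
        for c in reps.assembly.chrom_names
    }
    ids = "+".join(t.meta.sample_id for t in reps.tracks if t.meta.sample_id)
    meta = replace(first.meta, sample_id=ids or first.meta.sample_id)
    return BinnedTrack(reps.assembly, out, meta.with_stage("averaged"))


def ratio_normalize(
    exp: BinnedTrack, ctrl: BinnedTrack, cfg: RNConfig | None = None
) -> BinnedTrack:
    """Divide the experimental track by the control track, bin by bin.

    ``RN(i) = (exp(i) + pseudocount) / (ctrl(i) + pseudocount)`` for bins
    where the control has adequate coverage (``ctrl(i) >= control_floor``,
    expressed as a fraction of the control's background level 1.0); bins
    below the floor are masked (NaN) — a ratio against essentially no control
    signal asserts nothing.
    """
    cfg = cfg or RNConfig()
    if exp.assembly != ctrl.assembly:
        raise DataError("ratio_normalize: experimental/control assembly mismatch")
    for t, which in ((exp, "experimental"), (ctrl, "control")):
        t.require_stage("scale_normalized", f"ratio_normalize ({which})")
        t.require_stage("averaged", f"ratio_normalize ({which})")
    pc = cfg.pseudocount
    out: dict[str, np.ndarray] = {}
    n_masked = 0
    for chrom in exp.assembly.chrom_names:
        e, c = exp.values[chrom], ctrl.values[chrom]
        ratio = (e + pc) / (c + pc)
        low = c < cfg.control_floor
        ratio[low] = np.nan
        n_masked += int(low.sum())
        out[chrom] = ratio
    if n_masked:
        logger.info(
            "ratio_normalize: masked %d bins with control < %.3g",
            n_masked, cfg.control_floor,
        )
    meta = replace(
        exp.meta,
        sample_id=f"{exp.meta.sample_id}/{ctrl.meta.sample_id}".strip("/"),
    )
    return BinnedTrack(exp.assembly, out, meta.with_stage("ratio_normalized"))


@dataclass
class PipelineResult:
    """RN output plus the per-sample intermediates and logged factors."""

    rn: BinnedTrack
    exp_avg: BinnedTrack
    ctrl_avg: BinnedTrack
    scale_factors: dict[str, float] = field(default_factory=dict)
    background_values: dict[str, float] = field(default_factory=dict)
    config: RNConfig = field(default_factory=RNConfig)


def _normalize_side(reps: ReplicateSet, cfg: RNConfig, result: PipelineResult) -> BinnedTrack:
    totals = [t.total for t in reps]
    normed = counts_normalize(reps, cfg.target_total)
    for t, tot in zip(normed, totals):
        result.scale_factors[t.meta.sample_id] = t.total / tot if tot else float("nan")
    smoothed = ReplicateSet([smooth_track(t, cfg.smooth_window) for t in normed])
    scaled = []
    for t in smoothed:
        background = float(np.percentile(t.flatten(), cfg.background_percentile))
        result.background_values[t.meta.sample_id] = background
        scaled.append(scale_normalize(t, cfg.background_percentile))
    return average_replicates(ReplicateSet(scaled))


def run_rn_pipeline(
    exp_reps: ReplicateSet, ctrl_reps: ReplicateSet, cfg: RNConfig | None = None
) -> PipelineResult:
    """Full RN pipeline on raw replicate sets.

    Each side is counts-normalized, smoothed, scale-normalized and averaged;
    the experimental average is then divided by the control average. Returns
    the RN track together with both averaged intermediates (the experimental
    average is the "uncontrolled" track used for before/after comparisons)
    and the per-sample scale factors / background values.
    """
    cfg = cfg or RNConfig()
    for reps, which in ((exp_reps, "experimental"), (ctrl_reps, "control")):
        if reps.state != ():
            raise StateError(
                f"run_rn_pipeline expects raw {which} replicates "
                f"(state={list(reps.state)})"
            )
    if exp_reps.assembly != ctrl_reps.assembly:
        raise DataError("experimental/control assembly mismatch")
    result = PipelineResult(rn=None, exp_avg=None, ctrl_avg=None, config=cfg)  # type: ignore[arg-type]
    result.exp_avg = _normalize_side(exp_reps, cfg, result)
    result.ctrl_avg = _normalize_side(ctrl_reps, cfg, result)
    result.rn = ratio_normalize(result.exp_avg, result.ctrl_avg, cfg)
    return result
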