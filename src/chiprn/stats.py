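"""Distribution summaries and enrichment statistics for binned ChIP signal.

The central test mirrors the evaluation used for hyperChIPable / tRNA /
origin locus sets: aggregate the track to coarse bins (default 500 bp),
split the genome into bins overlapping the locus set versus all remaining
bins, and compare the two distributions with a two-sided Mann-Whitney U test.
For small problems the exact permutation null is enumerated (correct under
ties); otherwise the normal approximation with tie correction is used.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError, DegenerateInputError
from .genome import BinnedTrack, GenomeAssembly, LocusSet
from .normalize import ReplicateSet

logger = logging.getLogger(__name__)

# Exact Mann-Whitney enumeration is used when BOTH hold; beyond either bound
# the normal approximation is statistically safe anyway.
EXACT_MAX_PRODUCT = 10_000
EXACT_MAX_COMBINATIONS = 500_000


# ---------------------------------------------------------------------------
# aggregation helpers
# ---------------------------------------------------------------------------

def aggregate_bins(track: BinnedTrack, agg_bin: int) -> tuple[np.ndarray, np.ndarray]:
    """Re-bin a track to ``agg_bin`` bp by averaging constituent bins.

    Returns ``(values, locus_index)`` where ``values`` is the flattened
    aggregated signal (NaN-aware mean; bins that are entirely masked stay
    NaN) and ``locus_index`` gives, per aggregated bin, ``(chrom_index,
    start_bp)``-encoded position as a structured lookup used by overlap
    computations. The trailing aggregated bin of a chromosome may cover fewer
    source bins.
    """
    w = track.assembly.bin_size
    if agg_bin % w != 0 or agg_bin <= 0:
        raise ConfigError(
            f"agg_bin {agg_bin} must be a positive multiple of bin size {w}"
        )
    step = agg_bin // w
    values: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    chroms: list[np.ndarray] = []
    for ci, chrom in enumerate(track.assembly.chrom_names):
        v = track.values[chrom]
        n_out = math.ceil(v.size / step)
        if step == 1:
            agg = v.copy()
        else:
            padded = np.full(n_out * step, np.nan)
            padded[: v.size] = v
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                agg = np.nanmean(padded.reshape(n_out, step), axis=1)
        values.append(agg)
        starts.append(np.arange(n_out) * agg_bin)
        chroms.append(np.full(n_out, ci))
    return np.concatenate(values), np.rec.fromarrays(
        [np.concatenate(chroms), np.concatenate(starts)], names=("chrom", "start")
    )


def _overlap_mask_at(
    assembly: GenomeAssembly, loci: LocusSet, agg_bin: int, index: np.ndarray
) -> np.ndarray:
    """True for aggregated bins with >=1 bp overlap with any interval."""
    mask = np.zeros(index.size, dtype=bool)
    name_to_ci = {c: i for i, c in enumerate(assembly.chrom_names)}
    lengths = assembly.lengths
    for iv in loci:
        if iv.chrom not in name_to_ci:
            raise DataError(f"{loci.name}: unknown chromosome {iv.chrom!r}")
        ci = name_to_ci[iv.chrom]
        sel = (
            (index.chrom == ci)
            & (index.start < min(iv.end, lengths[iv.chrom]))
            & (index.start + agg_bin > iv.start)
        )
        mask |= sel
    return mask


# ---------------------------------------------------------------------------
# distribution / outlier summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSummary:
    """Tukey box-plot summary of an aggregated signal distribution.

    Outliers follow the whisker convention: values beyond Q1 - 1.5*IQR or
    Q3 + 1.5*IQR. Positive (high) outliers are what non-specific ChIP
    enrichment produces, so they are counted separately.
    """

    q1: float
    q2: float
    q3: float
    lower_fence: float
    upper_fence: float
    n_bins: int
    outlier_count_high: int
    outlier_count_low: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def outlier_fraction(self) -> float:
        return (self.outlier_count_high + self.outlier_count_low) / self.n_bins

    @property
    def outlier_fraction_high(self) -> float:
        return self.outlier_count_high / self.n_bins


def distribution_summary(track: BinnedTrack, agg_bin: int = 500) -> DistributionSummary:
    """Tukey summary of the genome-wide signal distribution at ``agg_bin`` bp."""
    values, _ = aggregate_bins(track, agg_bin)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise DegenerateInputError("distribution_summary: no unmasked bins")
    q1, q2, q3 = (float(q) for q in np.percentile(values, [25, 50, 75]))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return DistributionSummary(
        q1=q1, q2=q2, q3=q3, lower_fence=lo, upper_fence=hi,
        n_bins=int(values.size),
        outlier_count_high=int((values > hi).sum()),
        outlier_count_low=int((values < lo).sum()),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney locus-set enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentTestResult:
    """Outcome of a two-sided Mann-Whitney test of locus bins vs background."""

    set_name: str
    u_statistic: float
    p_value: float
    direction: str  # "over" | "under" | "none"
    n_set: int
    n_background: int
    method: str  # "exact" | "asymptotic"
    median_set: float
    median_background: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_statistic <= self.n_set * self.n_background):
            raise DataError("U outside [0, n_set * n_background]")
        if not (0.0 < self.p_value <= 1.0):
            raise DataError(f"p-value {self.p_value} outside (0, 1]")

    @property
    def significant(self) -> bool:
        """Significance at the conventional p < 0.01 (**) threshold."""
        return self.p_value < 0.01


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x via midranks (valid under ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _exact_two_sided_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all C(n, n1) group assignments.

    Two-sided defined symmetrically around the null mean n1*n2/2:
    p = Pr(|U - mu| >= |U_obs - mu|).
    """
    n = pooled.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        # 1e-12 guard: midranks are halves, U deviations are exact halves too
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_from_groups(
    set_values: np.ndarray, background_values: np.ndarray, set_name: str = "set"
) -> EnrichmentTestResult:
    """Two-sided Mann-Whitney U of two value groups (exact when small)."""
    x = np.asarray(set_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0:
        raise DegenerateInputError(f"locus set {set_name!r}: no overlapping bins")
    if y.size == 0:
        raise DegenerateInputError(f"locus set {set_name!r}: empty background")
    u = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    use_exact = (
        n1 * n2 <= EXACT_MAX_PRODUCT
        and math.comb(n1 + n2, n1) <= EXACT_MAX_COMBINATIONS
    )
    if use_exact:
        method = "exact"
        p = _exact_two_sided_p(np.concatenate([x, y]), n1, u)
    else:
        method = "asymptotic"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    med_x, med_y = float(np.median(x)), float(np.median(y))
    direction = "over" if med_x > med_y else "under" if med_x < med_y else "none"
    logger.debug(
        "mann_whitney[%s]: U=%.1f p=%.3g (%s, n=%d/%d)", set_name, u, p, method, n1, n2
    )
    return EnrichmentTestResult(
        set_name=set_name, u_statistic=u, p_value=p, direction=direction,
        n_set=n1, n_background=n2, method=method,
        median_set=med_x, median_background=med_y,
    )


def mann_whitney_enrichment(
    track: BinnedTrack, loci: LocusSet, agg_bin: int = 500
) -> EnrichmentTestResult:
    """Rank-test a locus set's signal against the rest of the genome.

    The track is aggregated to ``agg_bin`` bp; a bin belongs to the locus
    group if >=1 bp of it intersects any interval of the set, and the
    background is every remaining (disjoint) genome bin. Direction is read
    off the group medians.
    """
    values, index = aggregate_bins(track, agg_bin)
    mask = _overlap_mask_at(track.assembly, loci, agg_bin, index)
    keep = ~np.isnan(values)
    x = values[mask & keep]
    y = values[~mask & keep]
    if x.size == 0:
        raise DegenerateInputError(
            f"locus set {loci.name!r}: no aggregated bin overlaps it"
        )
    return mann_whitney_from_groups(x, y, set_name=loci.name)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def replicate_correlation(reps: ReplicateSet) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-bin values between replicates.

    Zero-variance replicates yield undefined coefficients, reported as NaN
    with a warning. Returned as a labelled square DataFrame (diagonal 1).
    """
    if len(reps) < 2:
        raise DataError("replicate_correlation requires >= 2 replicates")
    names = [
        t.meta.sample_id or f"rep{i + 1}" for i, t in enumerate(reps.tracks)
    ]
    data = np.vstack([t.flatten() for t in reps.tracks])
    k = data.shape[0]
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data[i], data[j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                warnings.warn(
                    f"zero-variance replicate among ({names[i]}, {names[j]}); "
                    "correlation undefined", RuntimeWarning, stacklevel=2,
                )
                r = np.nan
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation outcome (NaN rho = undefined, e.g. constant input)."""

    rho: float
    p_value: float
    n: int


def signal_efficiency_correlation(
    track: BinnedTrack, origins: LocusSet, flank: int = 500
) -> CorrelationResult:
    """Spearman correlation of per-origin ChIP signal vs origin efficiency.

    Each origin's signal is summarized as the maximum unmasked track value
    within ``flank`` bp of the origin midpoint (peak height). Origins must
    carry numeric efficiency scores; unscored origins are skipped.
    """
    scored = [iv for iv in origins if iv.score is not None]
    if len(scored) < 3:
        raise DegenerateInputError(
            f"signal_efficiency_correlation: need >= 3 scored origins, "
            f"got {len(scored)}"
        )
    w = track.assembly.bin_size
    signals, effs = [], []
    for iv in scored:
        v = track.values[iv.chrom]
        mid = iv.midpoint
        lo = max((mid - flank) // w, 0)
        hi = min(math.ceil((mid + flank) / w), v.size)
        window = v[lo:hi]
        window = window[~np.isnan(window)]
        if window.size == 0:
            continue
        signals.append(float(window.max()))
        effs.append(float(iv.score))
    if len(signals) < 3:
        raise DegenerateInputError(
            "signal_efficiency_correlation: fewer than 3 origins with unmasked signal"
        )
    if np.std(effs) == 0 or np.std(signals) == 0:
        warnings.warn(
            "constant efficiencies or signals; Spearman rho undefined",
            RuntimeWarning, stacklevel=2,
        )
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=len(signals))
    rho, p = sps.spearmanr(signals, effs)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(signals))
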