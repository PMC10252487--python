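"""Ground-truth synthetic ChIP-seq coverage emulating the decoy-control design.

The generator models four strain/IP conditions:

``untagged``
    IP in a strain with no tagged protein: background plus non-specific
    ("hyperChIPable"-like) artifact enrichment. The artifact factors are an
    independent, reduced draw — untagged IPs enrich different sequences than
    tagged-decoy IPs, which is exactly why untagged strains make poor
    subtraction controls.
``decoy_only``
    IP of the epitope-tagged decoy protein alone: the same artifact loci as
    the experimental IP (shared factors) plus the decoy's operator-array
    control peaks, but no true binding sites.
``target_decoy``
    The experimental strain: shared artifacts, true binding sites, and the
    operator-array control peaks.
``dbm``
    A DNA-binding-mutant control: biochemically matched, shared artifacts,
    no sequence-specific binding.

Coverage per 50 bp bin is negative-binomial with mean ``background_mean``
times the product of the enrichment factors of all locus classes active at
that bin for the condition (rectangular loci; the smoothing stage of the RN
pipeline supplies realistic peak shape). Dispersion 0 degenerates to Poisson.
Every random draw is governed by explicit seeds.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genome import (
    BinnedTrack,
    GenomeAssembly,
    GenomicInterval,
    LocusSet,
    TrackMeta,
)
from .normalize import ReplicateSet
from .peaks import naive_call_peaks
from .stats import mann_whitney_from_groups

logger = logging.getLogger(__name__)

CONDITIONS = ("untagged", "decoy_only", "target_decoy", "dbm")
LOCUS_CLASSES = ("artifact", "artifact_untagged", "true_site", "control_peak")

#: Which locus classes contribute enrichment in each condition.
DEFAULT_CONDITION_MATRIX: dict[str, tuple[str, ...]] = {
    "untagged": ("artifact_untagged",),
    "decoy_only": ("artifact", "control_peak"),
    "target_decoy": ("artifact", "true_site", "control_peak"),
    "dbm": ("artifact",),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic genome and coverage model.

    Defaults: a 4 x 200 kb genome at 50 bp bins; 30 artifact loci with
    enrichment factors 3-8 shared across tagged-strain IPs (and independent
    reduced factors 1.5-3 in the untagged IP); 20 true binding sites with
    factors 4-12 present only in the experimental condition; two operator
    arrays 1.6 kb apart serving as decoy-strain control peaks; NB background
    with mean 20 reads per bin and dispersion 0.1.
    """

    n_chroms: int = 4
    chrom_length: int = 200_000
    bin_size: int = 50

    n_artifact: int = 30
    artifact_factor_range: tuple[float, float] = (3.0, 8.0)
    artifact_width_range: tuple[int, int] = (600, 1500)
    untagged_factor_range: tuple[float, float] = (1.5, 3.0)

    n_true_sites: int = 20
    true_factor_range: tuple[float, float] = (4.0, 12.0)
    true_width_range: tuple[int, int] = (500, 1000)

    control_array_widths: tuple[int, int] = (200, 100)
    control_array_factors: tuple[float, float] = (12.0, 8.0)
    control_array_separation: int = 1600  # midpoint-to-midpoint, bp

    background_mean: float = 20.0
    dispersion: float = 0.1

    #: dead zone kept free at chromosome ends and between placed loci, so
    #: smoothing never bleeds one locus class into another
    placement_margin: int = 3000

    condition_matrix: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_MATRIX)
    )

    def __post_init__(self) -> None:
        if self.n_chroms <= 0 or self.chrom_length <= 0 or self.bin_size <= 0:
            raise ConfigError("assembly dimensions must be positive")
        for lo, hi in (
            self.artifact_factor_range,
            self.untagged_factor_range,
            self.true_factor_range,
        ):
            if lo < 1.0 or hi < lo:
                raise ConfigError(f"enrichment factor range ({lo}, {hi}) invalid: factors must be >= 1")
        if any(f < 1.0 for f in self.control_array_factors):
            raise ConfigError("control array factors must be >= 1")
        if self.background_mean <= 0:
            raise ConfigError("background_mean must be > 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        missing = set(CONDITIONS) - set(self.condition_matrix)
        if missing:
            raise ConfigError(f"condition_matrix missing conditions: {sorted(missing)}")
        for cond, classes in self.condition_matrix.items():
            unknown = set(classes) - set(LOCUS_CLASSES)
            if unknown:
                raise ConfigError(f"condition {cond!r}: unknown locus classes {sorted(unknown)}")

    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(
            tuple(f"chr{i + 1}" for i in range(self.n_chroms)),
            tuple([self.chrom_length] * self.n_chroms),
            bin_size=self.bin_size,
        )


@dataclass
class SimulationTruth:
    """Ground-truth manifest: where every locus class sits and how strong it is.

    Per-locus enrichment factors are carried as interval scores. For the
    artifact loci, ``untagged_factors`` holds the independent (reduced)
    factors used in the untagged condition, parallel to
    ``artifact_loci.intervals``.
    """

    config: SimulationConfig
    seed: int
    assembly: GenomeAssembly
    artifact_loci: LocusSet
    true_sites: LocusSet
    control_peak_loci: LocusSet
    untagged_factors: np.ndarray

    def locus_sets(self) -> dict[str, LocusSet]:
        return {
            "artifact": self.artifact_loci,
            "true_site": self.true_sites,
            "control_peak": self.control_peak_loci,
        }

    def enrichment_field(self, condition: str) -> dict[str, np.ndarray]:
        """Multiplicative enrichment per bin (1.0 = pure background)."""
        if condition not in self.config.condition_matrix:
            raise ConfigError(f"unknown condition {condition!r}")
        asm = self.assembly
        w = asm.bin_size
        field_ = {c: np.ones(asm.n_bins(c)) for c in asm.chrom_names}
        active = self.config.condition_matrix[condition]

        def apply(loci: LocusSet, factors) -> None:
            for iv, f in zip(loci, factors):
                lo = iv.start // w
                hi = min(math.ceil(iv.end / w), field_[iv.chrom].size)
                field_[iv.chrom][lo:hi] *= f

        if "artifact" in active:
            apply(self.artifact_loci, [iv.score for iv in self.artifact_loci])
        if "artifact_untagged" in active:
            apply(self.artifact_loci, self.untagged_factors)
        if "true_site" in active:
            apply(self.true_sites, [iv.score for iv in self.true_sites])
        if "control_peak" in active:
            apply(self.control_peak_loci, [iv.score for iv in self.control_peak_loci])
        return field_

    def expected_rn(self) -> BinnedTrack:
        """Noise-free ideal RN track: target_decoy field / decoy_only field."""
        exp = self.enrichment_field("target_decoy")
        ctrl = self.enrichment_field("decoy_only")
        meta = TrackMeta(
            sample_id="ideal_rn", condition="target_decoy/decoy_only",
            state=("scale_normalized", "averaged", "ratio_normalized"),
        )
        return BinnedTrack(
            self.assembly, {c: exp[c] / ctrl[c] for c in exp}, meta
        )

    def control_peak_region(self, margin: int = 2000) -> tuple[str, int, int]:
        """(chrom, start, end) spanning both operator arrays plus a margin."""
        ivs = self.control_peak_loci.intervals
        chrom = ivs[0].chrom
        lo = min(iv.start for iv in ivs) - margin
        hi = max(iv.end for iv in ivs) + margin
        return chrom, max(lo, 0), min(hi, self.assembly.length_of(chrom))


def _place_loci(
    rng: np.random.Generator,
    asm: GenomeAssembly,
    occupied: list[tuple[str, int, int]],
    n: int,
    width_range: tuple[int, int],
    margin: int,
    max_tries: int = 20_000,
) -> list[tuple[str, int, int]]:
    """Place n bin-aligned rectangles, margin-separated from everything."""
    w = asm.bin_size
    placed: list[tuple[str, int, int]] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise DataError(
                f"could not place {n} loci of width {width_range} in the assembly "
                f"(placed {len(placed)} after {max_tries} tries); genome too small"
            )
        tries += 1
        chrom = asm.chrom_names[rng.integers(len(asm.chrom_names))]
        width = int(rng.integers(width_range[0] // w, width_range[1] // w + 1)) * w
        length = asm.length_of(chrom)
        lo_start, hi_start = margin, length - margin - width
        if hi_start <= lo_start:
            continue
        start = int(rng.integers(lo_start // w, hi_start // w + 1)) * w
        end = start + width
        clash = any(
            c == chrom and start - margin < e and s < end + margin
            for c, s, e in occupied
        )
        if clash:
            continue
        placed.append((chrom, start, end))
        occupied.append((chrom, start, end))
    return placed


def build_truth(config: SimulationConfig | None = None, seed: int = 0) -> SimulationTruth:
    """Draw locus positions and enrichment factors; deterministic per seed."""
    config = config or SimulationConfig()
    asm = config.assembly()
    rng = np.random.default_rng(np.random.SeedSequence([7_000_001, seed]))
    occupied: list[tuple[str, int, int]] = []
    margin = config.placement_margin

    # the two operator arrays are placed as one rigid pair
    w1, w2 = config.control_array_widths
    sep = config.control_array_separation
    pair_span = sep + (w1 + w2) // 2 + max(w1, w2)
    (pair_chrom, pair_start, _) = _place_loci(
        rng, asm, occupied, 1, (pair_span, pair_span), margin
    )[0]
    occupied[-1] = (pair_chrom, pair_start, pair_start + pair_span)
    bs = asm.bin_size
    mid1 = pair_start + max(w1, w2)
    mid2 = mid1 + sep
    f1, f2 = config.control_array_factors
    control_ivs = []
    for mid, width, factor, label in ((mid1, w1, f1, "array_a"), (mid2, w2, f2, "array_b")):
        start = (mid - width // 2) // bs * bs
        end = start + max(width // bs, 1) * bs
        control_ivs.append(
            GenomicInterval(pair_chrom, start, end, category="control_peak",
                            score=float(factor), name=label)
        )

    artifact_pos = _place_loci(
        rng, asm, occupied, config.n_artifact, config.artifact_width_range, margin
    )
    true_pos = _place_loci(
        rng, asm, occupied, config.n_true_sites, config.true_width_range, margin
    )

    af = rng.uniform(*config.artifact_factor_range, size=config.n_artifact)
    uf = rng.uniform(*config.untagged_factor_range, size=config.n_artifact)
    tf = rng.uniform(*config.true_factor_range, size=config.n_true_sites)

    artifact_loci = LocusSet(
        "artifact_loci",
        [
            GenomicInterval(c, s, e, category="artifact", score=float(f),
                            name=f"artifact_{i + 1:03d}")
            for i, ((c, s, e), f) in enumerate(zip(artifact_pos, af))
        ],
    )
    true_sites = LocusSet(
        "true_sites",
        [
            GenomicInterval(c, s, e, category="true_site", score=float(f),
                            name=f"true_{i + 1:03d}")
            for i, ((c, s, e), f) in enumerate(zip(true_pos, tf))
        ],
    )
    control = LocusSet("control_peaks", control_ivs)
    logger.info(
        "build_truth(seed=%d): %d artifact loci, %d true sites, control pair on %s",
        seed, len(artifact_loci), len(true_sites), pair_chrom,
    )
    return SimulationTruth(
        config=config, seed=seed, assembly=asm,
        artifact_loci=artifact_loci, true_sites=true_sites,
        control_peak_loci=control, untagged_factors=uf,
    )


def simulate_coverage(
    truth: SimulationTruth, condition: str, replicate_seed: int
) -> BinnedTrack:
    """One raw replicate coverage track for a condition (NB per-bin counts)."""
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cfg = truth.config
    field_ = truth.enrichment_field(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [13_000_017, truth.seed, CONDITIONS.index(condition), replicate_seed]
        )
    )
    values: dict[str, np.ndarray] = {}
    for chrom, f in field_.items():
        mu = cfg.background_mean * f
        if cfg.dispersion == 0:
            counts = rng.poisson(mu)
        else:
            n = 1.0 / cfg.dispersion
            counts = rng.negative_binomial(n, n / (n + mu))
        values[chrom] = counts.astype(np.float64)
    meta = TrackMeta(
        sample_id=f"{condition}_r{replicate_seed}", antibody="sim", condition=condition
    )
    return BinnedTrack(truth.assembly, values, meta)


def simulate_replicates(
    truth: SimulationTruth, condition: str, n_replicates: int = 3, seed: int = 0
) -> ReplicateSet:
    """n raw replicate tracks with seeds derived from ``seed``."""
    return ReplicateSet(
        [
            simulate_coverage(truth, condition, replicate_seed=seed * 1009 + i)
            for i in range(n_replicates)
        ]
    )


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """How well a normalized track separates true binding from artifacts.

    A locus is called *enriched* when the Mann-Whitney test of its bins
    against the rest of the genome is over-directed and significant at
    ``alpha`` AND its median signal reaches ``min_fold`` over the background
    level 1.0 (significance alone is not enough: smoothing correlates
    neighbouring bins, which a rank test does not know about, so a minimum
    effect size is required — the same reason practical peak calling uses
    fold-enrichment cutoffs).

    - artifact_removal_rate: fraction of artifact loci NOT called enriched.
    - true_site_retention: fraction of true sites called enriched.
    - peak_false_positive_rate: fraction of naive peak calls overlapping
      neither a true site nor a control-peak array.
    """

    artifact_removal_rate: float
    true_site_retention: float
    peak_false_positive_rate: float
    n_artifact: int
    n_true_sites: int
    n_peaks: int
    alpha: float
    min_fold: float
    per_locus: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def _locus_called(
    values: np.ndarray, locus_mask: np.ndarray, name: str,
    alpha: float, min_fold: float,
) -> tuple[bool, float, float]:
    keep = ~np.isnan(values)
    x = values[locus_mask & keep]
    y = values[~locus_mask & keep]
    if x.size == 0:
        return False, float("nan"), float("nan")
    res = mann_whitney_from_groups(x, y, set_name=name)
    called = (
        res.direction == "over" and res.p_value < alpha and res.median_set >= min_fold
    )
    return called, res.p_value, res.median_set


def evaluate_recovery(
    rn: BinnedTrack,
    truth: SimulationTruth,
    alpha: float = 0.01,
    min_fold: float = 1.5,
    peak_threshold: float = 2.0,
    peak_min_width: int = 150,
    peak_merge_gap: int = 200,
) -> RecoveryReport:
    """Score a normalized track against the simulation ground truth.

    Works on any track whose background level is 1.0 — the RN output, or a
    scale-normalized averaged (uncontrolled) track for the before/after
    comparison.
    """
    if rn.assembly != truth.assembly:
        raise DataError("track assembly does not match the simulation truth")
    values = rn.flatten()
    rows = []
    for cls, loci in (("artifact", truth.artifact_loci), ("true_site", truth.true_sites)):
        for iv in loci:
            single = LocusSet(iv.name or cls, [iv])
            mask = single.bin_overlap_mask(truth.assembly)
            called, p, med = _locus_called(values, mask, single.name, alpha, min_fold)
            rows.append(
                {"locus": single.name, "class": cls, "chrom": iv.chrom,
                 "start": iv.start, "end": iv.end, "factor": iv.score,
                 "p_value": p, "median_signal": med, "called_enriched": called}
            )
    table = pd.DataFrame(rows)
    art = table[table["class"] == "artifact"]
    tru = table[table["class"] == "true_site"]
    removal = 1.0 - art["called_enriched"].mean() if len(art) else float("nan")
    retention = tru["called_enriched"].mean() if len(tru) else float("nan")

    peaks = naive_call_peaks(
        rn, threshold=peak_threshold, min_width=peak_min_width, merge_gap=peak_merge_gap
    )
    ok_sets = list(truth.true_sites) + list(truth.control_peak_loci)
    n_fp = sum(
        1
        for p in peaks
        if not any(iv.overlaps(p.chrom, p.start, p.end) for iv in ok_sets)
    )
    fp_rate = n_fp / len(peaks) if len(peaks) else 0.0
    return RecoveryReport(
        artifact_removal_rate=float(removal),
        true_site_retention=float(retention),
        peak_false_positive_rate=float(fp_rate),
        n_artifact=len(art),
        n_true_sites=len(tru),
        n_peaks=len(peaks),
        alpha=alpha,
        min_fold=min_fold,
        per_locus=table,
    )
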