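# Methods

## The problem and the model

ChIP-seq signal is contaminated by non-specific enrichment: a reproducible
set of "hyperChIPable" loci (often highly expressed regions such as tRNA
genes) is pulled down regardless of the antibody's actual target. Because
this enrichment arises during the immunoprecipitation itself, neither input
chromatin nor an untagged-strain IP subtracts it well — untagged IPs enrich
*different* sequences than IPs in strains where the antibody has a real
epitope to bind.

The remedy implemented here is **ratio normalization (RN)** against a decoy
control: a parallel IP in a strain expressing only an epitope-tagged decoy
protein (bacterial LexA, which binds nothing in the yeast genome except
integrated lexA-operator arrays) or a DNA-binding mutant (dbm) of the target
protein. Both tracks are processed identically and divided bin by bin.
Non-specific enrichment shared between experiment and control cancels to ~1;
target-specific binding survives as fold enrichment over control.

## Pipeline

Input is binned coverage (fixed 50 bp windows, 0-based half-open
coordinates). For each side (experimental, control), replicates are:

1. **Counts-normalized** — each replicate scaled so its genome-wide sum
   equals a common target (default: mean of replicate totals). Pure
   rescaling; per-track bin ratios are untouched.
2. **Smoothed** — centered moving average over a window (default 500 bp).
   The window is converted to an odd bin count (500 bp / 50 bp = 10 → 11
   bins, logged) because a centered window needs odd width. At chromosome
   ends the window shrinks to the available bins; no padding, so no signal
   is fabricated.
3. **Scale-normalized** — every bin divided by a low percentile (default
   20th) of the genome-wide bin distribution, taken over *all* bins
   including zeros (excluding zeros would redefine the background).
   Percentiles use linear interpolation between order statistics. After
   this stage "background" is 1.0 in every sample, making samples
   comparable and the eventual ratio interpretable as fold enrichment.
4. **Averaged** — per-bin arithmetic mean across replicates.

Then `RN(i) = (exp(i) + c) / (ctrl(i) + c)` with pseudocount `c = 0.01` (in
background units). Bins whose control value falls below a floor (default
0.1, i.e. 10% of the control background) are masked rather than divided: a
ratio against essentially absent control coverage asserts nothing. Masked
bins are carried as NaN, omitted from bedGraph output, and break peak-caller
runs.

The stage order (smooth before scale-normalize before average, divide last)
is fixed as the pipeline's contract. The pseudocount and floor are this
package's explicit policy for near-zero denominators; they are configurable
in `RNConfig`.

## Evaluation statistics

- **Distribution summaries** use 500 bp aggregated bins (mean of ten 50 bp
  bins, NaN-aware) and Tukey box-plot fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR).
  Positive outliers — the signature of non-specific enrichment — are counted
  separately. The outlier rule is invariant under positive rescaling.
- **Locus-set enrichment** is a two-sided Mann–Whitney U test of aggregated
  bins overlapping a locus set (≥1 bp intersection) against all remaining
  genome bins — a disjoint contrast, so the partition covers the genome
  exactly. For small problems (n₁·n₂ ≤ 10,000 and C(n, n₁) ≤ 500,000) the
  exact permutation null is enumerated, with midranks so ties are handled
  correctly; otherwise the normal approximation with tie correction is used
  (the method actually applied is recorded in the result). Two-sided p is
  defined symmetrically around the null mean: Pr(|U − n₁n₂/2| ≥ |U_obs −
  n₁n₂/2|). Direction is read off group medians. Significance is annotated
  at p < 0.01. No multiple-testing correction is applied across locus sets;
  callers comparing many sets should correct downstream.
- **Replicate agreement** is pairwise Pearson correlation on per-bin values;
  zero-variance tracks give NaN with a warning rather than an error.
- **Origin-efficiency correlation** is Spearman's ρ between per-origin
  efficiency scores and per-origin signal, summarized as the maximum
  unmasked value within ±500 bp of the origin midpoint (peak height; the
  midpoint anchor is used for all features since interval annotations do not
  define a better anchor).

## Feature aggregation and peak classification

Feature-centered matrices take the signal across a window (default 5 kb)
centered on the bin containing each interval's midpoint; minus-strand rows
are flipped so columns run 5′→3′. Windows leaving the chromosome drop the
row with a warning (a shorter row would misalign columns). Rows are emitted
unscaled; any per-row scaling is a plotting decision.

Peak classification assigns each called peak to exactly one category: the
highest-priority reference category it overlaps (default priority confirmed
> likely > dubious, matching origin-annotation confidence), else "other".
Counts therefore always sum to the number of peaks. Venn overlaps between
2–3 interval sets are reported per perspective (for each set, its elements
tallied by which other sets they intersect), because interval sets of
different sizes share no common element universe.

The naive peak caller (runs of unmasked bins ≥ threshold, short-gap merging,
minimum width, leftmost-maximum summit) exists for closed-loop testing on
synthetic data and quick inspection; it makes no statistical claim. For real
data the documented MACS2 invocation is pinned: effective genome size
1.24 × 10⁷, `--nomodel`, `--extsize 100`, `-q 5e-2`, optional control file.

## The simulator

`simulate` generates the study conditions the method was designed for, with
known ground truth:

- genome: 4 chromosomes × 200 kb, 50 bp bins — large enough for ~1,600
  aggregated 500 bp bins while keeping full runs under a few seconds;
- 30 artifact loci (600–1,500 bp, factors uniform 3–8) shared by all
  tagged-strain IPs; in the untagged condition the same loci get an
  independent, reduced draw (uniform 1.5–3) — encoding the observation that
  untagged IPs enrich different sequences, the core argument for decoy
  controls. The reduced range is calibrated so the untagged track's positive
  500 bp-bin outlier fraction lands in the empirically observed 3–8% band;
- 20 true binding sites (500–1,000 bp, factors 4–12), active only in the
  experimental (`target_decoy`) condition;
- two operator arrays (200 and 100 bp, factors 12 and 8) with midpoints
  1.6 kb apart, active in decoy-bearing strains — used to check that
  500 bp smoothing still resolves peaks 1.6 kb apart;
- per-bin counts ~ NB(mean = 20 × product of active factors, dispersion
  0.1; variance μ + 0.1μ²). Overdispersion is universal in ChIP coverage;
  dispersion 0 degenerates to Poisson.

Loci are bin-aligned rectangles placed by rejection sampling with a 3 kb
dead zone between loci and from chromosome ends, so smoothing cannot bleed
one locus class into another. Enrichment is multiplicative and rectangular;
the smoothing stage supplies realistic peak shape. All draws flow from
explicit seeds (`SeedSequence`; no global random state), so (seed,
condition, replicate_seed) fully determine a track.

What the simulator does *not* model: read-level effects (fragment-length
distribution, GC bias, mappability), copy-number structure such as the rDNA
repeat array, chromatin-state autocorrelation of the background, or
shoulder-shaped binding profiles. Passing recovery tests therefore shows the
pipeline's arithmetic and decision rules behave as designed under realistic
counting noise — not that real antibody backgrounds are fully captured.

## Recovery scoring

`evaluate_recovery` scores a normalized track (background 1.0) against the
truth. A locus is *called enriched* when its 50 bp bins, tested against all
remaining genome bins, are Mann–Whitney over-enriched at α (default 0.01)
**and** the locus median reaches a minimum fold enrichment (default 1.5 over
background). Significance alone is deliberately insufficient: smoothing
makes neighbouring bins strongly correlated, and a rank test that treats
them as independent overstates significance — under the default noise model
roughly a quarter of perfectly cancelled artifact loci would be "significant"
by p-value alone. Requiring a minimum effect size is the same reason
practical ChIP analyses pair p-values with fold-change cutoffs. Reported
rates: artifact removal (fraction of artifact loci *not* called), true-site
retention (fraction of true sites called), and the naive-peak false-positive
rate (peaks overlapping neither a true site nor a control array).

Under the default conditions, RN achieves removal and retention ≥ 0.9
(typically 1.0) while the uncontrolled experimental average removes ≤ 0.2 of
artifacts — the method's core claim, checked in the test suite and
recomputed by `scripts/acceptance.py`.

## Numerical and degenerate-input policy

- Percentile scaling refuses tracks whose background percentile is ≤ 0
  (too many empty bins) instead of emitting infinities.
- Counts normalization refuses all-zero replicates.
- Smoothing with integer-valued counts is exact: cumulative sums of values
  < 2⁵³ are representable, so the oracle comparison in the tests is
  bit-exact.
- Tie-breaks are deterministic everywhere (leftmost summit; stable
  chromosome order; seeded placement).
- Peak positions on flat-topped smoothed peaks are estimated by
  signal-weighted centroid (`peak_centroid`), not argmax, which wanders
  under noise.

## Known limitations

- The Mann–Whitney test inherits bin-level correlation from smoothing; its
  p-values are anticonservative for wide smoothing windows. The effect-size
  gate mitigates this for calling, but reported p-values should be read
  accordingly.
- The control floor masks low-coverage bins rather than modelling their
  uncertainty; a fully probabilistic ratio (e.g. Gamma–Poisson) is out of
  scope.
- BED/bedGraph/narrowPeak are the only I/O dialects; BAM/FASTQ and
  alignment are upstream concerns.
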