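# Methods

`mitoqc` re-implements, as a tested library, the analytical workflow used to
validate whole-mitochondrial-genome sequencing on a 2-pool amplicon panel:
artifact read filtering, threshold-based variant and point-heteroplasmy (PHP)
calling, VarFreq-distribution run QC with a recurrent-noisy-position
blacklist, and dilution-series sensitivity analysis.  A seeded synthetic-data
generator provides inputs with the statistical structure the analysis
assumes, together with ground truth for every injected feature.

## Coordinates and the circular reference

The canonical axis is the 16,569 bp rCRS numbering, 1-based inclusive, as in
forensic mtDNA nomenclature.  For alignment the circle is linearized by
repeating the first 80 bases after position 16,569 ("rCRS + 80", 16,649
positions); `remap_position` folds the extension back onto positions 1–80.
Intervals never wrap internally: a feature spanning the origin is represented
as two canonical intervals, which keeps interval arithmetic total.  The
bundled reference is a seeded random sequence of canonical length — every
position-level computation in the package is sequence-agnostic, so no
sequence download is required for tests or simulations.

One bookkeeping subtlety is documented rather than resolved: the VarFreq
analyses are reported over 16,648 positions, whereas 16,569 + 80 = 16,649;
the package uses the full 16,649/16,569 axes and treats the one-position
discrepancy as a reporting artifact of the source data.

## Amplicon panel model

The generator tiles the circle with `n_amplicons` overlapping amplicons with
lengths in 125–174 bp, alternating between two pools, named `mt_1 …
mt_<n>`.  The default is **164 amplicons**.  The assay being emulated is
described as 81 primer pairs per pool with amplicon names reaching `mt_164`,
and five specific amplicons (`mt_125`, `mt_130`, `mt_133`, `mt_139`,
`mt_164`) are the canonical micro-amplicon hotspots; a 164-amplicon tiling
is the smallest panel in which those names exist and the 125–174 bp length
range can tile 16,569 positions.  Geometry then fixes the mean overlap at
about 49 bp (mean length ≈ 150 bp against a mean advance of 101 bp); an
11 bp target overlap is honored whenever the requested amplicon count makes
it feasible (roughly 102–145 amplicons).  Requested configurations that
cannot tile the circle with positive overlap are rejected.

## Read filtering

Amplification negatives on this chemistry are dominated by short, poorly
mapped reads — micro-amplicons formed between the forward primer of one
amplicon and the reverse primer of its overlapping neighbour.  The filter
characterizes them by a two-cluster analysis of (aligned length, MAPQ),
z-score standardized.  Small inputs (≤ 40 points) are solved to the exact
minimum within-cluster sum of squares by a projection sweep (for two
clusters in the plane, the optimal partition is a threshold split along some
direction; sweeping all critical directions is exhaustive); larger inputs
use k-means with 30 restarts and a fixed seed.  A length cutoff is derived
as the mean of cluster midpoints rounded up to a configurable granularity,
but the shipped pipeline default is the validated literal 80 bp — the
published workflow's choice — unless cutoff derivation is explicitly
requested.  MAPQ informs clustering and reporting but not the filter
predicate, mirroring the validated workflow (length-only filter); aligned
length is the CIGAR-consuming reference span, since artifacts are defined by
their aligned footprint.  Hotspot amplicons are those whose removed-read
count exceeds 2× the panel-wide mean, with reads assigned by maximal span
overlap.

## Threshold caller

Pileup columns carry strand-resolved counts for A/C/G/T/DEL plus insertion
sequences anchored to the preceding canonical position.  Every canonical
position is classified by a fixed cascade with the validated defaults
(minimum total coverage 20 reads; minimum variant coverage 20 reads; 96.0%
confirmation; 10.0% PHP; 20.0% insertion; 30.0% deletion; low-coverage
marking below 5.0% of the amplicon median):

1. depth < 20 → no-call;
2. top base = reference at ≥ 96% → reference;
3. top base ≠ reference at ≥ 96% (and ≥ 20 reads) → substitution;
4. second base ≥ 10% (and ≥ 20 reads) → PHP, reported as the IUPAC code of
   the top two bases with the minor frequency;
5. DEL ≥ 30% → deletion; insertions are tested independently at 20%;
6. otherwise reference, flagged.

The ordering (substitution before PHP before indel) is a package decision —
the source parameter set lists thresholds without an order — and is frozen
in configuration.  Ties between equal counts resolve by
(count, reference-preference, lexicographic).  Calls in the homopolymer
C-stretches (np 303–310 and 16,184–16,193 by default) and in the
strand-bias region (np 8,248–8,256) are emitted but flagged, not
suppressed.  The phylogeny-weighted alignment scoring of the original
vendor caller is out of scope; calling operates on pileups of already
aligned reads.  Haplotypes are reported in EMPOP-style notation (`263G`,
`309.1C`, `524.AC`, `7861Y`, `249DEL`) that round-trips through the parser.

## VarFreq QC and the blacklist

VarFreq (haplotype purity) at a position is the percentage of reads
supporting the called allele — the major allele at PHP positions; reads
carrying an insertion at the anchor are not counted as supporting the clean
allele.  The empirical cumulative distribution is computed on the integer
grid 0–99; positions at exactly 100 contribute to the denominator but to no
grid point.  The recurrent-noisy-position blacklist collects positions whose
mean VarFreq across the replicates of a sample group falls below 90% in at
least two distinct groups (recurrence across *samples*, not merely
replicates), reporting per-group mean, SD, the second most common signal
(base, DEL or INS) and a NUMT annotation from the packaged table of 26
recurrently impure positions observed on forensic control DNAs.

Run reliability is judged by an empirical envelope: the elementwise min/max
band of ≥ 3 known-good ECDFs over the grid window 93–99, with distance
defined as the maximal exceedance of the band's upper edge and a default
tolerance of 0.005 (absolute proportion).  The envelope is deliberately the
simplest formalization of the cumulative-VarFreq diagnostic; no parametric
test is attempted.  Coverage uniformity is the fraction of positions at
≥ 0.2× the mean base coverage (platform convention; configurable).

## Sensitivity analysis

Input mass converts to mtDNA template copies linearly (100 pg ≈ 2,900
copies; 0.6 pg ≈ 17 copies, round-half-even with the real value retained).
Replicates are scored against truth with false positives = called variants
absent from truth, false negatives = truth variants uncalled at covered
positions; positions inside no-call intervals are excused, and positions on
the recurrent-noise blacklist are excluded from FP/FN accounting — the
workflow's own QC output exists precisely so analysts treat calls there
with caution, and scoring them at face value would misrepresent the
workflow being modeled.  Haplotype comparison excludes either profile's
no-call intervals, counts a PHP whose allele pair contains the other
profile's call as concordant-with-note by default (strict mode available),
tags indel discordances inside homopolymer tracts, and supports
control-region restriction (np 16,024–16,569 + 1–576, the standard forensic
bounds).

## Synthetic-data generator

The generator is the package's model of the data-generating process, with
defaults frozen at the study's conditions:

* **Templates.** The template pool is `Poisson(copies)`; each amplicon
  captures templates by binomial thinning (capture probability 0.9).  Each
  PHP site assigns its alternate allele per *template* (probability =
  true frequency); this is the central modelling choice — read-level
  assignment would understate low-input heteroplasmy variance, while
  template-level assignment makes PHP quantification coarse and unstable
  exactly when few templates are captured.
* **Depth.** Sequencing yield is decoupled from input mass: per amplicon,
  reads ~ Poisson with a mean set by `target_depth` (default 1,400×
  genome-wide base coverage, matching the observed median of 1,383), scaled
  by the panel overlap factor and a lognormal per-amplicon bias (CV 0.25,
  uncalibrated — the study reports no per-amplicon bias figures).  This
  models library normalization before pooling, which is why real dilution
  series keep near-constant depth while templates dwindle; a fixed
  reads-per-template mode (`per_template_reads`) is available as an
  override.  Reads are distributed over captured templates uniformly
  (equivalently Poisson reads per template with mean depth/templates).
* **Noise.** Per-position error fractions are Gamma-distributed with mean
  `base_error_rate` (0.005) and shape = 3 × captured templates (the shape
  factor approximates the number of independent early-PCR lineages per
  template).  At high input this collapses to a uniform error rate; at low
  input single early errors are jackpot-amplified into visible impurity,
  which is what degrades the cumulative VarFreq distribution of low-input
  runs.  Independently, founder errors hit captured templates at 2×10⁻⁴ per
  base, attenuated by 2⁻ᶜ for an origin cycle c ~ U{1..4}; with a single
  captured template these surface as false-positive calls, reproducing the
  spurious calls seen at the most extreme dilutions.  These two rates are
  the generator's only calibrated parameters: they were set, once, so that
  the simulated ladder reproduces the validated behavior (reliable calls to
  0.6 pg; PHP instability below 0.3 pg; false positives and gaps at the
  last dilutions; X10+ runs separable from the 100 pg band).  Simulated
  replicates at 0.6/0.3 pg sit near the run-classifier boundary
  (distance ≈ 0.005–0.012 against tolerance 0.005), so the classifier is
  conservative in exactly the region the diagnostic was proposed to probe.
* **Recurrent noise.** Each packaged noisy position draws a per-sample
  fraction ~ Normal(100 − mean VarFreq, SD)/100 truncated to [0, 1] of
  reads carrying its second allele (a base, DEL, or a duplicating INS);
  inside the strand-bias region those reads are emitted on a single
  strand.  If a configured second allele coincides with the synthetic
  reference base it is rotated to the next base so the noise stays
  visible.
* **Artifacts.** Micro-amplicon reads (length 40–79 bp, MAPQ 0–20) are
  appended at hotspot overlap junctions: 2.7% of mapped reads in positive
  samples, and in negatives a 69% short-read fraction over a trace
  background of full-length reads (≈ 9.4× residual base coverage) — the
  levels observed in the validated runs.  Genuine reads draw MAPQ 40–60,
  disjoint from artifacts by default so the clustering step is well-posed
  (an overlap can be configured for stress testing).
* **Homopolymers.** C-stretch regions receive an elevated per-read deletion
  rate (1%).

Truth records the realized template count, per-amplicon captures, realized
PHP template fractions and noise fractions, and assigns every emitted read
id to exactly one category (genuine / artifact / noise-carrying).

### What the generator does not model

Flow-space signal, PCR chimeras, per-base quality realism, primer-site
polymorphisms, degradation profiles, and amplification-efficiency
differences between amplicons beyond the lognormal bias.  Truth haplotypes
are substitution-only (indel truths are exercised through hand-built
profiles in tests).  Passing recovery tests therefore demonstrates that the
*analysis logic* implements the validated workflow faithfully under the
stated statistical assumptions — not that those assumptions exhaust real
instrument behavior.

## Numerical and scaling choices

Variant frequencies are computed on unrounded counts and rounded to one
decimal only for display.  Pileups are dense numpy count arrays; reads are
stored columnar with sparse deviations from the reference, so a full
1,400× genome simulation with ~240,000 reads builds and calls in a few
seconds.  Test and acceptance runs use the study's own scale — a 13-step
ladder in triplicate at ≤ ~2,900 templates, two sample groups × 6
replicates for the blacklist, 9 negatives — which keeps the complete suite
within a few minutes on one CPU.  Positions with configured noise means of
88–90% sit within one or two SDs of the 90% blacklist threshold, so their
detection is intrinsically probabilistic; recall is therefore asserted to be
perfect only for positions with configured mean ≤ 85% and reported as a
rate above that.
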