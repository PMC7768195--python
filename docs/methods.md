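# Methods

This note documents the models, rules and numerical choices behind
`bafdomains`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real data.

## Coordinates and interval algebra

All intervals are 0-based, half-open (BED convention); zero-width
intervals are rejected at construction. "Within *g* bp of each other"
merges intervals whose inter-interval gap is ≤ *g*: abutting and
overlapping intervals always merge, and intervals on different chromosomes
never do. Blacklist filtering drops a peak on any shared base (≥ 1 bp)
rather than trimming it, reading "exclude" literally. Nearest-gene
distance is measured to the gene *body*, not the TSS, with deterministic
tie-breaks (smaller body start, then lexicographic gene id). These
conventions are enforced by per-base brute-force oracles in the test
suite, not merely asserted.

Consensus regions are defined by per-base support depth: a base counts a
sample at most once (sample peak sets must be internally merged), maximal
runs with depth ≥ *min_support* are extracted, and the runs are then
merged within the consensus gap (2 kb for BAF ATPase peaks, 5 kb for
H3K27me3). The alternative reading — whole-peak reciprocal overlap — is
ill-defined for staggered intervals; per-base depth matches the semantics
of genomic-ranges toolkits and reduces to the pooled merge at
min_support = 1.

## Signal model

A track is piecewise-constant coverage; uncovered positions are 0, while a
chromosome entirely absent from a track raises by default (an absent
chromosome usually signals an input mismatch, not true zero coverage; a
lenient mode returns 0). Normalization rescales to a per-10-million-
fragment scale, and the promoter threshold (mean H3K4me3 > 8) is
interpreted on that same scale, averaged over the whole peak. Aggregation
is always length-weighted, so binned window means average exactly to the
interval mean, and window bins beyond chromosome bounds contribute 0.
Heat-map style matrices are capped at a matrix-wide empirical percentile;
the cap is the upper order statistic rather than an interpolated quantile
because only the order statistic makes capping idempotent. Log₂ fold
changes use a symmetric pseudocount (default 1 normalized unit, recorded
in the configuration) to tame zeros.

## Width quantiles

Peaks are ranked by (width, chrom, start) and the peak of rank *r* out of
*n* receives label Q⌈*k·r*/*n*⌉. This makes the partition balanced (group
sizes differ by ≤ *k* − 1), width-monotone up to ties, and fully
deterministic — properties that matter because "Q4" is the operational
definition of a broad domain and downstream binding fractions depend on
it. Quartiles can be computed per sample or on a pooled consensus set; the
pipeline uses the consensus set.

## Chromatin states

Six states are assigned from four core marks by ordered rules (H3K27me3 ∧
H3K4me3 → bivalent; H3K27me3 → polycomb-only; H3K4me3 ∧ H3K27ac → active
promoter; H3K4me1 ∧ H3K27ac → active enhancer; H3K4me1 alone → primed
enhancer; else no signal), with "high" meaning above a per-mark threshold
(default 1.0 normalized unit, configurable). A manual cluster-curation
step is not reproducible, so labels come from these rules; Ward/Euclidean
agglomerative clustering on log₂(1+x), per-mark standardized signal is
retained for exploration and row ordering (default k = 8). The bivalent
rule is purely mark-based, without requiring promoter context.
Reversibility is the fraction of sites whose rule-assigned label under the
"perturbation removed" condition equals the control label, reported
overall and per control state.

## Expression and association

Counts are converted to TPM (length-normalized rates scaled to 10⁶ per
sample; all-zero samples are left zero and flagged). The two-group
differential test is a deliberate stand-in for a negative-binomial count
model: a per-gene Welch *t* test on log₂(TPM+1) with Benjamini–Hochberg
adjustment, flagged at |log₂FC| ≥ log₂(4) and adjusted P < 0.05. The
pipeline accepts externally produced DE tables in the same schema when a
count-model test is preferred; the package's contribution is the
thresholding and the downstream association statistics, not the count
model. The multiple-testing procedure is fixed to Benjamini–Hochberg.

Peaks map to all genes whose body or closed ±1 kb TSS window they overlap
(promoter and distal intragenic peaks) or to the single nearest gene
(distal intergenic peaks). When a gene receives several peaks its domain
width is the maximum mapped width (mean and nearest are available in
configuration); maximum was chosen because the question is whether a gene
is under *any* broad domain. Breadth-vs-signature reports per-set medians
and the Welch test on the two width samples; genes with no mapped peak are
excluded and counted. Q4/Q1 binding percentages are compared with
Fisher's exact test on the bound/unbound 2×2 table — a *t* test is
ill-defined for a single pair of percentages — and the binding-enrichment
ratio compares the bound proportion of significantly up- versus
down-regulated genes, with both proportions always reported and an
infinite ratio reported as such with its counts.

Fold signatures (5× for joint cohort comparisons, 20× for pairwise ones)
use pseudocounted group means (default 0.1 expression units) to stabilize
zero denominators.

## Synthetic data: what it emulates and what it does not

The generator plants the structure the analysis assumes, with full ground
truth and byte-level determinism from one seed:

- **Genome** — 5 chromosomes × 40 Mb, 10,000 non-overlapping genes placed
  in per-gene slots, CpG islands at 70 % of promoters plus background,
  20 blacklist intervals. Infeasible packings raise.
- **Peaks** — lognormal widths: broad domains (log-median 5 kb, σ = 0.4)
  at 500 tumor-high genes, narrow peaks (log-median 0.6 kb) elsewhere;
  peak centers jittered up to 2 kb around the TSS so location classes are
  mixed. Four tumor replicates with ≤ 100 bp coordinate jitter and 5 %
  peak dropout (3-of-4 consensus then recovers ≥ 98 % of planted domains
  in expectation); four control cell types with narrow peaks only.
- **Mark tracks** — one constant run per site per mark: the state
  archetype mean plus truncated Gaussian noise (σ = 0.25). Archetype
  means (high ≈ 6–10, background 0.2) and the state frequency vector
  (27.4 % polycomb-only, 17.1 % bivalent, 28.8 % primed enhancer, 6 %
  active promoter, 11.1 % active enhancer, 9.6 % no signal) mirror the
  published composition of fusion-protein binding sites. Induction maps
  repressed and quiet states to active ones; reversion redraws from the
  control archetypes.
- **Expression** — negative-binomial counts (lognormal baseline, median
  100, dispersion 0.05), 6 + 6 samples; tumor-high genes get an 8-fold
  planted increase, control-high genes (120) the reciprocal. Fusion
  binding is assigned per gene with probability 0.6 (induced), 0.25
  (repressed), 0.3 (background), realized as a synthetic promoter-proximal
  fusion peak per bound gene — so the expected enrichment ratio is 2.4.

Deliberately *not* emulated: read-level noise and alignment artifacts,
peak-caller behavior, overlapping or nested gene models, chromatin-state
mixtures within one site, library-composition biases beyond what TPM
induces, and the absolute counts of any real dataset (e.g. the number of
binding sites), which depend on genome scale and sequencing depth.
Passing tests therefore demonstrate that the implementation recovers
planted structure under these idealized conditions, not that it would
reproduce any particular real dataset's numbers.

## Problem sizes and numerical conventions

Tests and the acceptance script run the default scenario (10,000 genes,
~2,000 tumor peaks/sample, 2,000 state sites, 12 expression samples),
which executes in seconds; oracle-equivalence checks use 1,000 random
merge instances and 500 consensus instances with coordinates below 10⁵.
Degenerate cases are pinned by convention: Welch with two zero-variance
equal-mean samples returns t = 0, p = 1; empty reference sets give overlap
fraction 0 (not an error); an empty quantile group reports NaN summaries.
The pipeline's `run.log` carries timestamps and is excluded from
byte-identity comparisons; all analytic outputs are byte-identical across
reruns for a fixed seed and configuration.

## Known limitations

- The Welch-based DE stand-in is anticonservative for very low counts
  compared to a count model; use an external DE table for real data.
- Library-composition effects of strongly asymmetric planted folds shift
  null log₂FCs away from zero under TPM (visible as a ≈ −0.4 median null
  shift in the default scenario); the 4-fold flag threshold absorbs this,
  but smaller planted folds would not be recoverable at the same
  threshold.
- bigWig input is not supported; convert to bedGraph first.
- Chromosome names are matched exactly (no alias resolution).
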