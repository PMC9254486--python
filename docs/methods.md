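# Methods

This note records the statistical procedures `rloopscape` implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Coordinate model

All coordinates are 0-based half-open (BED convention) in every module;
1-based formats would be converted at the reader boundary. Strand is `+`,
`-` or `.`, and `.` matches either strand in stranded comparisons, because
chromatin-marker tracks are typically unstranded while R-loop peaks are
stranded. Chromosome-name mismatches between a file and the genome layout
are a hard error with an explicit rename-map escape hatch — silently
dropping a chromosome is the classic interval-analysis bug. Every reader
validates intervals against the layout at load time so no stage can fail
mid-analysis on an out-of-bounds record.

## Peak post-processing

**Consensus.** Peaks are assumed to have been called twice per sample and
strand: against an input control and against an RNase H1-digested control
(RNase H1 destroys the RNA moiety of a hybrid, so peaks surviving it are
non-R-loop background). A peak is kept iff the input-referenced call
overlaps at least one same-strand RNase H1-referenced call by ≥ 1 bp
(threshold configurable), and the retained peak keeps its original
coordinates rather than the intersection — the minimal reading of
"overlapping peaks were kept".

**Both-strand artifact filter.** Any +/− pair whose reciprocal overlap
(overlap as a fraction of each peak's own length) is ≥ 0.90 on *both*
sides removes both members; removal is evaluated pairwise, so one peak with
several qualifying partners removes all of them. Applied after consensus,
per sample.

**Sharing.** Cross-sample sharing clusters same-strand overlapping peaks by
single linkage (a sweep over sorted starts; chains A∩B, B∩C join even when
A∩C is empty). A cluster is `all_samples` when every sample contributes,
`two_plus` when at least two but not all do, `unique` otherwise; fractions
are over cluster counts. Clusters are strand-specific — a `+` peak never
joins a `-` peak — consistent with the strand-aware pipeline. Per-sample
unique peak sets are emitted for sample-specific colocalization runs.

**Track correlation.** Coverage tracks are summed into fixed windows
(default 1 kb) across the genome, excluding listed chromosomes (by
convention the mitochondrial genome), and compared by Pearson correlation.
A constant binned track raises rather than returning an undefined value.

## AT/GC skew

For window *i* (default 50 bp, non-overlapping tiling from position 0;
a final partial window is kept when at least half a window long),

    S_i = (G_i − C_i) / (G_i + C_i),

and the A/T analog. Counting is case-insensitive; N contributes to no
category. Windows with a zero denominator are *missing*, not zero — filling
them with 0 would fabricate "no skew" signal inside N-rich assembly gaps.
Skew is strand-antisymmetric (the reverse complement negates it), which
drives two metaprofile options below.

## Metaprofiles

The profile engine averages any per-base signal over a region set on a
fixed bin grid, mean ± SEM per bin (SEM = sd/√n over contributing regions;
missing values are excluded bin-wise).

* `scale_regions`: `flank/bin` fixed 50 bp bins either side and the region
  body rescaled onto `body/bin` bins (defaults 500 bp flanks, 1 kb body,
  50 bp bins). Body bin *j* averages per-base values over the fractional
  slice `[jL/n, (j+1)L/n)` with every bin guaranteed at least one base.
  This per-base slice-mean is used instead of interpolating window-midpoint
  values: the two agree in the large-region limit and the slice-mean stays
  well defined for regions comparable to one bin. Regions shorter than one
  bin are skipped and counted.
* `reference_point`: `2·flank/bin` bins around an anchor
  (start / center / end; start and end are resolved 5′→3′ on the minus
  strand when orienting).

Minus-strand regions are reversed when `orient_by_strand` (default on for
skew) and their values negated when `flip_sign_on_minus`. For gene-body
skew profiles both are on by default: without the flip, + and − genes
cancel because of strand antisymmetry. Both behaviors remain flags because
reasonable conventions differ.

## Annotation

**Strand-relative.** A stranded peak is `sense` if it overlaps any
same-strand transcript, else `antisense` if it overlaps any opposite-strand
transcript, else `untranscribed`. Sense takes precedence for peaks spanning
divergent transcripts; this makes the three categories exclusive and
exhaustive. Fractions are over the peak count.

**Feature-level.** Isoforms are collapsed per gene to the longest span so
each peak gets exactly one label. The peak *midpoint* is classified with
the fixed precedence 5′UTR > 3′UTR > exon > intron > upstream > downstream
> intergenic, with up/downstream flanks of 5 kb (configurable) resolved by
strand and UTRs derived from the BED12 thick (CDS) interval. The expected
distribution is the fraction of the mappable genome (layout minus mask)
each category covers under the same precedence, computed by painting
per-base label arrays; enrichment is observed/expected. Midpoint-plus-
precedence is a deterministic, testable stand-in for annotation tools whose
exact rules are unpublished; the precedence order is a parameter of the
implementation, not a claim about any external tool.

## Matched-permutation colocalization

The observed statistic for a marker × R-loop pair is the number of genomic
base pairs covered by both sets, each merged first so a base never counts
twice; it is unstranded because marker tracks are unstranded. The R-loop
peaks stay fixed and the *marker* peaks are shuffled: each peak is
re-placed uniformly at random over every position where it fits entirely
inside the gap/blacklist-free genome, preserving its exact length.
Placement is genome-wide by default with a per-chromosome option; shuffled
peaks may overlap one another (no exclusion is applied between them).

For ChIP-chip markers the shuffle additionally preserves probe density:
the density of a peak is the number of probes whose midpoint falls inside
it per kb of peak length, and a shuffled peak conforms when its density at
the new location is within a tolerance of its own original density. The
tolerance defaults to 2 standard deviations of the original per-peak
density distribution (self-calibrating; the absolute value depends on the
probe platform). Non-conforming peaks are re-placed iteratively until at
least 99% conform, capped at 100 rounds; on cap the achieved fraction is
recorded in the result and a warning is raised rather than failing.

With n permutations (default 1000),

    p_enrich  = (1 + #{null ≥ observed}) / (n + 1)
    p_deplete = (1 + #{null ≤ observed}) / (n + 1)

(the add-one estimator: never zero, mildly conservative, and under the
independence null `P(p ≤ t) ≤ t` exactly by exchangeability). Fold
enrichment is `log2(observed / null mean)`; a zero observed or zero null
mean yields a signed-infinity sentinel with an explicit flag. Panels run
one test per marker × R-loop set with per-cell child seeds from one master
seed (bit-reproducible regardless of panel size) and Bonferroni-adjust the
one-tailed p in the observed direction, `min(p_enrich, p_deplete)`, times
the number of cells across the whole panel. An optional region restriction
(e.g. peaks near terminators) keeps whole R-loop peaks that overlap the
region set; peaks are not clipped.

## Expression association

Quartiles split transcript FPKM at the empirical 25/50/75 percentiles with
boundary ties assigned to the lower quartile (so equal values never
straddle a boundary; the all-equal degenerate case collapses to Q1 with a
warning). Peaks link to transcripts by ≥ 1 bp overlap with matching strand;
a peak spanning two same-strand genes counts for both (documented
double-counting). Quartile occupancy is the share of R-loop-positive genes
per quartile, tested against the uniform 0.25 expectation by exact binomial
test with Bonferroni ×4. Peaks-per-gene averages over R-loop-positive genes
by default (≥ 1 by construction); the all-genes denominator is available
via a flag since either convention is defensible. The specificity test
selects genes R-loop-positive in exactly one of two samples, reports the
per-gene FPKM difference (a − b), its median, and a sign test against
median zero; it is antisymmetric under sample exchange. The
positive-vs-negative expression comparison uses a two-sided rank-sum
(Mann–Whitney) test — rank-based to avoid distributional assumptions on
FPKM.

## Synthetic data

The generator emulates a three-sample ssDRIP-style study at desk scale.
Defaults (all overridable in `SimulationConfig`):

* genome: 2 Mb over chr2L (1.2 Mb), chr3R (0.78 Mb) and a 20 kb
  mitochondrial stand-in, uniform base composition except programmed
  regions; two N-gap regions form the mask;
* R-loop peaks: log-normal lengths, median 500 bp, capped at 10 kb
  (echoing observed DRIP peak-size distributions), placed sense-strand
  within genes plus unstranded-background peaks; per-sample placement bias
  among TSS / gene body / TTS distinguishes an embryo-like terminator-heavy
  sample from the cultured-cell-like samples;
* raw calls: the final peaks plus 15% noise calls for the input-referenced
  set, and a ±60 bp jittered copy plus noise for the RNase H1-referenced
  set, so the consensus step has something real to do;
* expression: log-normal FPKM (log-mean 1.0, log-sd 1.5) per transcript
  and sample; a gene becomes R-loop-positive with probability 0.2, times
  an odds multiplier of 4 in the top quartile, so the expected Q4 share of
  R-loop genes is 4/(4+3) ≈ 0.571; an optional `delta_fpkm` shifts the
  first sample's FPKM for its sample-specific R-loop genes (0 by default);
* markers: for planted factor ρ ≠ 1 the track decomposes exactly —
  `round(ρ·M·μ/L)` peaks fully inside merged R-loop territory (μ being the
  expected overlap of one uniformly placed peak, estimated from the
  territory coverage function) and the remainder avoiding the territory —
  so E[observed]/E[null] = ρ with near-zero variance; ρ = 1 markers are
  placed uniformly and independently, which is what permutation-test
  calibration requires;
* probes: 25 bp probes every 100 bp in a dense region (first 500 kb of
  chr2L) and every 1 kb elsewhere; 500 ChIP-chip-like peaks (log-normal,
  median 800 bp) are drawn entirely from the dense regime, giving the
  two-regime fixture on which density matching is exercised;
* skew-transition sites: optional regions planting +δ AT skew (δ = 0.4)
  on the 5′ half and −δ on the 3′ half of a 2 kb window with co-placed
  peaks, so oriented peak-centered profiles must cross zero at the center
  bin.

Everything derives deterministically from one seed through spawned child
streams; the same seed yields byte-identical files. Ground truth (ρ values,
odds, site positions) is written to `ground_truth.json`, which no pipeline
stage reads.

What the synthetic data does *not* emulate: real sequence composition
(isochores, repeats, codon structure), read-level noise, correlated
replicate structure, overlapping gene models, or trans effects linking
chromatin and expression. Passing tests therefore demonstrate correctness
of the statistics and recoverability of planted effects under the stated
generative model, not biological performance on real ssDRIP-seq data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full default study (2 Mb
genome, ~40,000 skew windows, three ~800-peak samples, 300-peak markers,
500 ChIP-chip peaks) and a permutation-calibration study of 200 independent
null datasets at 200 permutations each on a 200 kb genome; these sizes were
chosen so the whole suite completes in well under a minute while leaving
every statistic comfortably powered. Permutation counts in examples and
tests (300–500) trade precision of the null mean (relative error
≈ cv/√n, far below the planted-effect tolerances) against runtime; the
library default stays at 1000.

Ties in interval sorting are broken by (start, end); isoform-collapse ties
by transcript id; quartile boundary ties low. Empty inputs raise or warn
explicitly (empty consensus input, no sample-specific genes, zero-variance
tracks) rather than returning silent zeros.

## Known limitations

* Feature annotation is midpoint-based; a peak spanning a feature boundary
  is summarized by one label.
* The shuffle places markers independently; territory-size fluctuations of
  overlapping shuffled peaks are accepted as part of the null, matching the
  "length-matched uniform placement" definition rather than exclusion-aware
  alternatives (GAT/regioneR-style local constraints are out of scope).
* The probe-density unit (probes per kb, midpoint membership) is one
  defensible convention; platforms reporting densities per probe-window
  would need the tolerance set explicitly.
* Liftover between assemblies is unsupported; all tracks must share one
  coordinate space.
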