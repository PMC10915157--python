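# Methods

This note documents the models, parameter choices and numerical
conventions behind `gametemap`, and what the synthetic benchmarks do and
do not establish about real data.

## The synthetic gamete generator

The generator (`simdata`) emulates single-gamete genotype data from an
F1 hybrid between two inbred strains, at configurable scale.  Its
defaults describe the study system the package targets:

| parameter | default | meaning |
|---|---|---|
| `error_rate` | 0.035 | genotype miscall probability per observed site (sequencing accuracy 96.5%) |
| `dropout_rate` | 0.5 | fraction of map sites unobserved per cell (per-allele capture in diploids) |
| `xo_rate_per_mb` | 0.0044 | expected crossovers per chromatid per Mb (≈ 11 autosomal crossovers per gamete at mouse-genome scale) |
| `obligate` | on | every bivalent receives ≥ 1 crossover; each chromatid inherits each crossover with probability 1/2 |
| `interference_shape` | 5 | gamma renewal shape (1 = no interference) |
| `sv_missing_rate` / `sv_flip_rate` | 0.05 / 0.02 | missing and flipped entries of the SV genotype matrix |

**Crossover interference** is modelled generatively as a stationary gamma
renewal process: inter-crossover distances are Gamma(shape, scale) with
the scale set so the expected event count on the chromosome matches the
rate model.  Stationarity is achieved by burn-in from ten mean gaps
before the chromosome start.  Shape 1 recovers a Poisson process
(exponential gaps — verified by a KS test in the suite); larger shapes
push adjacent crossovers apart, the qualitative phenomenon interference
denotes.  The shape default of 5 produces a median adjacent-distance
inflation of roughly 1.4–1.5× over the uniform null at mouse-like rates,
a strength chosen to be clearly detectable at desk scale; it is not a
fitted biological constant.

**Allele support counts.** Each called allele carries `1 + Poisson(1)`
supporting reads.  This is a minimal model that keeps the allele-count
genotyping rule exercised; it does not model amplification-depth
structure.

**Non-haploid cells.** A diploid contaminant carries both full-length
parental genomes; each allele is captured independently with probability
`1 − dropout`, so covered sites are heterozygous (both captured) or a
random homozygous call (one captured) — exactly the signature that makes
the non-continuity score explode.  A gained chromatid defaults to the
*reciprocal crossover product* of the retained chromatid (same exchange
points, opposite parental phase): this is the chromatid pair an MI
nondisjunction co-segregates, it differs from the retained chromatid at
every site, and it produces the whole-chromosome heterozygosity and
switch-rate elevation the three-signal aneuploidy screen keys on.
`gain_origin="homolog"` (an independent chromatid, which can share long
identical stretches and dilute the signal) and `"sister"` (identical,
detectable only through read depth) are available for sensitivity
analyses.  A lost chromosome or sub-interval simply yields no
observations.

**What the generator does not model:** read-level data (FASTQ),
sequencer-specific error profiles, GC/mappability bias, structured
(non-uniform) dropout, crossover hotspots along the chromosome, and
ligation-efficiency effects.  Passing the recovery benchmarks therefore
shows the *algorithms* are correct and calibrated at the stated noise
levels, not that real libraries meet those noise levels.

## Crossover decoding

Hidden parental states form a symmetric two-state chain with initial
probabilities 0.5/0.5, emission 0.99 and per-step transition 0.2 between
adjacent retained sites (the published constants; both exposed in
configuration).  The transition is per retained *pair*, not
distance-scaled — the distance-scaled variant used in SV proofreading is
available behind a flag.

**Bidirectional filtering consensus.** The decoder computes the running
filtered posterior `P(s_i | o_1..i)` forward along the chromosome and
again on the reversed sequence, takes the MAP state of each pass, and
keeps only sites where the two agree.  Viterbi would be the conventional
decoder, but on a symmetric stationary chain the Viterbi path is
direction-invariant, which would make a forward/reverse consensus
vacuous; the filtering interpretation preserves the consensus step's
purpose of flagging direction-discordant sites.  Exact posterior ties
(|p − 0.5| ≤ 1e−12) are also marked ambiguous.  Ambiguous sites are
excluded from segmentation and support counts.  A consequence worth
knowing: at a genuine crossover the one or two flanking sites are
usually ambiguous (the forward pass still credits the last old-state
site to the old run while the reverse pass already assigns it to the
new one), so crossover intervals are effectively bounded by the nearest
concordant markers.  A Viterbi mode is provided as an alternative
decoder.

**Support filter.** Runs with fewer than `min_snps` supporting SNPs *or*
spanning less than `min_span = 0.5 Mb` are deleted iteratively — weakest
first (fewest SNPs, then shortest span, then leftmost) — with same-state
neighbours merged after each deletion, to a fixed point.  Deleted sites
do not count as support of the merged run.  The filter applies to every
run, including terminal ones.

`min_snps` is fundamentally a *marker-density-scaled* quantity: the
published value of 100 SNPs corresponds to roughly 1 Mb of markers at
the ~100 observed hetSNPs/Mb of a full-scale dataset.  The package keeps
100 as the default, and the synthetic benchmarks (17 observed
markers/Mb) use the bp-equivalent value of 17 so that the filter vetoes
the same physical scale of pseudo-crossover in both regimes.  Applying
the raw count at sparse density would blind the caller to every
crossover within ~6 Mb of a chromosome end, which is a property of the
mismatched filter, not of the method.

**Summaries.** A crossover's point position is its interval midpoint
(the data only bound it between flanking markers).  Density profiles use
half-open windows (default 1 Mb) and a normalized coordinate
midpoint/length ∈ [0, 1].  The interference null re-places, per
cell-chromosome with ≥ 2 crossovers, the same number of crossovers
uniformly at random; for two crossovers the null median adjacent
distance has the closed form `(1 − 1/√2)·L`, which the acceptance suite
verifies to 1% at 10⁵ replicates.  Observed and null distributions are
compared with a two-sided rank-sum test.

## Ploidy and aneuploidy screening

**Non-continuity** is the frequency of switches between the two
homozygous parental genotypes along a chromosome, after dropping
heterozygous and missing calls (a het call carries no parental signal in
a haploid); it is normalized by the number of adjacent pairs so scores
are comparable across coverage (a raw-count mode exists).  The per-cell
screening statistic sums the autosomal scores excluding the single
highest autosome, so one gained chromosome cannot masquerade as
diploidy.  Sex chromosomes never contribute.

**Inflection detection** re-implements the extremum-distance estimator
idea: sort the per-cell scores, draw the chord between the endpoints,
find the point of most-negative distance (the convex elbow, i.e. the end
of the haploid plateau), and place the threshold at the steepest rise of
the curve at or beyond the elbow.  A curve that never leaves the chord
by more than 0.1% of its range (a linear ramp) yields a "no inflection"
sentinel and all cells are treated as haploid.

**Aneuploidy** uses three per-chromosome statistics — hetSNP recall,
heterozygosity rate, non-continuity — each converted to a robust z-score
against the median/MAD of the *same cell's other autosomes*.  The MAD of
~9 values is a noisy scale estimate, so it is floored at the binomial
standard error of the median rate at the chromosome's site count; this
keeps euploid z-scores calibrated without touching real signals, which
sit tens of floored-MADs out.  A gain requires both the non-continuity
and heterozygosity z above the threshold (default 5); a loss requires
the recall z below −5 (a fully silent chromosome scores against a
baseline recall of ~0.5 with a floor of ~0.02, i.e. z ≈ −22).  Cells
with more than half of their autosomes deviant are flagged as
amplification artifacts.  Sub-chromosomal gain/loss (e.g. gain of the
top quarter with loss of the rest) is resolved by enabling interval-level
statistics (equal subdivisions of each chromosome); exact numeric
criteria for "elevation" are not published, so the z-rule and threshold
are deliberate package choices, exposed in configuration.

**QC and doublets.** Cells pass QC with genome coverage strictly above
1% (the boundary case fails; documented convention).  The cross-species
doublet rule flags cells whose minor genome exceeds 10% of reads.  Sex
assignment thresholds the X read fraction at 0.8/0.2 — the published
signal is qualitative ("number and ratio"), the cutoffs are ours and
configurable.

## Uniformity statistics

Spikiness is `Σ|x_{t+1} − x_t| / Σ x_t` over retained (non-blacklisted)
bins, with adjacent pairs never spanning a chromosome boundary.  The
entropy statistic is standard Shannon entropy of the bin proportions
(zero-count bins contribute 0), in nats by default with the base
configurable — the role of the statistic (uniformity of the read
distribution) pins the formula even though printed renditions of it are
often garbled.  The CV uses the population standard deviation by
default, with `ddof=1` as a logged switch; bins are aggregated to the
target scale by summation and partial terminal bins are retained.
Blacklisted bins are removed before any computation, so all three
metrics are invariant to the counts they contain.

## SV phasing

The genotype matrix is presence-coded: 1 — the cell carries the SV
(breakpoints within ±100 bp and length within ±100 bp of the benchmark
record), 0 — the locus is covered by reads with no SV call, missing —
uncovered.  A cell carries an SV exactly where its local ancestry equals
the SV's carrier haplotype, so a single cell's column is *not* piecewise
constant; but the XOR of two cells' columns cancels the carrier labels
and leaves the XOR of their ancestry mosaics, which is.  All HMM
decoding in this module therefore operates on pairwise agreement
vectors, with the distance-scaled transition
`P(d) = 1 − e^(−d·10⁻⁸)` (d = bp between adjacent framework loci;
missing entries skip the emission but the gap still accumulates).

Pipeline stages and their published constants:

1. **Framework selection** — loci genotyped in ≥ 5 cells; top 100 cells
   by SV total (ties by cell identifier); loci carried by ≥ 3 retained
   cells.
2. **Leave-one-out proofreading** — for each held-out cell, every other
   cell's agreement vector is decoded; a locus where more than 5 cells —
   or at least half of the informative cells, provided at least 4 are
   informative (a lone informative pair at a crossover boundary must not
   decide alone) — contradict the held-out cell is tallied against it.
   Rows wrong in > 5 cells are excluded as error-prone; rows wrong in
   < 3 cells have the flagged entries flipped; the published rule is
   silent on the [3, 5] gap, which is left unchanged and reported.
3. **Imputation** (`nSPT = 2`) — a missing entry is imputed only when a
   supporting cell's agreement relation with the target is constant over
   more than nSPT consecutive informative loci on at least one side, and
   *all* implications across cells and sides agree; any conflict —
   including the two sides of a crossover implying opposite values —
   leaves the entry missing.
4. **Assembly** — loci with ≥ 2 residual missing entries, then cells
   with any, are dropped; each cell is relabelled to a common frame via
   its decoded agreement mosaic with a reference cell, with runs shorter
   than `cvlink = 2` loci flipped as errors; the per-locus majority is
   corrected for the reference cell's own crossover mosaic, whose
   breakpoints are identified as the inter-locus gaps where more than
   half of the pairwise mosaics switch.  The result is defined up to a
   global per-chromosome label swap, and the precision metric maximizes
   over it.

SV benchmarking follows the published matching rules (±500 bp
breakpoints for insertions, ≥ 1 bp interval overlap for deletions, ±100
bp length tolerance in both), single-linkage merging at ≤ 500 bp
breakpoint distance with a member-wise median representative and a 50 bp
minimum size, and single-crediting of benchmark records in the precision
computation so split calls cannot inflate it.

## Benchmark problem sizes

The simulation benchmarks run at desk scale, chosen to keep the full
suite within a few minutes while leaving each statistic comfortably
powered: crossover recovery uses 20 seeds × 200 gametes on one 150 Mb
chromosome with 5000 markers; the diploid screen 20 seeds × (90 + 10)
cells on five 40 Mb autosomes; aneuploidy 20 seeds × (200 euploid + 50
aneuploid) cells on ten 30 Mb autosomes; SV phasing one 100 × 500
matrix; the acceptance script runs the same blocks at 5 seeds.  Full
mouse-scale inputs (4.3 M hetSNPs, hundreds of cells) change memory and
time, not the algorithms.

## Known limitations

* The SNP-phasing consensus and the SV draft-haplotype construction are
  simplified re-implementations with the same contract (truth recovery
  on simulation) as the published external tools they replace; they do
  not reproduce those tools' internals.
* The interference null places crossovers uniformly; reproduction of
  any specific published null median would require the (unspecified)
  density-matched placement, so none is claimed.
* Genotype-level input is assumed; alignment, variant calling and
  read-depth-based CNV segmentation are out of scope (the copy-ratio
  profiler normalizes binned counts only).
* Zygote-style recoding ("heterozygous = maternal") is provided only as
  a preprocessing flag; the paternal genome is not modelled.
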