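# Methods

This note documents the models behind `meioscan`, the parameter defaults
and their justification, the numerical choices of the callers, and what
the synthetic data can and cannot establish about real sequencing
experiments.

## Synthetic genomes and markers

The reference is uniform-random ACGT sequence over a small karyotype
standing in for the marker-bearing chromosome arms of a fly cross: X
(100 kb), chromosome 2 (120 kb), chromosome 3 (120 kb) and Y (40 kb).
These sizes were chosen as the package's working problem size: large
enough that every chromosome carries hundreds of markers and dozens of
read-length-scale features, small enough that a full cohort analysis runs
on a laptop. Because deletion counts per genome, marker spacing, read
length, insert size and coverage are all kept at their experimental
values, per-event detection behaviour does not depend on total genome
length; only the number of events per run does.

Phased SNPs distinguish the two parental haplotypes. Inter-marker spacing
is geometric with mean 500 bp — the memoryless choice consistent with
"randomly placed" markers, matching the observed arm-level densities of
roughly 1/250–1/530 bp when the mean is set accordingly. Parent A carries
the reference base, parent B a uniformly drawn alternate. The male
haplotype contribution (autosomes plus Y, no X) receives its own 1/500-bp
marker set, placed off the maternal marker positions; this models the
selection of cross-informative markers from sequenced isogenized stocks.
Without the exclusion, a male variant coinciding with a maternal marker
site would masquerade as a one-marker conversion tract.

## Meiosis model

Each meiosis replicates the two parental sequences into four chromatids
(sisters identical; no inter-sister events). The DSB count is uniform on
11–24 per meiosis — the literature range for total fly meiotic DSBs — and
positions are uniform over the female genome. Each DSB resolves as:

* **NHEJ** with probability `hr_fail_prob` (no allelic template;
  default 0 for the wild-type condition, 0.8 for the
  heterosynapsis-mutant condition, matching the ~80% loss of
  interhomolog HR). The scar size is drawn from a configurable range;
  the default is 0 bp (scarless). Named presets cover the mechanistic
  scenarios: `clip-2bp` (2–10 bp, overhang clipping), `clip-oligo`
  (50–100 bp, removal of annealed end oligonucleotides) and
  `clip-resected` (500–1500 bp, trimming of long resection tracts).
* **Crossover** with probability `co_fraction` (default 0.25, the lower
  end of the one-third-to-one-quarter range): a reciprocal exchange of
  everything distal to the breakpoint between one chromatid of each
  parent.
* **Noncrossover gene conversion** otherwise: a tract of geometric
  length with mean `gc_tract_mean` (default 400 bp, the middle of the
  350–450 bp estimate), placed symmetrically around the DSB, clamped at
  chromosome ends, copied from one homolog chromatid onto the recipient.
  One-sided placement is a configuration away (`gc_tract_dist`,
  placement in `simulate_meiosis`) but symmetric is the default.

One of the four chromatids is sampled as the offspring; consequently one
half of crossovers and one quarter of conversions are visible in a
sequenced offspring, and only conversions whose tract covers at least one
informative marker are detectable at all (probability
`1 − exp(−L/spacing)` under geometric spacing, ≈ 0.55 at the defaults).

A rare subtlety: an NHEJ scar drawn over an existing scar on the same
chromatid is truncated to its non-overlapping part (dropped if empty), so
the recorded truth always matches the materialized sequence. With default
parameters this affects well under 1% of scars.

## Read simulation

Paired 100-bp reads are sampled uniformly over the supplied haplotype
sequences with Normal(400, 40) fragment lengths that never cross a
chromosome boundary; mate 2 is the reverse complement of the fragment
end. Substitution errors are applied per base (default 0.001); there are
no indel errors, quality-profile models or duplicates — sensitivity
claims are therefore made under a clean error model and verified at both
0 and 0.001 substitution rates. Base qualities are a constant Phred 30.

**Coverage convention.** `coverage` is the fold-coverage of each supplied
sequence: the pair count is `ceil(coverage · total_len / (2 · read_len))`
with `total_len` the summed length of all supplied haplotypes. This is
the convention of per-sequence read simulators (one run per haplotype
FASTA, outputs pooled), so a diploid locus sequenced "at 10×" has ~10
reads over each haplotype copy and ~20× total depth, and a heterozygous
deletion junction is covered by ~10 junction reads.

## Read mapping and deletion calling

The mapper indexes unique reference 21-mers (ambiguous k-mers are
dropped; on near-random synthetic sequence effectively none are) and
anchors four non-overlapping seeds per read, trying the reverse
complement when no seed hits. Reads whose seeds agree on one diagonal are
verified ungapped with at most 5 mismatches. Seeds on two diagonals imply
a reference gap: the junction is placed to maximize matched bases, the
gap is left-normalized, and the read becomes a gapped alignment (gap ≤
50 bp) or a split alignment (up to 100 kb). Reads that fail all of this
are kept as soft-clipped anchors. Sentinel padding between chromosomes
guarantees no alignment window crosses a boundary. Everything is
vectorized over the read batch and deterministic.

Small deletions are called by clustering gapped alignments on (start,
size) within ±2 bp; the consensus is the modal exact pair. Soft-clipped
reads anchored nearby are then re-genotyped against the candidate
deletion allele and added to the support count — the local re-evaluation
step that rescues junction reads whose short flank defeats seed
anchoring. A call requires `min_support` = 3 supporting reads (at ~10
junction-covering reads per heterozygous deletion this leaves ample
margin; the Poisson tail below 3 reads is the main residual miss mode).

Large deletions are called from split-read breakpoint voting (±5 bp) with
discordant insert-size pairs (observed span > mean + 3 SD) as
corroboration. Discordant pairs alone can support a call only in groups
of ≥ 3 with mutually consistent inner intervals **and** a median implied
size ≥ 4.5 insert SD; below that the 3-SD tail of the insert distribution
(~0.1% of pairs) produces chance clusters, which is exactly the
false-positive mode the threshold removes. Calls are deduplicated across
callers by reciprocal overlap ≥ 0.5, preferring gapped over split over
insert evidence. With substitution-only errors and unique anchors, a
spurious gapped or split cluster of three agreeing reads essentially
cannot arise, which is why deletion-free cohorts yield exactly zero
calls.

Sensitivity is estimated end to end: spike 5–25 heterozygous deletions
per genome onto one of four haplotypes, sample one haplotype as the
offspring, sequence it with the male contribution, map, call, and match
calls to the offspring-carried truth (breakpoints within ±10 bp or
reciprocal overlap ≥ 0.5; each call matches at most one truth event).
The denominator is the truth carried by the sequenced offspring —
deletions on unsampled chromatids are absent from the reads and not
meaningful targets. Reports give 50-bp size bins with exact binomial CIs.

## Recombination calling

Offspring genotypes come from a pileup of ungapped alignments at the
parental marker sites. A site is called for the alternate parent ('B')
with ≥ 2 supporting reads at ≥ 10% of coverage; it is called 'A' only
when **zero** B reads were seen, and left missing otherwise. The
asymmetry is deliberate: at a true B marker the male-derived reference
reads can dominate through a coverage fluctuation, and forcing 'A' there
fabricates a one-marker conversion tract, whereas a missing marker costs
almost nothing.

The per-chromosome haplotype vector is segmented with missing calls never
breaking blocks. An internal block spanning ≤ `max_gc_span` (default
10 kb) flanked by ≥ `min_flank_markers` (default 2) opposite markers on
both sides is a gene conversion (tract_min = converted markers,
tract_max = flanking opposite markers); conversions are excised
iteratively, and remaining block transitions are crossovers with the
breakpoint bracketed by the bounding markers. Thin internal blocks that
fail the conversion rule collapse their transitions into a single event
flagged `ambiguous` (avoiding inflation of double-crossover counts used
for interference); a transition involving a thin terminal block is
flagged `terminal`, since a chromosome-end minority block cannot be
distinguished from a large conversion. The defaults separate 350–450 bp
tracts from crossovers at ~500 bp marker spacing with a wide margin.

Karyotypes are classified from per-chromosome depth normalized to the
autosomal mean: r_X ≈ 0.5 with Y present is XY, without Y is X0, r_X ≈ 1
with Y present is XXY; thresholds (≈0 below 0.05, ≈0.5 within 0.3–0.7,
≈1 above 0.8) are configurable.

## Genetics statistics

Map distance is `100·R/n` with the normal-approximation CI from the
binomial variance, clamped to [0, 100]. For sparse recombinant counts
(np < ~20) that interval undercovers — R = 0 gives a zero-width interval
— so `stevens_ci(method="wilson")` provides the score interval, which
maintains ≥ 93% empirical coverage across the regimes a recombination
assay meets; the default remains the variance formula for continuity
with the classical calculation. Crossover density divides by the
TE-masked span in Mb. Interference reports expected double crossovers
both unrounded and rounded to the nearest integer, the coefficient of
coincidence, and flags the undefined zero-expectation case. %X-NDJ
doubles the viable exceptional classes before forming the corrected
total. Focus-count comparisons default to Welch's unpaired t-test
(unequal group sizes and variances are the norm in germarium counts; the
classical Student variant is a flag away), with zero-variance identical
groups assigned p = 1. Printed percentages round half-up, so 87.5%
becomes 88%.

The NDJ comparison helper is a two-proportion z-test on corrected
totals — an approximation of the contingency-table comparisons used in
the genetic literature, not a reimplementation of any specific one.

## The cohort replica

`run_paper_replica` chains everything: one reference and marker set, a
wild-type truth cohort (default 196 meioses) to fix the expected CO and
detectable-NCO-GC means per offspring, then a mutant cohort (default 28
offspring, `hr_fail_prob` 0.8) taken through reads, mapping, genotyping,
event calling, deletion calling and karyotyping. The report contains
observed versus expected totals, percent reductions, one-sample t-tests,
the expected-deletion table (15 DSBs × 0.8 / 4 chromatids × 28 progeny =
84 expected; floor(84 × 0.85) = 71 detectable if small), and per-sample
karyotypes. `verify_report` recomputes the totals independently from the
emitted event tables. Runs are bit-identical for a fixed config and
seed; a manifest with the config hash is written alongside the outputs.

The expected-detected count for large deletions, floor(84 × 0.65) = 54,
is what the arithmetic yields from the measured large-class sensitivity
bound; a size-weighted variant of this calculation can give smaller
values, and the package reports only the unweighted form.

## Numerical and degenerate-input choices

* All coordinates are 0-based half-open internally; VCF output is
  1-based, with anchor-base REF/ALT records for deletions ≤ 50 bp and
  symbolic `<DEL>` + `END` above.
* Every stochastic operation takes an integer seed; derived seeds are
  drawn below 2³¹.
* Deletion spiking resamples collisions up to 100 times, then raises.
* Conversion tracts and exchanges beyond chromosome bounds are clamped
  and recorded as realized.
* `mean_spacing` < 2, zero-length chromosomes, duplicate names, empty
  references, all-missing haplotype vectors, zero progeny and
  fully-masked spans all raise `ValueError` rather than degrade.

## What the synthetic data does not show

The generator emulates the structure of a progeny-sequencing experiment,
not its noise: no real TE landscape or repeats (mapping ambiguity is
near-absent by construction), no indel sequencing errors, no
quality-score structure, no PCR or optical duplicates, no mapping-quality
recalibration, and no non-allelic homologous recombination or other
structural rearrangements. Sensitivity and zero-false-positive results
therefore characterize the callers' behaviour under the stated error
model, and transfer to real data only to the extent that alignment
ambiguity and error structure are handled upstream. The recombination
caller's exactness on error-free simulations is an algorithmic statement
about segmentation, not a claim about real variant-calling accuracy.
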