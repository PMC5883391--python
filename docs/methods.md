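# Methods

## The coverage model

Map reads to an assembly and tally per-base depth. If the genome is diploid
and heterozygous enough for an assembler to separate the two alleles of a
locus into distinct contigs, reads from that locus split between the two
copies and each copy sits near the per-haplotype depth *m*. Loci assembled
as a single diploid consensus receive reads from both haplotypes and sit
near 2*m*. Repeat families represented in the assembly by fewer copies than
exist in the genome concentrate the reads of all copies onto the surviving
exemplars, far above 2*m*. Bases near contig ends, mis-joins and other
breakpoints fall below *m*. The depth histogram of such an assembly is
therefore a mixture: a dominant peak at *m*, a shoulder near 2*m*, a
low-coverage shelf and a high-coverage tail — and the mixture's masses
measure how much of the assembly is in each state.

### Peak detection (`covprof.fit_peaks`)

The histogram is smoothed with a centred moving average of width
`smooth_bandwidth` (default 5 depth units; the histogram is unit-spaced and
the structures of interest are tens of units wide, so light smoothing only
suppresses count noise). The mode is the argmax of the smoothed counts over
depth ≥ 2 — the depth-1 bin is dominated by error and breakpoint artifacts
and is never a credible haploid peak. Smoothing flattens narrow peaks into
plateaus, so argmax ties break toward the largest raw count.

A shoulder is accepted at the smoothed argmax within [1.6·mode, 2.4·mode]
if its height is at least 25% of the mode peak's. The window brackets the
diploid expectation of 2× while tolerating the asymmetry seen in practice
(a shoulder at 1.88× of the mode must be accepted); the height criterion
rejects bumps that are mixture-tail artifacts.

State boundaries prefer detected local minima of the smoothed histogram:
`b_low` is the deepest minimum in (0, mode), `b_mid` the deepest in
(mode, shoulder) — or (mode, 2·mode) when no shoulder — and `b_high` the
deepest above the shoulder (capped at 4·mode). When a minimum does not
exist the boundaries fall back to mode/3, 1.5·mode and 2.5·mode, and the
`fallback` map records which, so reports can distinguish detected from
assumed boundaries.

### The partition (`covprof.partition_states`)

Bases with 0 < depth ≤ `b_low` are BREAKPOINT, (b_low, b_mid] HAP_SEP,
(b_mid, b_high] COLLAPSED, above `b_high` REPEAT. Zero-depth bases are a
separate diagnostic, not a state: an uncovered base says nothing about
ploidy structure. The partition conserves bases exactly — spans plus
zero-depth always equal the histogram total — and implies a haploid-size
lower bound of HAP_SEP/2 + COLLAPSED: separated bases are counted once per
haplotype pair, collapsed bases at face value, and repeat bases not at all
(they stand for an unknown, larger genomic span), which is what makes it a
lower bound.

Per-contig classification assigns each contig the state holding a plurality
of its covered bases; ties go to COLLAPSED, the conservative call for
genome-size purposes.

## Genome-size estimators (`sizeest`)

* **Coverage extrapolation.** diploid = aligned bases / mode, haploid =
  diploid/2. The numerator is the contig-side aligned total (for long reads,
  the span of contig sequence covered, not the read-side total inflated by
  insertions); the mode is the per-base depth of unique haplotype-separated
  sequence. Homogeneity holds: scaling both inputs equally leaves the
  estimate unchanged.
* **Duplication adjustment.** haploid = span · (1 − d/2), where d is the
  fraction of universal single-copy orthologs found complete and duplicated,
  taken as a proxy for the haplotype-duplicated fraction of the assembly.
  Collapsing each duplicated pair removes half of the duplicated span, hence
  d/2.
* **Partition bound.** As above; flagged `lower_bound`.

Estimates are consolidated side by side with their spread (max − min);
no averaging, since the methods measure subtly different things.

Report rounding is decimal half-up to 2 decimals in Gbp. A printed
diploid/haploid pair halves the *rounded* diploid figure, so the displayed
chain is internally consistent (4.47 → 2.24 rather than the 2.23 that raw
halving plus rounding would give); raw values are retained in JSON.

## Alignment multiplicity (`multiplicity`)

`best_per_query` solves weighted interval scheduling per query sequence:
the maximum-weight set of query-disjoint alignments with weight
alnlen × identity (= matched bases). Strict disjointness approximates the
one-best-alignment-per-position filtering of whole-genome aligners, which
tolerates slight overlaps; ties break deterministically (higher identity,
longer alignment, then name). `classify_multiplicity` then categorizes a
reference contig iff a single retained alignment covers ≥ `min_cov`
(default 50%) of it; N counts distinct query *contigs* — not alignments —
with such coverage, matching the interpretation of 1:2 as "the two
haplotype contigs". Fractions are weighted by reference contig length, and
uncategorized contigs are reported explicitly rather than dropped.
`containment_stats` reports, over alignments of at least `min_aln_len`
(default 1 kb), the reference-base fraction in contigs with any qualifying
alignment and with single-alignment coverage above each requested level.

## Mapping metrics (`mapstats`)

Concordance delegates to the SAM proper-pair flag rather than re-deriving
insert bounds — the flag is what mappers actually emit, and the synthetic
aligner sets it by an explicit rule (below). Pair classes are an exact
partition: concordant (both mates mapped, proper), discordant, single-end
only, unmapped. Site multiplicity counts distinct concordant placements per
pair, which requires an alignment source that reported all candidate sites;
with single-best input the operation refuses rather than mislabeling
everything "one site". The disagreement rate is ΣNM / Σ aligned read bases
over primary mapped records and is meaningful for end-to-end alignments,
where clipping cannot hide disagreement.

## The synthetic-data generator (`synthio`)

The generator emulates the diploid situation end to end:

* **Genome.** A single chromosome per haplotype. Unique loci (~50 kb,
  ±20%) interleave with repeat loci — one copy of an ~8 kb repeat unit
  each, from 4 families, filling `repeat_fraction` (default 10%) of the
  haploid span. Haplotype B derives from A at `het_rate` (default 0.005)
  heterozygous events per base: 90% SNVs, 10% indels of 1–3 bp. Indels are
  kept short and rare so coordinate bookkeeping between haplotypes stays an
  exact piecewise-offset map while non-SNV divergence is still exercised.
  Copies within a repeat family are identical on haplotype A, so
  multi-placement of repeat reads is exact.
* **Assembly.** A state plan gives genome fractions for HAP_SEP, COLLAPSED
  and REPEAT_UNDERREP (default 0.6/0.3/0.1). Unique loci are assigned by
  shuffled span quota; HAP_SEP loci emit both alleles (runs of consecutive
  HAP_SEP loci become "haplotig" contigs carrying haplotype B), COLLAPSED
  loci emit haplotype A's sequence — a deliberate convention instead of an
  IUPAC consensus, giving haplotype-B reads a clean analytic mismatch
  expectation of ≈ het_rate against collapsed contigs. Repeat copies are
  omitted except `survivors_per_family` exemplars, whose bases are labelled
  REPEAT_UNDERREP; the primary contig stream breaks at omissions, emulating
  repeat-induced fragmentation. A BED-style truth labels every assembly
  base with exactly one state.
* **Reads.** `depth` is diploid fold-coverage; reads split evenly between
  haplotypes, so each haplotype is covered `depth`-fold — a collapsed locus
  then sits at 2·depth, the diagnostic signal. Long reads are lognormal
  (mean 3 kb, σ = 0.35 — scaled to the 50 kb locus size the way corrected
  long reads relate to real gene-scale loci); short reads are 2×150 bp FR
  pairs with Normal(400, 40) inserts. Errors are uniform substitutions.
* **Oracle aligner.** Each read is placed where its origin locus sits in
  the assembly: haplotype-B reads go to their haplotig when their midpoint
  locus is haplotype-separated, otherwise onto the primary contig through
  the B→A coordinate map (with M/I/D CIGARs across the het indels). Reads
  wholly inside a repeat copy get one placement per surviving family copy —
  primary at the lowest coordinate, the rest flagged secondary, capped at
  10 per read; reads from omitted loci that straddle the unit boundary are
  emitted unmapped. Placements are clipped (soft clips) at contig-run
  boundaries. The proper-pair flag is set when both mates land on one
  contig in FR orientation with the forward mate leftmost and an outer span
  within 4 SD of the configured insert mean. NM is the generative edit
  distance (injected errors + het mismatches + het indel bases); a
  sequencing error landing on a het site is booked twice but observed at
  most once, an O(error·het) relative overcount that is orders of magnitude
  below the test tolerances.
* **Contaminated contig.** For the coverage-shift detector: host reads at
  `depth` over the whole contig, foreign reads at (fold−1)·depth inside the
  insert, both sampled with overhang-then-clip so mean coverage is flat up
  to the boundaries — mirroring how a mapper clips reads that run off a
  foreign sequence, and giving the sharp step the detector looks for.

Everything is driven by `numpy.random.default_rng` seeds; identical
configurations produce byte-identical FASTA/FASTQ/SAM/BED output.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: platform-specific error profiles
(homopolymer indels, quality ramps), chimeric reads, mapping ambiguity from
diverged (non-identical) repeat copies, GC-coverage bias, structural
variation between haplotypes beyond short indels, and a real mapper's
scoring decisions. The oracle aligner is a *truth* mapper: its placements
are exactly right by construction, so recovery results measure the
downstream statistics, not alignment robustness.

## Coverage-shift detection (`breakscan`)

Depth is averaged in non-overlapping windows (default 1 kb) and segmented
by greedy binary segmentation: the candidate changepoint maximises the
weighted between-segment mean difference (the largest SSE drop), and is
accepted if the depth step across it — judged on `min_segment`-sized local
flanks, so an interior insert is not averaged away by long matching
outer flanks — is at least `fold_threshold` (default 2.0). Recursion stops
when segments would drop below `min_segment` (default 5 kb). A segment is
flagged when its mean differs ≥ `fold_threshold`-fold from its neighbours
*and* it is shorter than its combined flanks: the foreign insert is the
local anomaly, not the background. Boundaries are reported at window
resolution. Window and threshold defaults are free parameters chosen to
resolve multi-kilobase inserts at typical long-read depths; a contig
shorter than 3·min_segment is not scanned. `split_at` removes flagged
intervals and returns flanks, removed sequence and an old→new coordinate
map; concatenating flanks and removed sequence reconstructs the original
contig exactly.

## Pipeline and determinism (`report`, `cli`)

The report JSON is the single source; markdown is derived from it. Stages
with missing inputs are skipped with an explicit reason. Provenance embeds
the package version, seed and full config echo, and every number in the
report is reproducible by calling the underlying operation with that echo.
JSON is written with sorted keys and no timestamps, so identical config and
seed give byte-identical output. Logging (including stage timings) goes to
stderr only.

## Problem sizes used in the tests

Unit and property tests run on 100–500 kb genomes; the recovery suite runs
ten seeded replicates of a 2 Mbp haploid genome with 30× long and 20× short
truth alignments, and 100 seeded replicates of the contaminated-contig
detector. These sizes put all the relevant structure (dozens of loci,
hundreds of thousands of reads, well-separated histogram peaks) well above
counting noise while keeping the whole suite fast.

## Known limitations

* Boundary detection degrades when the haploid and diploid peaks are not
  separated (depth below ~15× per haplotype or very high depth variance);
  the fallback boundaries then drive the partition and are flagged as such.
* The duplication adjustment assumes the gene-level duplication rate
  transfers to the whole assembly span.
* The multiplicity classifier inherits the one-best-per-position filter's
  blindness to repeats: omitted-copy loci end up uncategorized, which is
  reported but not resolved.
* `show-coords` parsing covers the tab dialect only; 1 bp query intervals
  cannot encode strand in that dialect and are read as forward.
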