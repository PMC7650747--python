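# Methods

This note documents the models implemented in phage-profiler, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical conventions used throughout.

Coordinates are 0-based, half-open everywhere in the code; report output
converts to 1-based inclusive only where a format demands it. All
randomness derives from one root seed through `numpy.random.SeedSequence`
spawning, so identical inputs give byte-identical outputs.

## Synthetic communities

A community is a list of clusters plus unrelated singletons. Each cluster
is one ancestor genome — i.i.d. bases with P(G)=P(C)=gc/2 — and variants
obtained by substituting each base independently with probability *p* to a
uniformly chosen different base. Substitution-only evolution (indels exist
behind an off-by-default flag) keeps the map from planted divergence to
expected nucleotide identity analytic: ANI ≈ 100·(1−p). Defaults emulate
a small actinophage community: genome sizes 35–60 kb (up to 130 kb for the
long-DTR architecture), GC 45–75%, within-cluster substitution rate 0.02
(≈98% ANI, the relatedness of phages in one sequence-based cluster), and a
divergent singleton with a private domain repertoire.

Domain tables mimic RPS-BLAST tabular output: each genome draws
`domains_per_genome` accessions from its cluster pool (singletons from
disjoint pools), with e-values sampled log-uniformly between 1e-4 and 1e-30
— all below the 0.001 parse cutoff, so the planted repertoire is exactly
what the matrix builder should recover. A `shared_domain_fraction` knob
moves cluster pools from disjoint (perfectly separable) towards identical.

### Read simulation

Reads are generated by a fragmentation model of a sequencing library.
Every packaged DNA molecule is sheared at Poisson breakpoints (mean
fragment length = 2 × read length); one read is taken off each end of every
fragment at least one read long; substitution errors are applied i.i.d.
The number of molecules is calibrated so total bases ≈ target depth ×
reference length (virion length for DTR genomes). The crucial property of
this model is that a molecule's physical ends are fragment boundaries:
coverage stays full to the end and read starts pile up *exactly at* the
terminus. That is the library-chemistry feature that makes genome termini
visible at single-base resolution in real data, and naive uniform read
placement cannot produce it (it yields read-length ramps instead of sharp
steps, which would make base-precise boundary recovery impossible).

Virion architectures:

* **DTR** — the molecule is `repeat + core + repeat`; mapping its reads
  onto the unit genome (repeat assembled once) doubles depth over the
  repeat with single-base steps at both repeat boundaries, plus local
  pileups of terminus-anchored reads just inside each end.
* **HEADFUL_PAC** — molecules are terminally redundant circular
  permutations. A configurable fraction of packaging events (default 0.5)
  starts exactly at the *pac* position — the first headful of a processive
  series — giving a forward-strand read-start pileup there; the remainder
  start uniformly on the circle. Capsid fill varies per molecule: the
  terminal redundancy is drawn uniformly from [0, 2·tr] (tr defaults to 4%
  of genome length), so the genome end is variable and the redundant
  segment decays smoothly instead of stacking into a repeat-like plateau.
* **NONE** — negative control: fragmentation of the bare circle, no
  molecule ends, hence no termini signal at all.

What the generator does *not* emulate: quality-score error profiles,
indel sequencing errors, paired-end inserts, GC-coverage bias, host DNA
contamination, and repeat content within genomes (genomes are i.i.d.
random, so every 150-mer is effectively unique). Passing tests therefore
demonstrate correctness of the detectors under clean mapping conditions,
not robustness to repeat-rich real genomes.

## Read mapping and termini classification

The built-in mapper is exact k-mer seeded (default k=15, probed at
non-overlapping offsets along the read) with ungapped evaluation over the
full read length on both strands; the genome is treated as circular so
headful-permuted reads map across the origin. Reads below 90% identity
stay unmapped; ties break to the leftmost position. This is sufficient for
substitution-only reads and keeps the pipeline dependency-free; SAM export
is provided for interoperability with external mappers.

`detect_dtr` finds the elevated plateau on a depth profile smoothed with a
51-bp circular window (elevated = above the midpoint between the background
median and its ratio-threshold multiple), then refines each boundary to the
largest single-base depth step near the plateau edge. An interval
qualifies if (a) its median depth is ≥ 1.6× the median of the remainder,
(b) it spans ≥ 200 bp and less than half the genome, and (c) *both*
boundary steps are at least half the plateau elevation. The 1.6 default is
deliberately more tolerant than the nominal 2-fold coverage increase —
sampling noise and edge effects pull the plateau below 2× at moderate
depth — while criterion (c) implements "delimited at single base
positions": a true repeat boundary steps by the full extra coverage in one
base, whereas the smoothly decaying elevation downstream of a *pac* site
(terminal redundancy plus start pileup reaches ≈1.5–1.7× locally) has no
sharp far edge and is rejected. Repeats ≥ 2 kb are called DTR_LONG, else
DTR_SHORT; the 2-kb cut interpolates between the ~1-kb and ~12-kb repeats
of short- and long-DTR phages and is configurable.

`detect_pac` flags a position whose strand-specific read-start count
exceeds `peak_factor` (default 2.0) times the 99.9th percentile of all
other start counts on that strand (floored at 1). A genuine *pac* pileup
is orders of magnitude above the Poisson background (~0.1 starts/base at
30×), so the binding constraint is the false-positive rate on unstructured
libraries; doubling the extreme background quantile keeps that below ~1%
per genome while tolerating moderate pileups. A *pac* call is suppressed
whenever a DTR was detected, so one call never carries both signatures.
`classify_termini` additionally requires ≥1000 mapped reads, below which
the genome stays UNDETERMINED.

## ANIb

Fragment size 1020 bp with the 30% identity / 70% aligned-fraction
qualifying thresholds, following the fragment-based ANI convention; all
three are exposed in `ANIConfig`. Fragment alignment is exact 20-mer
seeded on both strands; a fragment sharing no seed k-mer with the reference
is scored unaligned (aligned fraction 0). This is what keeps unrelated
genome pairs at "no ANI" — a forced global alignment of random DNA would
otherwise report ~50% identity. Seeded fragments are aligned over their
full length with edlib's semi-global (query-infix) alignment, and identity
is the normalised edit similarity `100·(len − edit_distance)/len`. This
quantity has a unique optimum (unlike per-column identity, which varies
among co-optimal alignment paths) and equals classical percent identity
exactly for collinear substitution-diverged sequences; the tests verify it
against an independent dynamic-programming oracle. Directed values are
symmetrised by the mean (a one-sided missing value defers to the other
direction), the matrix diagonal is a computed self-ANI of 100, and
clustering uses average linkage on distance 100 − ANI with missing values
imputed as distance 100 so that unrelated genomes join last. Leaves are
sorted lexicographically before clustering, which fixes tie-breaking.

## Domain phyletics

Hit tables are tab-separated with a header (or a caller-supplied column
map); the e-value cutoff is inclusive (≤ 0.001) and unparseable e-values
drop the row with a logged warning. The presence-absence matrix keys on
domain accessions, by default restricted to Pfam-prefixed ones; duplicate
hits collapse to a single presence, and genomes without hits keep all-zero
rows. Ward clustering interprets "Ward" as the D2 criterion — squared
Euclidean distances inside the Lance-Williams update, heights reported on
the Euclidean scale — with a D1 variant available. Cluster assignment cuts
the tree at a count or height; independently, any genome sharing fewer
than `singleton_min_shared` (default 3) domains with every other genome is
re-flagged as its own singleton, quantifying "too divergent to join any
cluster" (no published number exists for this; 3 shared domains is below
any plausible within-cluster overlap and above chance sharing).

The lifestyle flag is genomic *evidence*, not a prediction: a genome is
flagged `temperate-evidence` iff it carries at least one marker domain from
a shipped, editable list (tyrosine/serine recombinase and phage repressor
families); matching is case-insensitive on the accession. Synthetic
communities use artificial accession namespaces, so their flags read
`no-temperate-evidence` unless markers are planted deliberately.

## Congruence and reporting

Partition agreement uses the adjusted Rand index on flat assignments
(cluster-level congruence is what the classifications claim); a
cophenetic-correlation helper exists for tree-level comparison. The
pipeline writes every artifact as plain text (FASTA/FASTQ/TSV/Newick/
BedGraph/JSON), echoes every threshold and seed into the report's
provenance section, aborts with a stage-named error and removes partial
output on failure, and is byte-identical under a fixed seed.

## Problem sizes in tests and the acceptance script

The test suite verifies termini recovery over 50 seeded replicates per
architecture (47 kb / 1 kb DTR, 130 kb / 12 kb DTR, 40 kb headful, 40 kb
unstructured) at 30× depth, 150-bp reads, 0.5% error; ANI calibration on
50-kb pairs at 1/3/5% divergence; Ward heights against a brute-force
Lance-Williams oracle on an exhaustive sweep of small binary matrices
(tie-degenerate instances excluded, since a tied merge sequence is not
unique); and full recovery on a planted 4-cluster + singleton community of
13 genomes (36–49 kb). `scripts/acceptance.py` re-measures the same
quantities with 12 replicates per architecture, which bounds its runtime to
about half a minute while keeping every estimate comfortably away from the
decision thresholds.

## Known limitations

* The ORF scan reports maximal start-to-stop reading frames (ATG/GTG/TTG
  starts, code-11 stops, ≥300 nt, both strands, linear sequence). It is
  not a gene caller: no scoring, no overlap resolution, no genes spanning
  the origin — ORF counts on real genomes will not match curated
  annotation counts.
* cos-type (cohesive-end) termini, assembly and read QC are out of scope;
  only the two coverage signatures above are classified, everything else
  is UNDETERMINED.
* The mapper assumes substitution-only divergence between reads and
  reference; indel-rich reads would go unmapped rather than clipped.
* ANI values are meaningful above the seeding floor (~75–80% identity);
  pairs below it report "no ANI" rather than a number, by design.
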