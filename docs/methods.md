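# Methods

## Overview

`amplicon16s` implements taxonomic classification of full-length 16S rRNA
gene amplicons from long, error-prone reads (nanopore-class data), plus the
evaluation machinery needed to benchmark it: a mock-community scorer,
rarefaction and depth-stability diagnostics, cross-method profile
comparison, and a seeded amplicon simulator that provides ground truth for
every stage.

The classification model is deliberately simple and mirrors direct
read-mapping practice for long reads (OTU clustering at 97% identity is not
meaningful at ~12% read error): each read is aligned against a reference
collection of 16S sequences, the species with the maximum integer alignment
score is assigned, and when several species achieve exactly the maximum
score the read is assigned to their lowest common ancestor (LCA) in the
taxonomy — possibly far above genus when the tie spans distant taxa.

## Preprocessing

Stages run in a fixed order; read counts are conserved exactly at each one
(`input = retained + removed`), and the manifest records every stage count.

1. **Mean-quality pass filter** (`> Q7`, strict). Mean read quality uses
   error-probability averaging, `Q = -10*log10(mean 10^(-q_i/10))`, the
   convention of long-read QC tools; it equals the arithmetic mean of
   per-base scores only when they are all equal.
2. **Primer-anchored trimming.** The forward primer and the reverse
   complement of the reverse primer are located by semi-global alignment
   (edlib) with IUPAC-aware matching, unit mismatch cost, indels allowed,
   default `max_mismatches = 3` per site. Both strands are searched and the
   orientation with the smaller combined edit distance wins; reverse-strand
   reads are flipped. The retained span runs from the start of the forward
   site to the end of the reverse site — primers stay inside the amplicon,
   keeping read lengths comparable to reference 16S genes. Among equally
   good placements the forward site takes the leftmost and the reverse site
   the rightmost location, so end-to-end dimer artifacts keep their full
   length and are removed by size selection rather than silently rescued.
   Reads with only one locatable primer site (truncated fragments) are
   untrimmable — a status, not an error.
3. **Size selection**, inclusive on both ends: 1300–1950 bp for V1-V9,
   350–600 bp for V3-V4 (inclusivity is this package's choice; the window
   endpoints are standard). This removes amplicon dimers (~2x size) and
   residual short fragments.
4. **Seeded subsampling** without replacement (one documented generator,
   `numpy.random.default_rng(seed)`; the seed is recorded in the manifest).
   Mock evaluation defaults to 3000 reads, community profiling to 20,000.
5. **Low-complexity masking.** DUST-style triplet scoring over 64 bp
   windows (half-window step), threshold 2.0; masked positions are
   lowercased, never removed, and are excluded from alignment seeding only.
   This serves the same role as HMM-based repeat maskers (protecting
   seeding from simple repeats) while being deterministic and
   dependency-free.
6. **Host screening** (optional): a read is host-derived when its best
   local alignment score against the host reference reaches `min_score`
   (default 200 = a perfect 100 bp match); everything else is treated as
   bacterial.

## Alignment

The built-in aligner is a seed–chain–extend local aligner:

* **Seeding:** shared k-mers (default k = 13) against an index over every
  unmasked position of both strands of every reference.
* **Chaining:** seeds are clustered by diagonal per (reference, strand);
  a cluster needs at least 3 seeds to make its reference a candidate.
  Candidates whose seed count falls below half the best candidate's are
  pruned — a genuine score tie involves near-identical references with
  near-identical seed counts, so pruning cannot remove a tie member. At
  most 10 candidates are extended.
* **Extension:** banded local alignment with affine gaps under
  match +2, mismatch −4, gap open −4, gap extend −2 (a gap of length L
  costs open + L·extend). The band covers the seed-cluster diagonal range
  plus a margin; total band width defaults to 0.15 x read length, matched
  to nanopore indel rates. Scores are exact integers; tests verify equality
  with a full (unbanded) dynamic-programming oracle on short instances.
* Hit identity is computed by global edit-distance alignment (edlib) over
  the reported spans; it is reported in hits and PAF output but plays no
  role in classification, which uses scores only.

Reads whose best hit falls below `min_score` (default 100) are
unclassified. External long-read mappers can replace the built-in aligner
through PAF import (`AS:i` score tag preferred, match count otherwise).

## Classification and profiling

Strain-level reference taxa are rolled up to species before the tie set is
built, so two strains of one species never force an LCA above species.
Canonical ranks are root > domain > phylum > class > order > family >
genus > species > strain; NCBI `superkingdom` maps to domain, all other
rank names to `no_rank`, which stays in lineages (keeping LCA exact) but is
transparent to rank rollup.

Profiles tally classified reads at a requested rank via rollup; reads
assigned above that rank land in an explicit unassigned-at-rank bucket.
Relative abundances are percentages of classified reads (host, filtered
and unclassified reads are excluded). Taxa below 0.01% of total reads are
discarded (strictly below: at 20,000 reads, a 2-read taxon survives, a
1-read taxon does not).

Evaluation statistics:

* **Mock scoring:** per read and rank — correct (rollup matches the read's
  own truth), unclassified (no taxon at that rank), misclassified
  (anything else); the three percentages sum to 100. Per-genus species
  accuracy = among genus-correct reads, the fraction with the correct
  species.
* **Ambiguous fraction:** ambiguous-LCA reads as a percentage of all
  classified reads.
* **Rarefaction:** detected species (>= 1 read, deliberately without the
  0.01% filter — the filter is depth-dependent and would distort
  saturation) vs subsampling depth, mean and sd over seeded replicates.
* **Depth correlation:** Pearson r between species relative-abundance
  vectors at two depths, over the union of detected species with absent
  taxa as 0 (no log transform — the simplest reading of heat-map style
  comparisons; alternatives can be built from the exported tables). The
  correlation is over abundance vectors, not detected-species counts.
* **Method comparison:** union of each profile's top-15 taxa, long-format
  table plus pairwise Pearson r (r and n only; significance testing of the
  correlations is out of scope).

## Simulator

The simulator emulates the observable structure of amplicon sequencing
runs, not sequencing physics:

* **References:** a random ancestor (~1.44 kb: 20 bp forward primer site +
  1400 bp interior + 20 bp reverse site) evolved by per-site substitution
  along a genus/species tree. Defaults: ~4% divergence within genera, ~12%
  between; primer-binding blocks implanted verbatim (one concrete expansion
  of each degenerate primer) unless a species is configured with genuine
  primer mismatches. No secondary-structure realism is attempted.
* **PCR bias:** member weight = fraction x (1 + E)^n with per-cycle
  efficiency E = E0 · m^w, where w counts primer-site mismatches with
  3'-terminal (last 5 bases) mismatches weighted t-fold. Defaults E0 = 0.9,
  m = 0.5, t = 3, n = 35 cycles (matching a 35-cycle amplification
  protocol). The functional form is this package's model; the underlying
  phenomenon is the well-documented underrepresentation of
  primer-mismatched taxa. The model is monotone: more mismatches never
  increase a member's amplified share.
* **Reads:** templates drawn multinomially from the pool; per-base
  substitutions/insertions/deletions (nanopore-like default 6%/3%/3%,
  ~Q9); random strand; per-base qualities drawn uniformly in
  target_mean_q ± 3 rather than linked to the simulated errors — the
  mean-Q filter behaviour is what matters downstream. Artifacts: truncated
  fragments (random cut keeping one primer site) and head-to-tail dimers of
  two independently drawn amplicons (truth records the first). All
  randomness flows from explicit seeds; identical configurations give
  byte-identical FASTQ.
* **Communities:** even mixes, or lognormal(σ) abundances (fecal-like,
  default σ = 1.5) with optional genus-level dominance boosting.

What passing simulated benchmarks does *not* show: robustness to real 16S
secondary structure and conserved-region homology across distant taxa,
chimeras formed mid-PCR, reference databases with mislabelled or missing
taxa, or basecaller-specific error structure (homopolymer compression).
Those effects are why real mock communities (e.g. *Bacillus cereus* group,
*Escherichia*/*Shigella*) show species-level failures that the simulator
reproduces only through its explicit confuser pairs.

## Benchmark designs and problem sizes

* **Even mock (noisy):** ten community species in ten genera; the
  reference set adds a ~1.5%-divergent sister species to two genera
  (confuser pairs, mimicking *Bacillus*/*Escherichia*-type ambiguity);
  the seven well-separated singleton genera (sorted by name) are the
  designated set scored for per-genus species accuracy. 3000 reads at
  ~12% error, 2% truncation, 1% dimers.
* **Noiseless mock:** plain ten-species set, even community, zero error
  and artifact rates; the filtered species profile must hold exactly ten
  species.
* **Fecal-like:** 150 species in genera of 1–6 members, lognormal σ = 1.5
  abundances, 60,000 nanopore-like reads; species-abundance Pearson r
  between 20,000- and 30,000-read subsamples of the classifications.

These sizes run the full pipeline in minutes on a single CPU and were
chosen as the smallest instances that exercise every stage at realistic
parameter values.

## Numerical and design choices

* Tie definition is exact integer score equality; no epsilon is needed
  under an integer scoring scheme.
* Coordinates are 0-based half-open throughout; hit spans are always on
  the forward reference coordinate system with strand recorded.
* `lca({x}) = x`; LCA of an empty set is an error. Rollup returns nothing
  (rather than erroring) when a lineage skips the requested rank.
* Depth-correlation and rarefaction subsample classifications, not raw
  reads — classification is deterministic per read, so this is equivalent
  and much cheaper.
* Candidate pruning (seed-count ratio 0.5, cap 10) and read-side seeding
  stride are the only deliberate approximations in the aligner; both are
  configurable through `Scoring`.

## Known limitations

* The trimmer is a functional stand-in for adapter/barcode-trimming
  workflows of specific vendors; exact trimmed-read counts from real runs
  are not reproducible here. At ~12% read error with `max_mismatches = 3`
  per 20 bp primer site, roughly a third of simulated reads are
  untrimmable; real workflows that trim adapters rather than primers
  retain more.
* The aligner targets amplicon-vs-gene comparisons (kilobase scale); it
  indexes whole host references but is not a general-purpose genome
  mapper.
* Percentages are reported without multiple-testing machinery or
  uncertainty; the simulator's replicate seeds are the intended route to
  spread estimates.
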