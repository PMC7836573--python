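# amplicon16s

Taxonomic classification of **full-length 16S rRNA gene amplicons** from
long, error-prone reads (nanopore-class data), with the evaluation tooling
used to benchmark such pipelines: mock-community scoring, rarefaction and
depth-stability diagnostics, cross-method profile comparison — and a
seeded amplicon **simulator** (degenerate-primer PCR bias + nanopore error
model) that makes every stage testable with known ground truth.

It is written for microbiome researchers who want species-level community
profiles from V1-V9 (or V3-V4) amplicon reads, and for method developers
who need a transparent, fully reproducible reference implementation of the
direct read-mapping + LCA approach.

## The method

Amplicon reads are processed as:

1. mean-quality pass filter (`Q > 7`, with `Q = -10·log10(mean 10^(-q_i/10))`),
2. primer-anchored trimming (IUPAC-aware, both strands),
3. size selection (1300–1950 bp for V1-V9; 350–600 bp for V3-V4),
4. seeded subsampling, DUST masking, optional host-read removal,
5. alignment against a 16S reference collection by seed–chain–extend with
   banded affine-gap local alignment (match +2, mismatch −4, gap open −4,
   gap extend −2),
6. per-read assignment: the species with the maximum alignment score
   wins; when several species tie at exactly the maximum score the read is
   assigned to their **lowest common ancestor** (LCA) — a read tied between
   two congeneric species lands on the genus, and a tie spanning phyla
   falls all the way to the domain,
7. rank-level relative-abundance profiles over classified reads, with
   taxa below 0.01% of total reads discarded.

Error-tolerant best-hit mapping plus LCA is the standard alternative to
OTU clustering for long reads, where ~10% per-base error makes 97%
identity thresholds meaningless. See `docs/methods.md` for the model
details, simulator assumptions and design choices.

## Worked example

`examples/01_mock_classification.py` simulates an even ten-species mock
community (two genera get a near-identical sister species in the reference
set, mimicking *Bacillus*- or *Escherichia*-type confusers), sequences it
as 600 full-length V1-V9 reads at ~12% error, runs the pipeline and scores
the result:

```text
stage counts: {'input': 600, 'pass_q': 600, 'removed_low_q': 0, 'trimmed': 446,
 'untrimmable': 154, 'size_selected': 442, 'removed_by_size': 4, 'subsampled': 442,
 'host': 0, 'non_host': 442, 'classified': 442, 'unclassified': 0}
  genus: correct 100.0%  misclassified 0.0%  unclassified 0.0%  (n=442)
species: correct 100.0%  misclassified 0.0%  unclassified 0.0%  (n=442)

per-genus species accuracy (designated = well-separated genera):
  Genus03     100.0%
  ...
  Genus09     100.0%
```

Reading the numbers: 154 reads are untrimmable (truncated fragments carry
only one primer-binding site; at 12% error some intact reads also exceed
the 3-mismatch primer budget), 4 reads fail size selection (amplicon
dimers), and every classified read is assigned to the correct genus and
species; the per-genus table is the species-accuracy statistic reported
for the seven genera without a confuser.

Other examples: `02_primer_bias.py` (a 3-mismatch forward-primer site
collapses a member from a true 25% to ~0% of the amplified pool — why
degenerate primers matter), `03_rarefaction_depth.py` (species
accumulation and abundance stability vs depth), `04_compare_methods.py`
(top-15 genus table and pairwise Pearson r between error regimes).

The `amplicon16s` command exposes the same stages as subcommands
(`simulate`, `preprocess`, `classify`, `profile`, `eval-mock`, `compare`,
`rarefy`, `run`); try `amplicon16s --help`.

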