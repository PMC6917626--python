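# Methods

## Overview

The package implements a specimen-level ("reverse workflow") barcoding
analysis: individually tagged COI amplicons are demultiplexed to specimens,
each specimen's barcode is called as its dominant read under contamination
filters, barcodes are matched to a reference database by identity
thresholds, reconciled with phylum-level morphotype sorts (criteria C1–C4),
and clustered into MOTUs by objective clustering. A synthetic-data
generator supplies ground-truthed inputs so every stage is testable without
network access or deposited data.

## Tag design and demultiplexing

Tags are 9-bp words over {A,C,G,T} with pairwise Hamming distance ≥ 3 and
no homopolymer run longer than 3, found by seeded greedy rejection
sampling. Distance 3 makes single-error correction sound: for any code with
minimum distance ≥ 2k+1, nearest-tag decoding of a tag carrying ≤ k errors
cannot land on the wrong codeword. The demultiplexer therefore refuses
mismatch budgets ≥ ⌈d/2⌉. Both strand orientations are tried and recorded;
tags and primer stubs are trimmed by position (fixed construct layout), not
by alignment. The default mismatch budget in the analysis scripts is 1;
0 is the conservative library default because the tolerance of the original
laboratory pipeline is not knowable from its outputs.

## Dominant-read calling and filters

Reads are grouped by exact sequence; count ties break lexicographically so
the ranking is deterministic. Definitions, since "coverage" and "total
count" are often left undefined in survey reports:

- coverage — reads identical to the dominant sequence (must be > 50);
- total count — all reads retained for the specimen (must be > 10);
- ratio — second-dominant count / dominant count; ≤ 0.2 passes, values
  strictly between 0.2 and 0.35 are flagged for the C4 re-evaluation, and
  ≥ 0.35 fails (the boundary 0.35 itself fails, following the filter rule
  rather than the inclusive "0.2–0.35" phrasing of the rescue criterion).

All four boundaries are strict inequalities and configurable; the
interpretation used is recorded in the QC output. Dominant grouping is
exact-match by design — no denoising/collapse — because the dominant-read
definition does not imply a similarity radius.

Translation screening uses the invertebrate mitochondrial code (NCBI table
5) by default, configurable to the vertebrate code for chordates. A
sequence is *clean* if any reading frame translates without an internal
stop; with a reference supplied, a clean sequence whose global alignment
shows internal deletions of whole codons is *codon-gap* (retained, the
frame is intact); anything else is *numt-suspect* and treated as a filter
failure by the pipeline.

## Taxonomic assignment

The matcher is a local pairwise aligner (match +1, mismatch −1, gap open
−2, gap extend −1; both orientations; deterministic first-optimal
tie-break) over the supplied reference FASTA. Percent identity uses aligned
columns *including gap columns* as denominator — the closest analogue of
BLAST identity semantics, stated explicitly because it is often left
implicit. Query cover is the aligned query span over query length. Hits
need cover ≥ 80%; rank bands are ≥ 97% species, ≥ 90% genus, ≥ 80% family.
When several hits tie exactly on identity but disagree at the banded rank,
the call is demoted to the lowest rank at which they agree (and which its
band still licenses) — a conservative resolution of the
identical-sequence, conflicting-label situation common in public
databases. Unnamed reference labels are detected by configurable patterns
("sp.", "uncultured", "cf.", blank); such matches keep their rank but are
flagged `named_match = false` and never count as named species
identifications.

The aligner is validated in the test suite against an independent
brute-force Gotoh dynamic-programming oracle on instances ≤ 50 bp.

## Congruence criteria

Congruence is evaluated at the phylum level of the morphotype vocabulary
(zooplankton are sorted to phylum; finer morphology names can be attached
per specimen). C1–C3 apply to passing barcodes in order; C4 applies only to
flagged ones and requires all four of: ratio strictly inside (0.2, 0.35),
coverage and count filters met, dominant read ≥ 85% identity to a
morphotype-congruent taxon, and a second dominant read that does *not*
match the morphotype (an unmatched second dominant counts as non-matching).
`image_consistent` — the judgement that specimen photographs agree with the
barcode match — is a curated input defaulting to false, so C3 can never
fire without explicit human review. Rejected specimens keep their
morphology name when one exists.

## Distances and MOTU clustering

Distances are uncorrected p-distances on a common alignment. Terminal gap
columns are excluded; pairs overlapping fewer than 100 columns are
incomparable (NaN), which keeps 313-bp and 658-bp barcodes comparable over
their shared region while refusing meaningless comparisons. Within the
overlap, an internal gap is a fifth character state: gap-vs-base differs,
gap-vs-gap matches. Both choices ("fifth state" admits either reading of
gap-vs-gap) are configurable; the alternative rule excludes gap-containing
columns from numerator and denominator. Sequences whose longest internal
gap exceeds 30 bp are excluded before clustering (a sliding indel chains
otherwise distant sequences); codon-length deletions pass untouched.

Objective clustering returns the connected components of the graph joining
pairs at distance ≤ t — single linkage cut at t — computed with
scipy's sparse connected components and verified against a brute-force
union-find oracle on random 200×200 matrices. Cluster labels are
canonicalised to the lexicographically smallest member, making the
partition order-invariant. A threshold profile reports MOTU counts across
thresholds (counts are non-increasing in t, asserted in tests), with 3% as
the headline. The single-linkage dendrogram export (Newick) is a visual
companion, not an inference.

Multiple alignment: synthetic barcodes are substitution variants of a
common region, so the pipeline projects sequences onto the coordinates of
an anchor (the longest sequence) via pairwise global alignment with free
end gaps. This is exact for equal-length and nested amplicons and
represents deletions correctly; insertions relative to the anchor are
dropped. Real-data use with substantial indel variation should substitute
an external multiple alignment — the distance and clustering code accepts
any aligned FASTA.

## Summary arithmetic

Percentages are rounded half-up to one decimal (`pct`), not bankers'
rounding, because survey reports print half-up one-decimal figures and the
two rules differ at .x5. Every percentage field in the report equals its
ratio recomputed from the counts in the same report (asserted in tests). A
specimen counts as "barcoded" when its call passed the filters or was
rescued by C4. Identification sources follow the decision table:
barcode-only (named species match, no morphology name, or any C3),
morphology-only, both, none.

## The synthetic generator

What it emulates, and the defaults chosen as study-like conditions:

- ~10² specimens (20 species × 5) across the seven phylum-level
  morphotypes; 313-bp amplicons (658 available);
- a barcoding gap by construction: intraspecific divergence ≤ 1%,
  interspecific ≥ 5%, enforced as uncorrected p-distances. Species arise
  from one random in-frame ancestor by third-codon-position mutations
  (substitution probability 0.7/site, rejection-sampled against the
  divergence floor), which keeps every sequence stop-free so the
  translation screen stays meaningful. The floor is capped at 0.2 because
  third-position-only mutation cannot guarantee more;
- ~200 merged reads per specimen (Poisson), per-base substitution error
  0.001 (a merged-read error rate; with it, ~73% of 313-bp reads are
  error-free, so dominant coverage comfortably clears 50 at 200 reads);
- cross-specimen contamination 10% from a *single* randomly chosen donor
  per specimen (neighbouring-well carry-over), so the expected
  second/first dominant ratio is c/(1−c) ≈ 0.11 and the ratio filter's
  flag band is actually exercised;
- specimen-level dropout only (default 0 in the library; 0.32 in the
  survey-scale analysis script, emulating two-thirds amplification
  success) — the simplest mechanism that reproduces the
  amplification-success statistic;
- morphotype mis-sorts at a configurable rate (default 0); an optional
  single-codon-deletion haplotype variant; no chimeras, no quality-score
  profiles, no paired-end simulation (merged reads only), no indels by
  default.
- reference databases with configurable species coverage, named fraction
  (unnamed entries become "Genus sp.") and misidentification rate (wrong
  taxonomy string, truth recorded).

Consequently, passing tests show that the *pipeline logic* is correct under
the stated statistical structure; they do not show robustness to real-data
features the generator omits (chimeras, heterogeneous error, index
hopping, taxa without a barcoding gap, alignment-sensitive indel
variation).

Contamination rates in real surveys are not reported; the 10% default is
illustrative, chosen to exercise both the pass and flag bands of the ratio
filter, not calibrated.

## Problem sizes and determinism

The test suite uses worlds of 5–20 species (10–100 specimens, ≤ 20k reads),
clustering oracles at 200×200, and alignment oracles ≤ 50 bp; the whole
suite runs in about half a minute on one CPU, and the acceptance script's
recovery experiment (100 specimens, ~20k reads) in about 15 s. All
randomness flows from explicit integer seeds (numpy `default_rng` and
`random.Random`); identical configurations reproduce bit-identical worlds,
and hypothesis-based property tests are bounded and deterministic in
practice via fixed example budgets.

## Known limitations

- The internal matcher is not BLAST: scores, E-values and heuristics
  differ, so identities against large, real databases may differ near band
  boundaries.
- Anchor projection is not a full multiple aligner (see above).
- C4's "second dominant does not match the morphotype" is evaluated
  against the second dominant *sequence's* best hit; if the second
  dominant has no database hit it is treated as non-matching, which is
  permissive by design.
- The report's species/MOTU union arithmetic cannot reproduce expert
  judgement about overlap between morphology-only species and MOTUs; it
  exposes the counts side by side instead.
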