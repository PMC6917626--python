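# biocode

A specimen-level COI DNA-barcoding pipeline for marine biodiversity surveys,
with a ground-truthed synthetic-data generator so the entire analysis runs
and is validated without any external downloads.

## The problem

Marine surveys in biodiverse regions collect far more specimens than
taxonomists can identify: most animals are sorted only to coarse
morphotypes (phylum level for zooplankton), reference databases are
incomplete and partly misidentified, and cross-specimen contamination is a
real hazard when hundreds of individually tagged amplicons are pooled on
one sequencing run. This package implements the "reverse workflow" used by
such surveys: barcode everything first, cluster the barcodes into putative
species, and let the molecular clusters guide taxonomic verification.

## The method

For each specimen, a COI amplicon (313-bp mini-barcode or 658-bp full
barcode) is PCR-tagged with a 9-bp tag on each primer; tag sets have
pairwise Hamming distance ≥ 3, so a single sequencing error per tag is
correctable by nearest-tag decoding. After demultiplexing:

1. **Barcode calling.** The specimen's barcode is its *dominant read* (most
   abundant unique sequence). Calls are kept when coverage > 50 reads,
   total count > 10, and the contamination ratio
   r = n(second dominant)/n(dominant) ≤ 0.2; calls with 0.2 < r < 0.35 are
   flagged for re-evaluation; larger r fails. Translations are screened for
   internal stop codons (NUMT detection; invertebrate mitochondrial code by
   default).
2. **Taxonomic assignment.** Each barcode is aligned (local alignment,
   match +1 / mismatch −1 / gap open −2 / extend −1, both orientations)
   against a reference database. Hits need query cover ≥ 80%; the best
   hit's percent identity sets the rank: ≥ 97% species, ≥ 90% genus,
   ≥ 80% family. Equal-identity hits with conflicting labels demote the
   call to their lowest common rank; matches to unnamed entries
   ("Genus sp.", "uncultured …") never count as named species.
3. **Congruence criteria C1–C4.** Morphotype sorts and barcode identities
   are reconciled: C1 congruent + identity ≥ 97%; C2 congruent + identity
   > 85% (lowest applicable rank); C3 incongruent but identity ≥ 97% *and*
   specimen images confirm the match (curated input); C4 rescues flagged
   calls when the dominant read matches a morphotype-congruent taxon at
   ≥ 85% and the second dominant read does **not** match the morphotype.
4. **MOTU clustering.** Uncorrected p-distances are computed on a common
   alignment with internal gaps treated as a fifth character state
   (terminal gaps excluded, minimum overlap 100 bp); molecular operational
   taxonomic units are the connected components of the graph joining pairs
   at distance ≤ t (single linkage cut at t, headline t = 3%). Sequences
   with an internal gap > 30 bp are excluded first.
5. **Reporting.** All survey tallies (amplification success, long/short
   split, identification sources, MOTU counts) are recomputed from the
   row-level tables, with percentages rounded half-up to one decimal.

The synthetic generator (`biocode.synthetic_data`) builds worlds with a
barcoding gap by construction — intraspecific divergence below, and
interspecific divergence above, configurable bounds, via third-codon-position
mutations that never introduce stop codons — plus tagged read pools with
sequencing error, single-donor cross-contamination, specimen dropout,
morphotype mis-sorts, and imperfect reference databases. Truth tables make
every downstream number checkable.

## Worked example

```python
from biocode.synthetic_data import SimulationConfig, generate_world
from biocode.pipeline import run_pipeline, species_recall

cfg = SimulationConfig(n_species=6, specimens_per_species=3,
                       reads_per_specimen_mean=80, seed=3)
world = generate_world(cfg)
res = run_pipeline(world)
print("MOTUs:", res.partition.n_motus, " recall:", species_recall(world, res))
print(res.report.to_markdown())
```

prints

```
MOTUs: 6  recall: 1.0
# Survey summary

- specimens processed: 18
- barcodes obtained: 15 (83.3% amplification success)
- long (>= 658 bp): 0 (0.0%); short: 15 (100.0%)
- specimens with demultiplexed reads: 18
- passing all read filters: 12 (66.7%); rescued via C4: 3
- identified by barcode alone: 15 (100.0% of barcoded)
- barcodes tagged with species names: 15 (100.0% of barcoded)
- identified by morphology alone: 0
- distinct named species: 6
- MOTUs at 3% threshold: 6
...
```

Eighteen specimens of six species were simulated with 10% cross-specimen
contamination; twelve barcodes pass the filters outright, three sit in the
0.2–0.35 ratio band and are rescued by criterion C4 (their dominant read
matches the morphotype, the contaminant does not), and the six recovered
MOTUs coincide exactly with the six true species.

The same analysis at survey scale, stage by stage with file interfaces,
lives in `analysis/01_simulate.py` … `analysis/07_report.py`; each script
reads the previous stage's tables under `results/analysis/` and prints what
it found.

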