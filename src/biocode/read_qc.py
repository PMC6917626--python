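"""Per-specimen barcode calling from demultiplexed reads.

The barcode of a specimen is its dominant read: the most abundant unique
sequence in the specimen's read pool.  Three filters guard against
low-coverage calls and cross-specimen contamination:

* sequencing coverage (reads identical to the dominant sequence) must exceed
  a minimum (default > 50);
* the total read count retained for the specimen must exceed a minimum
  (default > 10);
* the abundance ratio second-dominant/dominant must be small (pass at
  <= 0.2); ratios strictly between 0.2 and 0.35 are flagged for downstream
  re-evaluation against morphology, larger ratios fail.

Called barcodes are additionally translated and screened for internal stop
codons, the classic signature of nuclear mitochondrial pseudogenes (NUMTs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .util import validate_nucleotides

INVERTEBRATE_MITO_TABLE = 5
VERTEBRATE_MITO_TABLE = 2
LONG_BARCODE_MIN = 658  # bp; full-length COI barcode


@dataclass
class FilterThresholds:
    """QC thresholds; defaults follow the strict inequalities coverage > 50,
    count > 10, ratio <= 0.2 with re-evaluation below 0.35."""

    coverage_min: int = 50
    count_min: int = 10
    ratio_pass: float = 0.2
    ratio_flag: float = 0.35


@dataclass
class RankedReadSet:
    """Unique sequences of one specimen ordered by descending abundance."""

    specimen_id: str
    unique_sequences: list[tuple[str, int]]
    coverage: int  # reads identical to the dominant sequence
    total_count: int
    ratio: float  # second-dominant count / dominant count, 0 if no second

    @property
    def dominant(self) -> str:
        return self.unique_sequences[0][0]

    @property
    def second_dominant(self) -> str | None:
        return self.unique_sequences[1][0] if len(self.unique_sequences) > 1 else None


@dataclass
class FilterOutcome:
    status: str  # "pass" | "flagged" | "fail"
    reasons: list[str] = field(default_factory=list)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)


@dataclass
class BarcodeRecord:
    """A called specimen barcode with its QC provenance."""

    specimen_id: str
    sequence: str
    source: str = "hts-called"  # or "sanger-supplied"
    translation_status: str = "clean"
    qc: FilterOutcome | str = "external"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def length_class(self) -> str:
        return "long" if self.length >= LONG_BARCODE_MIN else "short"


def rank_reads(specimen_id: str, reads: Iterable[str]) -> RankedReadSet | None:
    """Group identical reads and order unique sequences by abundance.

    Ties in count are broken lexicographically by sequence so the ranking is
    deterministic.  Returns None for an empty pool (specimen barcode-failed).
    """
    counts = Counter(r.upper() for r in reads)
    if not counts:
        return None
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    dominant_count = ordered[0][1]
    second_count = ordered[1][1] if len(ordered) > 1 else 0
    total = sum(counts.values())
    return RankedReadSet(
        specimen_id=specimen_id,
        unique_sequences=ordered,
        coverage=dominant_count,
        total_count=total,
        ratio=second_count / dominant_count,
    )


def apply_filters(
    r: RankedReadSet, thresholds: FilterThresholds | None = None
) -> FilterOutcome:
    """Apply the coverage, count and contamination-ratio filters."""
    t = thresholds or FilterThresholds()
    reasons: list[str] = []
    if r.coverage <= t.coverage_min:
        reasons.append(f"coverage <= {t.coverage_min}")
    if r.total_count <= t.count_min:
        reasons.append(f"total count <= {t.count_min}")
    if reasons:
        return FilterOutcome("fail", reasons, t)
    if r.ratio <= t.ratio_pass:
        return FilterOutcome("pass", [], t)
    if r.ratio < t.ratio_flag:
        return FilterOutcome(
            "flagged", [f"dominant ratio {r.ratio:.3f} in ({t.ratio_pass}, {t.ratio_flag})"], t
        )
    return FilterOutcome("fail", [f"dominant ratio {r.ratio:.3f} >= {t.ratio_flag}"], t)


def _frames_without_stop(seq: str, table: int, frames: Sequence[int]) -> list[int]:
    clean = []
    for f in frames:
        sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
        if not sub:
            continue
        protein = str(Seq(sub).translate(table=table))
        if "*" not in protein:
            clean.append(f)
    return clean


def _internal_gap_runs(aligned: str) -> list[int]:
    core = aligned.strip("-")
    runs, run = [], 0
    for c in core:
        if c == "-":
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def screen_translation(
    sequence: str,
    table: int = INVERTEBRATE_MITO_TABLE,
    reference: str | None = None,
    frame_offset_search: bool = True,
    expected_frame: int = 0,
) -> str:
    """Classify a barcode by its translation: 'clean', 'codon-gap' or 'numt-suspect'.

    A sequence is clean when some reading frame (the expected one, or all
    three when searching) translates without an internal stop codon.  When a
    reference is supplied, a clean sequence whose alignment to the reference
    shows internal deletions of whole codons (gap runs of length divisible by
    3) is classified 'codon-gap': the reading frame is intact but the indel
    is recorded.  Sequences with stops in every frame are NUMT suspects.
    """
    sequence = sequence.upper()
    validate_nucleotides(sequence, allow_n=True)
    if len(sequence) < 30:
        raise ValueError("sequence too short to screen (< 30 bp)")
    frames = (0, 1, 2) if frame_offset_search else (expected_frame,)
    if not _frames_without_stop(sequence, table, frames):
        return "numt-suspect"
    if reference is not None:
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-2,
            extend_gap_score=-1,
        )
        aln = aligner.align(reference.upper(), sequence)[0]
        query_row = str(aln[1])
        runs = _internal_gap_runs(query_row)
        if runs:
            if all(r % 3 == 0 for r in runs):
                return "codon-gap"
            return "numt-suspect"
    return "clean"


def call_barcode(
    specimen_id: str,
    reads: Iterable[str],
    thresholds: FilterThresholds | None = None,
    table: int = INVERTEBRATE_MITO_TABLE,
    reference: str | None = None,
) -> tuple[RankedReadSet | None, FilterOutcome | None, BarcodeRecord | None]:
    """Rank a specimen's reads, filter, and screen the dominant sequence.

    Returns ``(ranked, outcome, record)``; all None except ranked=None for an
    empty pool.  The BarcodeRecord is produced whenever ranking succeeds, so
    flagged calls remain available for morphology-based re-evaluation.
    """
    ranked = rank_reads(specimen_id, reads)
    if ranked is None:
        return None, None, None
    outcome = apply_filters(ranked, thresholds)
    status = screen_translation(ranked.dominant, table=table, reference=reference)
    record = BarcodeRecord(
        specimen_id=specimen_id,
        sequence=ranked.dominant,
        source="hts-called",
        translation_status=status,
        qc=outcome,
    )
    return ranked, outcome, record
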