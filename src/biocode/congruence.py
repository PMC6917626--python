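"""Reconciling morphological sorts with barcode identities.

Specimens are pre-sorted by eye into phylum-level morphotypes; barcodes are
matched to a reference database.  Four acceptance criteria decide which
barcodes are considered reliable:

* C1 - morphotype and barcode identity agree and the match is good
  (identity >= 97%, species-level band);
* C2 - the match is poorer (> 85%) but still consistent with the
  morphological sort, giving the lowest applicable taxonomic identity;
* C3 - morphotype and barcode disagree, but the match is strong (>= 97%)
  and the specimen images agree with the match (a curated, human judgement
  supplied as a flag) - accommodating mis-sorts at the bench;
* C4 - barcodes that failed the contamination-ratio filter (flagged, ratio
  between 0.2 and 0.35) are rescued only when coverage and count filters
  hold, the dominant read matches a morphotype-congruent taxon at >= 85%,
  and the second dominant read does NOT match the assigned morphotype.

Everything else is rejected: the specimen keeps its morphology name if one
exists, otherwise it remains unidentified.
"""

from __future__ import annotations

from dataclasses import dataclass

from .read_qc import FilterOutcome, RankedReadSet
from .tax_assign import MatchResult

MORPHOTYPE_VOCABULARY = (
    "Arthropoda",
    "Annelida",
    "Chaetognatha",
    "Chordata",
    "Cnidaria",
    "Mollusca",
    "Platyhelminthes",
)


@dataclass
class MorphotypeLabel:
    """Phylum-level morphology sort, plus optional finer identification."""

    label: str = "unknown"
    species_name: str | None = None
    image_consistent: bool = False

    def __post_init__(self) -> None:
        if self.label not in MORPHOTYPE_VOCABULARY and self.label != "unknown":
            # tolerate out-of-vocabulary labels but normalise unknowns
            if not self.label:
                self.label = "unknown"


@dataclass
class CongruenceThresholds:
    good_match: float = 97.0  # C1/C3 identity floor
    poor_match: float = 85.0  # C2 floor (strict >) and C4 floor (>=)


@dataclass
class CongruenceDecision:
    specimen_id: str
    criterion: str  # C1 | C2 | C3 | C4 | reject
    identity_source: str  # barcode | morphology | both | none
    final_name: str | None
    rationale: str


def _morphology_fallback(specimen_id: str, morphotype: MorphotypeLabel, why: str) -> CongruenceDecision:
    if morphotype.species_name:
        return CongruenceDecision(
            specimen_id, "reject", "morphology", morphotype.species_name,
            f"{why}; morphology name retained",
        )
    return CongruenceDecision(specimen_id, "reject", "none", None, why)


def resolve(
    specimen_id: str,
    match: MatchResult | None,
    morphotype: MorphotypeLabel | None,
    qc: FilterOutcome | None,
    ranked: RankedReadSet | None = None,
    second_match: MatchResult | None = None,
    thresholds: CongruenceThresholds | None = None,
) -> CongruenceDecision:
    """Apply criteria C1-C4 (in that order) to one specimen.

    ``second_match`` is the taxonomic assignment of the second dominant read;
    it is consulted only for flagged records (criterion C4).
    """
    t = thresholds or CongruenceThresholds()
    morphotype = morphotype or MorphotypeLabel()
    if qc is None:
        return _morphology_fallback(specimen_id, morphotype, "no reads")
    if qc.status == "fail":
        return _morphology_fallback(specimen_id, morphotype, "failed read filters")
    if match is None:
        return _morphology_fallback(specimen_id, morphotype, "no database match")

    congruent = (
        match.best_phylum is not None
        and morphotype.label != "unknown"
        and match.best_phylum == morphotype.label
    )
    match.congruent_with_morphotype = congruent
    pid = match.percent_identity

    if qc.status == "pass":
        if congruent and pid >= t.good_match and match.assigned_rank != "none":
            return CongruenceDecision(
                specimen_id, "C1", "both", match.assigned_name,
                f"congruent good match ({pid:.1f}%)",
            )
        if congruent and pid > t.poor_match and match.assigned_rank != "none":
            return CongruenceDecision(
                specimen_id, "C2", "both", match.assigned_name,
                f"congruent poor match ({pid:.1f}%), {match.assigned_rank}-level identity",
            )
        if not congruent and pid >= t.good_match and morphotype.image_consistent:
            return CongruenceDecision(
                specimen_id, "C3", "barcode", match.assigned_name,
                f"incongruent with sort but strong match ({pid:.1f}%) confirmed by images",
            )
        return _morphology_fallback(
            specimen_id, morphotype,
            f"match {pid:.1f}% to {match.best_phylum or 'nothing'} fails C1-C3",
        )

    # flagged: C4 re-evaluation
    if qc.status == "flagged":
        conditions = [
            qc.thresholds.ratio_pass < (ranked.ratio if ranked else -1.0) < qc.thresholds.ratio_flag,
            ranked is not None and ranked.coverage > qc.thresholds.coverage_min,
            ranked is not None and ranked.total_count > qc.thresholds.count_min,
            congruent and pid >= t.poor_match,
            second_match is None
            or second_match.best_phylum is None
            or second_match.best_phylum != morphotype.label,
        ]
        if all(conditions):
            return CongruenceDecision(
                specimen_id, "C4", "both", match.assigned_name,
                "flagged ratio rescued: congruent dominant, incongruent second dominant",
            )
        return _morphology_fallback(specimen_id, morphotype, "flagged record fails C4")

    return _morphology_fallback(specimen_id, morphotype, f"unhandled status {qc.status}")
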