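"""Headline tallies of a barcoding survey from the pipeline's row-level tables.

Every reported number is recomputed from the row-level TSVs (manifest, QC,
assignments, congruence decisions, MOTU partition), so the report is an
audit trail rather than a side channel.  Percentages are rounded half-up to
one decimal, matching how such surveys print 68.0%-style figures (bankers'
rounding would differ at .x5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .tax_assign import is_named

ACCEPT_CRITERIA = ("C1", "C2", "C3", "C4")


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to ``ndigits`` decimals; 0.0 when the
    denominator is zero."""
    if denominator == 0:
        return 0.0
    ratio = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    q = Decimal(1).scaleb(-ndigits)
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


def classify_identification_source(
    criterion: str,
    assigned_rank: str,
    named_match: bool,
    morphology_name: str | None,
) -> str:
    """Per-specimen identification source: barcode-only, morphology-only, both, none.

    A "qualifying" barcode identification is a named species-level match
    accepted by a reliability criterion.  C3 acceptances override the
    morphological sort, so they count as barcode-only even when a morphology
    name exists.
    """
    barcode_named = (
        criterion in ACCEPT_CRITERIA and assigned_rank == "species" and named_match
    )
    has_morph = bool(morphology_name)
    if barcode_named and criterion == "C3":
        return "barcode-only"
    if barcode_named and has_morph:
        return "both"
    if barcode_named:
        return "barcode-only"
    if has_morph:
        return "morphology-only"
    return "none"


@dataclass
class SummaryReport:
    total_specimens: int
    barcoded: int
    amplification_success_pct: float
    long_count: int
    long_pct: float
    short_count: int
    short_pct: float
    sequenced_amplicons: int
    passing_filters: int
    passing_filters_pct: float
    accepted_c4: int
    identified_barcode_only: int
    identified_barcode_only_pct: float
    identified_with_species_names: int
    identified_with_species_names_pct: float
    identified_morphology_only: int
    total_named_species: int
    motu_count_at_headline_threshold: int
    headline_threshold: float
    per_phylum_share_pct: dict[str, float] = field(default_factory=dict)
    thresholds_used: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_markdown(self) -> str:
        lines = [
            "# Survey summary",
            "",
            f"- specimens processed: {self.total_specimens}",
            f"- barcodes obtained: {self.barcoded} "
            f"({self.amplification_success_pct}% amplification success)",
            f"- long (>= 658 bp): {self.long_count} ({self.long_pct}%); "
            f"short: {self.short_count} ({self.short_pct}%)",
            f"- specimens with demultiplexed reads: {self.sequenced_amplicons}",
            f"- passing all read filters: {self.passing_filters} "
            f"({self.passing_filters_pct}%); rescued via C4: {self.accepted_c4}",
            f"- identified by barcode alone: {self.identified_barcode_only} "
            f"({self.identified_barcode_only_pct}% of barcoded)",
            f"- barcodes tagged with species names: {self.identified_with_species_names} "
            f"({self.identified_with_species_names_pct}% of barcoded)",
            f"- identified by morphology alone: {self.identified_morphology_only}",
            f"- distinct named species: {self.total_named_species}",
            f"- MOTUs at {self.headline_threshold:.0%} threshold: "
            f"{self.motu_count_at_headline_threshold}",
            "",
            "Per-morphotype specimen shares (%):",
        ]
        for phylum, share in sorted(self.per_phylum_share_pct.items()):
            lines.append(f"- {phylum}: {share}")
        return "\n".join(lines) + "\n"


def summarize(
    manifest: pd.DataFrame,
    qc: pd.DataFrame,
    assignments: pd.DataFrame,
    decisions: pd.DataFrame,
    partition: pd.DataFrame,
    headline_threshold: float = 0.03,
    thresholds_used: dict | None = None,
) -> SummaryReport:
    """Compute the survey-level tallies from the row-level tables.

    Expected columns: manifest(specimen_id, morphotype[, morphology_name]);
    qc(specimen_id, status, length_class); assignments(specimen_id, rank,
    name, named_match); decisions(specimen_id, criterion, identity_source,
    final_name); partition(specimen_id, motu_id).
    """
    for name, frame in [("qc", qc), ("assignments", assignments), ("decisions", decisions)]:
        unknown = set(frame["specimen_id"]) - set(manifest["specimen_id"])
        if unknown:
            raise ValueError(f"{name} table has specimen ids not in manifest: {sorted(unknown)[:5]}")

    total = len(manifest)
    crit = decisions.set_index("specimen_id")["criterion"] if len(decisions) else pd.Series(dtype=object)
    accepted_ids = set(crit[crit.isin(ACCEPT_CRITERIA)].index)

    qc_idx = qc.set_index("specimen_id") if len(qc) else pd.DataFrame()
    passing = set(qc_idx.index[qc_idx["status"] == "pass"]) if len(qc_idx) else set()
    # a specimen is "barcoded" when its called sequence was accepted:
    # passing the filters outright, or rescued by criterion C4
    barcoded_ids = passing | {s for s in accepted_ids if crit.get(s) == "C4"}
    barcoded = len(barcoded_ids)

    long_count = short_count = 0
    if len(qc_idx):
        klass = qc_idx.loc[sorted(barcoded_ids), "length_class"]
        long_count = int((klass == "long").sum())
        short_count = int((klass == "short").sum())

    morph_names = (
        manifest.set_index("specimen_id")["morphology_name"]
        if "morphology_name" in manifest.columns
        else pd.Series(index=manifest["specimen_id"], dtype=object)
    )
    assign_idx = assignments.set_index("specimen_id") if len(assignments) else pd.DataFrame()

    sources = {}
    for sid in manifest["specimen_id"]:
        criterion = crit.get(sid, "reject")
        rank = assign_idx["rank"].get(sid, "none") if len(assign_idx) else "none"
        named = bool(assign_idx["named_match"].get(sid, False)) if len(assign_idx) else False
        morph = morph_names.get(sid)
        morph = morph if isinstance(morph, str) and morph else None
        sources[sid] = classify_identification_source(criterion, rank, named, morph)
    source_series = pd.Series(sources)

    barcode_only = int((source_series == "barcode-only").sum())
    both = int((source_series == "both").sum())
    morph_only = int((source_series == "morphology-only").sum())

    named_species = set()
    for sid in barcoded_ids:
        criterion = crit.get(sid)
        if criterion in ACCEPT_CRITERIA and len(assign_idx) and sid in assign_idx.index:
            row = assign_idx.loc[sid]
            if row["rank"] == "species" and bool(row["named_match"]):
                named_species.add(row["name"])
    for sid, name in morph_names.items():
        if isinstance(name, str) and name and is_named(name):
            named_species.add(name)

    with_species_names = barcode_only + both
    motus = partition["motu_id"].nunique() if len(partition) else 0
    sequenced = int((qc["status"] != "no-reads").sum()) if len(qc) else 0

    shares = {}
    if "morphotype" in manifest.columns and total:
        counts = manifest["morphotype"].value_counts()
        shares = {str(k): pct(int(v), total) for k, v in counts.items()}

    return SummaryReport(
        total_specimens=total,
        barcoded=barcoded,
        amplification_success_pct=pct(barcoded, total),
        long_count=long_count,
        long_pct=pct(long_count, barcoded),
        short_count=short_count,
        short_pct=pct(short_count, barcoded),
        sequenced_amplicons=sequenced,
        passing_filters=len(passing),
        passing_filters_pct=pct(len(passing), sequenced),
        accepted_c4=sum(1 for s in accepted_ids if crit.get(s) == "C4"),
        identified_barcode_only=barcode_only,
        identified_barcode_only_pct=pct(barcode_only, barcoded),
        identified_with_species_names=with_species_names,
        identified_with_species_names_pct=pct(with_species_names, barcoded),
        identified_morphology_only=morph_only,
        total_named_species=len(named_species),
        motu_count_at_headline_threshold=motus,
        headline_threshold=headline_threshold,
        per_phylum_share_pct=shares,
        thresholds_used=thresholds_used or {},
    )
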