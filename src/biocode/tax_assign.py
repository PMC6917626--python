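"""Threshold-based taxonomic assignment against a reference barcode database.

Each query barcode is aligned locally against every reference entry (both
strand orientations) under fixed scores (match +1, mismatch -1, gap open -2,
gap extend -1).  Hits are eligible when the query cover is at least 80% and
the best eligible hit's percent identity sets the assigned rank:
>= 97% species, >= 90% genus, >= 80% family, otherwise none.  Equal-identity
hits that disagree at the assigned rank demote the call to their lowest
common rank.  Matches to reference entries without a proper binomial
("sp.", "uncultured", "cf.", blank) are recorded but do not count as named
species identifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .util import revcomp

RANKS = ("phylum", "class", "order", "family", "genus", "species")
UNNAMED_PATTERNS = ("sp.", "uncultured", "cf.")


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference barcode with its six-rank taxonomy string."""

    entry_id: str
    taxonomy: tuple[str, ...]  # (phylum, class, order, family, genus, species)
    sequence: str

    def __post_init__(self) -> None:
        if len(self.taxonomy) != len(RANKS):
            raise ValueError(f"taxonomy must have {len(RANKS)} ranks")
        if not self.taxonomy[0]:
            raise ValueError("taxonomy must be non-empty at phylum")

    @property
    def species_label(self) -> str:
        return self.taxonomy[-1]

    def label_at(self, rank: str) -> str:
        return self.taxonomy[RANKS.index(rank)]


def is_named(species_label: str, patterns: tuple[str, ...] = UNNAMED_PATTERNS) -> bool:
    """True when a species label looks like a proper binomial rather than a
    placeholder ("Genus sp.", "uncultured ...", "Genus cf. x", blank)."""
    label = species_label.strip()
    if not label:
        return False
    low = label.lower()
    return not any(p in low for p in patterns)


@dataclass
class AssignmentThresholds:
    species: float = 97.0
    genus: float = 90.0
    family: float = 80.0
    min_cover: float = 80.0


@dataclass
class MatchResult:
    """Best reference hit for one query barcode."""

    specimen_id: str
    best_entry_id: str | None = None
    percent_identity: float = 0.0
    query_cover: float = 0.0
    assigned_rank: str = "none"  # species | genus | family | none
    assigned_name: str | None = None
    named_match: bool = False
    best_taxonomy: tuple[str, ...] | None = None
    congruent_with_morphotype: bool | None = None  # filled by the congruence step

    @property
    def best_phylum(self) -> str | None:
        return self.best_taxonomy[0] if self.best_taxonomy else None


def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )


def _score_one(aligner: Align.PairwiseAligner, query: str, reference: str):
    alignments = aligner.align(reference, query)
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qseg = aln.aligned[1]
    if len(qseg):
        span = int(qseg[-1][1] - qseg[0][0])
    else:
        span = 0
    cover = 100.0 * span / len(query) if query else 0.0
    return float(aln.score), identity, cover, columns


def align_and_score(query: str, reference: str) -> tuple[float, float]:
    """(percent_identity, query_cover) of the best local alignment.

    Both orientations of the query are scored and the better kept (forward
    wins ties).  Percent identity uses aligned columns, including gap
    columns, as the denominator; query cover is the aligned query span over
    the query length, both x100.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    query, reference = query.upper(), reference.upper()
    aligner = _make_aligner()
    fwd = _score_one(aligner, query, reference)
    rev = _score_one(aligner, revcomp(query), reference)
    best = fwd if fwd[0] >= rev[0] else rev
    return best[1], best[2]


def _rank_for_identity(identity: float, t: AssignmentThresholds) -> str:
    if identity >= t.species:
        return "species"
    if identity >= t.genus:
        return "genus"
    if identity >= t.family:
        return "family"
    return "none"


def _demote_to_agreement(
    hits: list[ReferenceEntry], rank: str, t: AssignmentThresholds, identity: float
) -> str:
    """Walk down the rank bands until all tied hits agree on the label and the
    identity still meets that band's threshold."""
    order = ["species", "genus", "family"]
    if rank == "none":
        return "none"
    for r in order[order.index(rank) :]:
        threshold = getattr(t, r)
        if identity < threshold:
            continue
        labels = {h.label_at(r) for h in hits}
        if len(labels) == 1:
            return r
    return "none"


def assign_taxonomy(
    specimen_id: str,
    sequence: str,
    db: list[ReferenceEntry],
    thresholds: AssignmentThresholds | None = None,
) -> MatchResult:
    """Assign a taxonomic identity to one barcode from the best database hit.

    The best hit is the eligible entry (cover >= min_cover) with the highest
    percent identity; ties break by alignment score, then database order.
    """
    t = thresholds or AssignmentThresholds()
    if not db:
        return MatchResult(specimen_id=specimen_id)
    aligner = _make_aligner()
    query = sequence.upper()
    rc_query = revcomp(query)
    scored: list[tuple[float, float, int, ReferenceEntry]] = []
    for idx, entry in enumerate(db):
        fwd = _score_one(aligner, query, entry.sequence.upper())
        rev = _score_one(aligner, rc_query, entry.sequence.upper())
        score, identity, cover, _ = fwd if fwd[0] >= rev[0] else rev
        if cover >= t.min_cover:
            scored.append((identity, score, idx, entry))
    if not scored:
        return MatchResult(specimen_id=specimen_id)
    best_identity = max(s[0] for s in scored)
    tied = [s for s in scored if abs(s[0] - best_identity) < 1e-9]
    tied.sort(key=lambda s: (-s[1], s[2]))
    best = tied[0]
    rank = _rank_for_identity(best_identity, t)
    if len(tied) > 1:
        rank = _demote_to_agreement([s[3] for s in tied], rank, t, best_identity)
    entry = best[3]
    # query cover of the winning hit, recomputed for the winning orientation
    fwd = _score_one(aligner, query, entry.sequence.upper())
    rev = _score_one(aligner, rc_query, entry.sequence.upper())
    cover = (fwd if fwd[0] >= rev[0] else rev)[2]
    return MatchResult(
        specimen_id=specimen_id,
        best_entry_id=entry.entry_id,
        percent_identity=best_identity,
        query_cover=cover,
        assigned_rank=rank,
        assigned_name=entry.label_at(rank) if rank != "none" else None,
        named_match=is_named(entry.species_label),
        best_taxonomy=entry.taxonomy,
    )
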