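"""End-to-end orchestration: demultiplex -> call barcodes -> assign taxonomy
-> reconcile with morphotypes -> cluster MOTUs -> summarise.

Each stage lives in its own module; this module wires them together over a
manifest and a read pool (typically a synthetic TrueWorld) and returns all
row-level tables plus the survey summary, so scripts, tests and the
acceptance machinery share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import congruence, motu_clustering, read_qc, summary_report, tax_assign
from .synthetic_data import PRIMER_FWD, PRIMER_REV, TrueWorld
from .tag_demux import DemuxResult, demultiplex


@dataclass
class PipelineOptions:
    max_tag_mismatch: int = 1
    qc: read_qc.FilterThresholds = field(default_factory=read_qc.FilterThresholds)
    assign: tax_assign.AssignmentThresholds = field(default_factory=tax_assign.AssignmentThresholds)
    congruence: congruence.CongruenceThresholds = field(default_factory=congruence.CongruenceThresholds)
    motu_threshold: float = 0.03
    profile_thresholds: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
    min_overlap: int = motu_clustering.DEFAULT_MIN_OVERLAP
    max_internal_gap: int = motu_clustering.DEFAULT_MAX_INTERNAL_GAP
    translation_table: int = read_qc.INVERTEBRATE_MITO_TABLE

    def as_dict(self) -> dict:
        return {
            "max_tag_mismatch": self.max_tag_mismatch,
            "coverage_min": self.qc.coverage_min,
            "count_min": self.qc.count_min,
            "ratio_pass": self.qc.ratio_pass,
            "ratio_flag": self.qc.ratio_flag,
            "identity_species": self.assign.species,
            "identity_genus": self.assign.genus,
            "identity_family": self.assign.family,
            "min_cover": self.assign.min_cover,
            "motu_threshold": self.motu_threshold,
            "min_overlap": self.min_overlap,
            "max_internal_gap": self.max_internal_gap,
            "translation_table": self.translation_table,
        }


@dataclass
class PipelineResult:
    demux: DemuxResult
    qc_table: pd.DataFrame
    ranked: dict[str, read_qc.RankedReadSet]
    outcomes: dict[str, read_qc.FilterOutcome]
    barcodes: dict[str, read_qc.BarcodeRecord]
    assignments: pd.DataFrame
    matches: dict[str, tax_assign.MatchResult]
    decisions: pd.DataFrame
    partition: motu_clustering.MOTUPartition
    partition_table: pd.DataFrame
    profile: motu_clustering.MOTUProfile
    distance_matrix: motu_clustering.DistanceMatrix
    report: summary_report.SummaryReport

    @property
    def accepted_ids(self) -> set[str]:
        ok = self.decisions["criterion"].isin(summary_report.ACCEPT_CRITERIA)
        passing = {
            s for s, o in self.outcomes.items() if o is not None and o.status == "pass"
        }
        rescued = set(self.decisions.loc[ok & (self.decisions["criterion"] == "C4"), "specimen_id"])
        return passing | rescued


def run_pipeline(
    world: TrueWorld,
    options: PipelineOptions | None = None,
    image_consistent: dict[str, bool] | None = None,
    morphology_names: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full analysis over a (synthetic) survey world.

    ``image_consistent`` supplies the human image-review judgement consulted
    by criterion C3 (defaults to False everywhere: C3 never fires without
    curation input).  ``morphology_names`` optionally supplies finer
    morphology-based species names per specimen.
    """
    opt = options or PipelineOptions()
    manifest = world.manifest()
    if morphology_names:
        manifest["morphology_name"] = manifest["specimen_id"].map(morphology_names)

    demux = demultiplex(
        world.pooled_reads(),
        {s.specimen_id: (s.tag_fwd, s.tag_rev) for s in world.specimens},
        world.tag_set,
        max_mismatch=opt.max_tag_mismatch,
        trim_fwd_extra=len(PRIMER_FWD),
        trim_rev_extra=len(PRIMER_REV),
    )
    pools = demux.reads_by_specimen()

    qc_rows = []
    ranked: dict[str, read_qc.RankedReadSet] = {}
    outcomes: dict[str, read_qc.FilterOutcome] = {}
    barcodes: dict[str, read_qc.BarcodeRecord] = {}
    for s in world.specimens:
        sid = s.specimen_id
        reads = pools.get(sid, [])
        rset, outcome, record = read_qc.call_barcode(
            sid, reads, thresholds=opt.qc, table=opt.translation_table
        )
        if rset is None:
            qc_rows.append((sid, 0, 0, 0, 0.0, "no-reads", "empty read pool", "", 0, ""))
            continue
        if record.translation_status == "numt-suspect":
            outcome.status = "fail"
            outcome.reasons.append("stop codons in every reading frame")
        ranked[sid] = rset
        outcomes[sid] = outcome
        barcodes[sid] = record
        qc_rows.append(
            (
                sid,
                len(reads),
                rset.coverage,
                rset.total_count,
                rset.ratio,
                outcome.status,
                ";".join(outcome.reasons),
                record.translation_status,
                record.length,
                record.length_class,
            )
        )
    qc_table = pd.DataFrame(
        qc_rows,
        columns=[
            "specimen_id", "n_reads", "coverage", "total", "ratio", "status",
            "reasons", "translation_status", "length", "length_class",
        ],
    )

    matches: dict[str, tax_assign.MatchResult] = {}
    second_matches: dict[str, tax_assign.MatchResult] = {}
    assign_rows = []
    for sid, outcome in outcomes.items():
        if outcome.status not in ("pass", "flagged"):
            continue
        m = tax_assign.assign_taxonomy(
            sid, barcodes[sid].sequence, world.reference_entries, opt.assign
        )
        matches[sid] = m
        if outcome.status == "flagged" and ranked[sid].second_dominant:
            second_matches[sid] = tax_assign.assign_taxonomy(
                sid, ranked[sid].second_dominant, world.reference_entries, opt.assign
            )
        assign_rows.append(
            (sid, m.best_entry_id, m.percent_identity, m.query_cover,
             m.assigned_rank, m.assigned_name, m.named_match, m.best_phylum)
        )
    assignments = pd.DataFrame(
        assign_rows,
        columns=["specimen_id", "hit", "identity", "cover", "rank", "name",
                 "named_match", "hit_phylum"],
    )

    morph_names = morphology_names or {}
    image_ok = image_consistent or {}
    decision_rows = []
    for s in world.specimens:
        sid = s.specimen_id
        label = congruence.MorphotypeLabel(
            label=s.morphotype,
            species_name=morph_names.get(sid),
            image_consistent=image_ok.get(sid, False),
        )
        dec = congruence.resolve(
            sid,
            matches.get(sid),
            label,
            outcomes.get(sid),
            ranked=ranked.get(sid),
            second_match=second_matches.get(sid),
            thresholds=opt.congruence,
        )
        decision_rows.append(
            (sid, dec.criterion, dec.identity_source, dec.final_name, dec.rationale)
        )
    decisions = pd.DataFrame(
        decision_rows,
        columns=["specimen_id", "criterion", "identity_source", "final_name", "rationale"],
    )

    crit = decisions.set_index("specimen_id")["criterion"]
    cluster_ids = sorted(
        sid
        for sid, o in outcomes.items()
        if o.status == "pass" or (o.status == "flagged" and crit.get(sid) == "C4")
    )
    seqs = [barcodes[sid].sequence for sid in cluster_ids]
    aligned = motu_clustering.align_to_anchor(cluster_ids, seqs)
    partition, dmat = motu_clustering.cluster_barcodes(
        cluster_ids,
        aligned,
        threshold=opt.motu_threshold,
        min_overlap=opt.min_overlap,
        max_internal_gap=opt.max_internal_gap,
    )
    profile = motu_clustering.cluster_profile(
        dmat, list(opt.profile_thresholds), headline_threshold=opt.motu_threshold
    )
    motu_map = partition.motu_of()
    partition_table = pd.DataFrame(
        [(sid, motu_map[sid], opt.motu_threshold) for sid in sorted(motu_map)],
        columns=["specimen_id", "motu_id", "threshold"],
    )

    report = summary_report.summarize(
        manifest, qc_table, assignments, decisions, partition_table,
        headline_threshold=opt.motu_threshold, thresholds_used=opt.as_dict(),
    )
    return PipelineResult(
        demux=demux,
        qc_table=qc_table,
        ranked=ranked,
        outcomes=outcomes,
        barcodes=barcodes,
        assignments=assignments,
        matches=matches,
        decisions=decisions,
        partition=partition,
        partition_table=partition_table,
        profile=profile,
        distance_matrix=dmat,
        report=report,
    )


# ---------------------------------------------------------------------------
# truth-based evaluation (synthetic worlds only)


def species_recall(world: TrueWorld, result: PipelineResult) -> float:
    """Fraction of accepted barcodes assigned to their true species binomial,
    among specimens whose species is present and correctly named in the
    reference database."""
    correctly_named = set(
        world.reference_truth.loc[
            world.reference_truth["status"] == "correct", "true_species"
        ]
    )
    species_of = world.species_of()
    eligible = [
        sid
        for sid in result.accepted_ids
        if species_of[sid] in correctly_named
    ]
    if not eligible:
        return float("nan")
    match_idx = result.assignments.set_index("specimen_id")
    hits = 0
    for sid in eligible:
        if sid not in match_idx.index:
            continue
        row = match_idx.loc[sid]
        if row["rank"] == "species" and row["name"] == world.binomial_of(species_of[sid]):
            hits += 1
    return hits / len(eligible)


def observed_contaminant_share(world: TrueWorld) -> float:
    """Mean, over specimens with reads, of the fraction of pool reads whose
    true source is another specimen."""
    shares = []
    for sid, pool in world.read_pools().items():
        if pool:
            shares.append(sum(r.true_source != sid for r in pool) / len(pool))
    return float(pd.Series(shares).mean()) if shares else float("nan")
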