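#!/usr/bin/env python
"""Reconcile morphotype sorts with barcode identities (criteria C1-C4).

Joins the QC table, the assignment tables and the manifest, applies the
reliability criteria in order, and writes one decision per specimen.  Image
review (criterion C3) is a curated human judgement; supply it as a TSV of
specimen_id<TAB>true/false with --image-review, otherwise C3 never fires.
"""

import argparse
from pathlib import Path

import pandas as pd

from biocode.congruence import MorphotypeLabel, resolve
from biocode.read_qc import FilterOutcome, FilterThresholds, RankedReadSet
from biocode.tax_assign import MatchResult


def _match_from_row(row) -> MatchResult:
    return MatchResult(
        specimen_id=row.specimen_id,
        best_entry_id=row.hit if pd.notna(row.hit) else None,
        percent_identity=float(row.identity),
        query_cover=float(row.cover),
        assigned_rank=row.rank,
        assigned_name=row.name_ if pd.notna(row.name_) else None,
        named_match=bool(row.named_match),
        best_taxonomy=(row.hit_phylum, "", "", "", "", "") if pd.notna(row.hit_phylum) else None,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis/congruence"))
    ap.add_argument("--image-review", type=Path, default=None)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(args.indir / "inputs" / "manifest.tsv", sep="\t")
    qc = pd.read_csv(args.indir / "barcodes" / "qc.tsv", sep="\t").set_index("specimen_id")
    matches = {
        row.specimen_id: _match_from_row(row)
        for row in pd.read_csv(args.indir / "taxonomy" / "assignments.tsv", sep="\t")
        .rename(columns={"name": "name_"})
        .itertuples()
    }
    second = {
        row.specimen_id: _match_from_row(row)
        for row in pd.read_csv(args.indir / "taxonomy" / "second_assignments.tsv", sep="\t")
        .rename(columns={"name": "name_"})
        .itertuples()
    }
    image_ok: dict[str, bool] = {}
    if args.image_review and args.image_review.exists():
        df = pd.read_csv(args.image_review, sep="\t")
        image_ok = dict(zip(df["specimen_id"], df["consistent"].astype(bool)))

    rows = []
    for r in manifest.itertuples():
        sid = r.specimen_id
        q = qc.loc[sid]
        outcome = None
        ranked = None
        if q["status"] != "no-reads":
            outcome = FilterOutcome(
                q["status"],
                [s for s in str(q["reasons"]).split(";") if s and s != "nan"],
                FilterThresholds(),
            )
            second_count = int(round(q["ratio"] * q["coverage"]))
            ranked = RankedReadSet(
                sid,
                [("", int(q["coverage"])), ("", second_count)],
                int(q["coverage"]),
                int(q["total"]),
                float(q["ratio"]),
            )
        dec = resolve(
            sid,
            matches.get(sid),
            MorphotypeLabel(r.morphotype, image_consistent=image_ok.get(sid, False)),
            outcome,
            ranked=ranked,
            second_match=second.get(sid),
        )
        rows.append((sid, dec.criterion, dec.identity_source, dec.final_name, dec.rationale))

    decisions = pd.DataFrame(
        rows, columns=["specimen_id", "criterion", "identity_source", "final_name", "rationale"]
    )
    decisions.to_csv(args.outdir / "decisions.tsv", sep="\t", index=False)
    print(decisions["criterion"].value_counts().to_string())
    print(f"wrote {args.outdir / 'decisions.tsv'}")


if __name__ == "__main__":
    main()
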