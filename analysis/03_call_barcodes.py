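#!/usr/bin/env python
"""Call one barcode per specimen from its demultiplexed reads.

Groups identical reads, takes the dominant sequence as the specimen barcode,
applies the coverage (> 50), total-count (> 10) and contamination-ratio
(<= 0.2 pass, < 0.35 flagged) filters, and screens translations for stop
codons.  Writes a QC table, the called barcodes, and the second dominant
read of every flagged specimen (needed for the C4 re-evaluation).
"""

import argparse
from pathlib import Path

import pandas as pd

from biocode.read_qc import FilterThresholds, call_barcode


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis/barcodes"))
    ap.add_argument("--min-coverage", type=int, default=50)
    ap.add_argument("--min-count", type=int, default=10)
    ap.add_argument("--ratio-pass", type=float, default=0.2)
    ap.add_argument("--ratio-flag", type=float, default=0.35)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    thresholds = FilterThresholds(
        args.min_coverage, args.min_count, args.ratio_pass, args.ratio_flag
    )
    manifest = pd.read_csv(args.indir / "inputs" / "manifest.tsv", sep="\t")
    assignments = pd.read_csv(args.indir / "demux" / "assignments.tsv", sep="\t")
    pools = assignments.groupby("specimen_id")["sequence"].apply(list)

    rows = []
    with open(args.outdir / "barcodes.fasta", "w") as bc, \
         open(args.outdir / "second_dominant.fasta", "w") as sd:
        for sid in manifest["specimen_id"]:
            ranked, outcome, record = call_barcode(
                sid, pools.get(sid, []), thresholds=thresholds
            )
            if ranked is None:
                rows.append((sid, 0, 0, 0, 0.0, "no-reads", "empty read pool", "", 0, ""))
                continue
            if record.translation_status == "numt-suspect":
                outcome.status = "fail"
                outcome.reasons.append("stop codons in every reading frame")
            rows.append(
                (sid, ranked.total_count, ranked.coverage, ranked.total_count,
                 round(ranked.ratio, 4), outcome.status, ";".join(outcome.reasons),
                 record.translation_status, record.length, record.length_class)
            )
            if outcome.status in ("pass", "flagged"):
                bc.write(f">{sid}\n{record.sequence}\n")
            if outcome.status == "flagged" and ranked.second_dominant:
                sd.write(f">{sid}\n{ranked.second_dominant}\n")

    qc = pd.DataFrame(
        rows,
        columns=["specimen_id", "n_reads", "coverage", "total", "ratio", "status",
                 "reasons", "translation_status", "length", "length_class"],
    )
    qc.to_csv(args.outdir / "qc.tsv", sep="\t", index=False)
    print(qc["status"].value_counts().to_string())
    print(f"wrote {args.outdir / 'qc.tsv'} and barcode FASTAs")


if __name__ == "__main__":
    main()
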