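#!/usr/bin/env python
"""Cluster accepted barcodes into MOTUs by objective clustering.

Takes the barcodes of specimens that passed the read filters (plus C4
rescues), aligns them to a common anchor, drops sequences with a large
internal gap, computes uncorrected pairwise distances with internal gaps as
a fifth character state, and groups connected components at the 3% headline
threshold plus a profile of alternative thresholds.  Exports the distance
matrix (TSV + PHYLIP), the partition, the profile and a single-linkage
dendrogram in Newick format.
"""

import argparse
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from biocode.motu_clustering import (
    cluster_barcodes,
    cluster_profile,
    single_linkage_newick,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis/motus"))
    ap.add_argument("--threshold", type=float, default=0.03)
    ap.add_argument("--profile", type=str, default="0.01,0.02,0.03,0.04,0.05")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    qc = pd.read_csv(args.indir / "barcodes" / "qc.tsv", sep="\t")
    decisions = pd.read_csv(args.indir / "congruence" / "decisions.tsv", sep="\t")
    crit = decisions.set_index("specimen_id")["criterion"]
    status = qc.set_index("specimen_id")["status"]
    accepted = {
        sid for sid, st in status.items()
        if st == "pass" or (st == "flagged" and crit.get(sid) == "C4")
    }

    records = [
        (rec.id, str(rec.seq))
        for rec in SeqIO.parse(args.indir / "barcodes" / "barcodes.fasta", "fasta")
        if rec.id in accepted
    ]
    ids = [r[0] for r in records]
    from biocode.motu_clustering import align_to_anchor

    aligned = align_to_anchor(ids, [r[1] for r in records])
    partition, dmat = cluster_barcodes(ids, aligned, threshold=args.threshold)
    thresholds = [float(t) for t in args.profile.split(",")]
    profile = cluster_profile(dmat, thresholds, headline_threshold=args.threshold)

    motu_map = partition.motu_of()
    pd.DataFrame(
        [(sid, motu_map[sid], args.threshold) for sid in sorted(motu_map)],
        columns=["specimen_id", "motu_id", "threshold"],
    ).to_csv(args.outdir / "partition.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"threshold": profile.thresholds, "motu_count": profile.counts}
    ).to_csv(args.outdir / "profile.tsv", sep="\t", index=False)

    dm = pd.DataFrame(dmat.values, index=dmat.ids, columns=dmat.ids)
    dm.to_csv(args.outdir / "distance_matrix.tsv", sep="\t")
    with open(args.outdir / "distance_matrix.phy", "w") as fh:
        fh.write(f"{len(dmat.ids)}\n")
        for sid, row in zip(dmat.ids, dmat.values):
            fh.write(sid + "  " + " ".join(f"{v:.6f}" for v in row) + "\n")
    (args.outdir / "dendrogram.nwk").write_text(single_linkage_newick(dmat) + "\n")

    print(f"{len(ids)} barcodes clustered into {partition.n_motus} MOTUs "
          f"at {args.threshold:.0%}")
    if partition.excluded:
        print(f"excluded: {partition.excluded}")
    print("profile:", dict(zip(profile.thresholds, profile.counts)))


if __name__ == "__main__":
    main()
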