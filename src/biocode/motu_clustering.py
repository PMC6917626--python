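"""Pairwise distances and objective clustering of barcodes into MOTUs.

Distances are uncorrected p-distances computed on a common alignment.
Terminal gap columns are excluded; within the overlap, an internal gap is
treated as a fifth character state: gap-vs-base counts as a difference and
gap-vs-gap as a match.  Objective clustering groups sequences into molecular
operational taxonomic units (MOTUs) as the connected components of the graph
joining every pair at distance <= threshold - i.e. single linkage cut at the
threshold.  Sequences with a long internal gap are excluded up front because
a sliding indel connects otherwise distant sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

GAP = ord("-")
DEFAULT_MIN_OVERLAP = 100
DEFAULT_MAX_INTERNAL_GAP = 30


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _core_span(arr: np.ndarray) -> tuple[int, int]:
    """(start, end) of the non-terminal-gap region; end exclusive."""
    non_gap = np.nonzero(arr != GAP)[0]
    if non_gap.size == 0:
        return 0, 0
    return int(non_gap[0]), int(non_gap[-1]) + 1


def pairwise_distance(
    a: str,
    b: str,
    gap_fifth: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Uncorrected distance between two rows of an alignment.

    Returns NaN when the overlap (columns where neither sequence has a
    terminal gap) is shorter than ``min_overlap`` - the pair is incomparable.
    With ``gap_fifth`` (default) internal gaps are a fifth character state;
    otherwise columns containing a gap are excluded from the comparison.
    """
    x, y = _as_bytes(a), _as_bytes(b)
    if x.size != y.size:
        raise ValueError("aligned sequences must have equal length")
    ax, bx = _core_span(x), _core_span(y)
    lo, hi = max(ax[0], bx[0]), min(ax[1], bx[1])
    if hi - lo < min_overlap:
        return float("nan")
    xs, ys = x[lo:hi], y[lo:hi]
    if gap_fifth:
        compared = xs.size
        diffs = int(np.count_nonzero(xs != ys))
    else:
        keep = (xs != GAP) & (ys != GAP)
        compared = int(np.count_nonzero(keep))
        if compared < min_overlap:
            return float("nan")
        diffs = int(np.count_nonzero(xs[keep] != ys[keep]))
    return diffs / compared if compared else float("nan")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, NaN = incomparable pair
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")


def distance_matrix(
    ids: list[str],
    aligned: list[str],
    gap_fifth: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-vs-all distances for rows of one alignment."""
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(aligned[i], aligned[j], gap_fifth, min_overlap)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        ids=list(ids),
        values=values,
        metadata={"gap_rule": "fifth-state" if gap_fifth else "excluded",
                  "min_overlap": min_overlap},
    )


@dataclass
class MOTUPartition:
    threshold: float
    clusters: dict[str, set[str]]  # cluster id (lowest member id) -> members
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_motus(self) -> int:
        return len(self.clusters)

    def motu_of(self) -> dict[str, str]:
        return {m: cid for cid, members in self.clusters.items() for m in members}


@dataclass
class MOTUProfile:
    thresholds: list[float]
    counts: list[int]
    headline_threshold: float = 0.03


def objective_cluster(d: DistanceMatrix, threshold: float) -> MOTUPartition:
    """Connected components of the graph joining pairs at distance <= threshold.

    Incomparable (NaN) pairs are never joined.  Cluster labels are canonical:
    each cluster is named after its lexicographically smallest member, so the
    partition is invariant to input order.
    """
    n = len(d.ids)
    with np.errstate(invalid="ignore"):
        adjacency = d.values <= threshold
    np.fill_diagonal(adjacency, True)
    _, labels = connected_components(csr_matrix(adjacency), directed=False)
    clusters: dict[int, set[str]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), set()).add(d.ids[idx])
    named = {min(members): members for members in clusters.values()}
    return MOTUPartition(threshold=threshold, clusters=named)


def cluster_profile(
    d: DistanceMatrix,
    thresholds: list[float],
    headline_threshold: float = 0.03,
) -> MOTUProfile:
    """MOTU counts over an ascending list of thresholds."""
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    counts = [objective_cluster(d, t).n_motus for t in thresholds]
    return MOTUProfile(list(thresholds), counts, headline_threshold)


def longest_internal_gap(aligned: str) -> int:
    core = aligned.strip("-")
    best = run = 0
    for c in core:
        if c == "-":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def exclude_gap_outliers(
    ids: list[str],
    aligned: list[str],
    max_internal_gap: int = DEFAULT_MAX_INTERNAL_GAP,
) -> list[tuple[str, str]]:
    """Sequences whose longest internal gap run exceeds the cutoff.

    Codon-length deletions (3 bp) pass untouched; a long internal gap slides
    against different partners and corrupts single-linkage chains, so such
    records are removed before the distance computation.
    """
    excluded = []
    for sid, seq in zip(ids, aligned):
        gap = longest_internal_gap(seq)
        if gap > max_internal_gap:
            excluded.append((sid, f"internal gap of {gap} bp > {max_internal_gap}"))
    return excluded


def cluster_barcodes(
    ids: list[str],
    aligned: list[str],
    threshold: float = 0.03,
    gap_fifth: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_internal_gap: int = DEFAULT_MAX_INTERNAL_GAP,
) -> tuple[MOTUPartition, DistanceMatrix]:
    """Exclude gap outliers, compute distances, and cluster at one threshold."""
    excluded = exclude_gap_outliers(ids, aligned, max_internal_gap)
    drop = {sid for sid, _ in excluded}
    kept = [(sid, seq) for sid, seq in zip(ids, aligned) if sid not in drop]
    d = distance_matrix([s for s, _ in kept], [q for _, q in kept], gap_fifth, min_overlap)
    part = objective_cluster(d, threshold)
    part.excluded = excluded
    return part, d


def align_to_anchor(ids: list[str], seqs: list[str], anchor: str | None = None) -> list[str]:
    """Project sequences onto the coordinates of an anchor sequence.

    A lightweight stand-in for a full multiple aligner: every sequence is
    globally aligned to the anchor (the longest input by default) and written
    in anchor coordinates with terminal gaps as padding.  Insertions relative
    to the anchor are dropped, which is exact for amplicons that are
    substrings/substitution variants of a common region (the synthetic reads)
    and adequate for deletion variants.
    """
    from Bio import Align

    if not seqs:
        return []
    anchor = anchor or max(seqs, key=len)
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    # terminal gaps are free so short amplicons nest inside the anchor
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    out = []
    for seq in seqs:
        if len(seq) == len(anchor):
            out.append(seq)
            continue
        aln = aligner.align(anchor, seq)[0]
        anchor_row, query_row = str(aln[0]), str(aln[1])
        projected = "".join(
            q for a, q in zip(anchor_row, query_row) if a != "-"
        )
        out.append(projected)
    return out


def single_linkage_newick(d: DistanceMatrix) -> str:
    """Newick dendrogram from single-linkage clustering of the matrix.

    Incomparable pairs are imputed at just above the matrix maximum so the
    tree stays connected; the dendrogram is a visual companion to the
    threshold clustering, not an inference.
    """
    from scipy.cluster.hierarchy import single, to_tree
    from scipy.spatial.distance import squareform

    values = d.values.copy()
    finite = values[np.isfinite(values)]
    fill = (finite.max() if finite.size else 1.0) * 1.05 + 1e-9
    values[~np.isfinite(values)] = fill
    np.fill_diagonal(values, 0.0)
    tree = to_tree(single(squareform(values, checks=False)))

    def render(node) -> str:
        if node.is_leaf():
            return d.ids[node.id]
        left, right = node.get_left(), node.get_right()
        lb = max(node.dist - left.dist, 0.0)
        rb = max(node.dist - right.dist, 0.0)
        return f"({render(left)}:{lb:.6f},{render(right)}:{rb:.6f})"

    return render(tree) + ";"
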