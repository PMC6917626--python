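"""Design of short sample tags and demultiplexing of tagged amplicon reads.

Specimens are labelled by attaching a short tag (default 9 bp) to both the
forward and reverse PCR primer.  Tag sets are designed so that every pair of
tags differs at 3 or more positions, which makes single sequencing errors in a
tag correctable by nearest-tag decoding.  Demultiplexing assigns each merged
read to a specimen by decoding the tags at both ends, in either strand
orientation, and trims tags and primer stubs off the assigned read.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .util import DNA_ALPHABET, hamming, max_homopolymer_run, revcomp

DEFAULT_TAG_LENGTH = 9
DEFAULT_MIN_DISTANCE = 3
MAX_HOMOPOLYMER = 3


@dataclass(frozen=True)
class Tag:
    """A fixed-length sample tag over {A,C,G,T}."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(DNA_ALPHABET):
            raise ValueError(f"tag must be uppercase ACGT: {self.sequence!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TagSet:
    """An ordered set of tags with a guaranteed minimum pairwise Hamming distance."""

    tags: list[Tag]
    min_distance: int = DEFAULT_MIN_DISTANCE

    def __post_init__(self) -> None:
        seqs = [t.sequence for t in self.tags]
        if len(set(seqs)) != len(seqs):
            raise ValueError("tags must be unique")
        if len(set(map(len, seqs))) > 1:
            raise ValueError("tags must share one length")
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = hamming(seqs[i], seqs[j])
                if d < self.min_distance:
                    raise ValueError(
                        f"tags {seqs[i]}/{seqs[j]} at distance {d} < {self.min_distance}"
                    )

    @property
    def tag_length(self) -> int:
        return len(self.tags[0]) if self.tags else 0

    def sequences(self) -> list[str]:
        return [t.sequence for t in self.tags]

    def nearest(self, observed: str) -> tuple[str | None, int]:
        """Nearest tag by Hamming distance; (None, distance) on a tie."""
        best_tag: str | None = None
        best_d = len(observed) + 1
        tied = False
        for t in self.tags:
            d = hamming(t.sequence, observed)
            if d < best_d:
                best_tag, best_d, tied = t.sequence, d, False
            elif d == best_d:
                tied = True
        return (None if tied else best_tag), best_d


def generate_tag_set(
    n: int,
    tag_length: int = DEFAULT_TAG_LENGTH,
    min_distance: int = DEFAULT_MIN_DISTANCE,
    seed: int = 0,
    max_attempts: int = 200_000,
) -> TagSet:
    """Design ``n`` tags of ``tag_length`` bp with pairwise Hamming distance >= ``min_distance``.

    Greedy rejection sampling: candidate tags are drawn uniformly, rejected if
    they contain a homopolymer run longer than 3 or sit too close to an
    accepted tag.  Deterministic for a given seed.

    Raises
    ------
    ValueError
        If the geometry is impossible (``min_distance > tag_length``) or no
        admissible set is found within ``max_attempts`` draws.
    """
    if n < 1:
        raise ValueError("need n >= 1 tags")
    if min_distance > tag_length:
        raise ValueError(
            f"min_distance {min_distance} cannot exceed tag length {tag_length}"
        )
    rng = random.Random(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} tags of length {tag_length} at distance "
                f">= {min_distance} within {max_attempts} attempts"
            )
        cand = "".join(rng.choice(DNA_ALPHABET) for _ in range(tag_length))
        if max_homopolymer_run(cand) > MAX_HOMOPOLYMER:
            continue
        if all(hamming(cand, t) >= min_distance for t in accepted):
            accepted.append(cand)
    return TagSet([Tag(s) for s in accepted], min_distance=min_distance)


@dataclass(frozen=True)
class ReadAssignment:
    specimen_id: str
    fwd_mismatches: int
    rev_mismatches: int
    orientation: str  # "forward" | "reverse-complement"
    trimmed_sequence: str


@dataclass
class DemuxResult:
    """Outcome of demultiplexing one read pool against a specimen manifest."""

    assignments: dict[str, ReadAssignment] = field(default_factory=dict)
    unassigned: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.assignments) + len(self.unassigned)

    def reads_by_specimen(self) -> dict[str, list[str]]:
        """Trimmed read sequences grouped by assigned specimen."""
        pools: dict[str, list[str]] = {}
        for a in self.assignments.values():
            pools.setdefault(a.specimen_id, []).append(a.trimmed_sequence)
        return pools


def demultiplex(
    reads: Iterable[tuple[str, str]],
    manifest: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str, str]],
    tagset: TagSet,
    max_mismatch: int = 0,
    trim_fwd_extra: int = 0,
    trim_rev_extra: int = 0,
) -> DemuxResult:
    """Assign tagged reads to specimens by decoding the tags at both read ends.

    Parameters
    ----------
    reads
        Iterable of ``(read_id, sequence)``; sequences are merged amplicons
        laid out as ``fwd_tag + fwd_primer + insert + rc(rev_primer) + rc(rev_tag)``.
    manifest
        Mapping ``specimen_id -> (fwd_tag, rev_tag)`` or an iterable of
        ``(specimen_id, fwd_tag, rev_tag)`` rows.  Tag pairs must be unique.
    max_mismatch
        Per-tag mismatch budget.  Must satisfy ``max_mismatch < ceil(min_distance/2)``
        so nearest-tag decoding cannot mis-assign.
    trim_fwd_extra, trim_rev_extra
        Additional bases (primer stubs) trimmed after the tags, by position.
    """
    if max_mismatch >= (tagset.min_distance + 1) // 2:
        raise ValueError(
            f"max_mismatch {max_mismatch} too large for tag distance {tagset.min_distance}"
        )
    if not isinstance(manifest, Mapping):
        manifest = {row[0]: (row[1], row[2]) for row in manifest}
    pair_to_specimen: dict[tuple[str, str], str] = {}
    for specimen_id, pair in manifest.items():
        pair = (pair[0], pair[1])
        if pair in pair_to_specimen:
            raise ValueError(f"duplicate tag pair {pair} in manifest")
        pair_to_specimen[pair] = specimen_id

    L = tagset.tag_length
    result = DemuxResult()
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < 2 * L:
            result.unassigned.append((read_id, "read shorter than two tags"))
            continue
        hit: ReadAssignment | None = None
        budget_fail = pair_fail = False
        for orientation in ("forward", "reverse-complement"):
            oriented = seq if orientation == "forward" else revcomp(seq)
            fwd_tag, fwd_d = tagset.nearest(oriented[:L])
            rev_tag, rev_d = tagset.nearest(revcomp(oriented[-L:]))
            if fwd_d > max_mismatch or rev_d > max_mismatch:
                budget_fail = True
                continue
            if fwd_tag is None or rev_tag is None:
                budget_fail = True  # tie within budget: undecodable
                continue
            specimen = pair_to_specimen.get((fwd_tag, rev_tag))
            if specimen is None:
                pair_fail = True
                continue
            trimmed = oriented[L + trim_fwd_extra : len(oriented) - L - trim_rev_extra]
            hit = ReadAssignment(specimen, fwd_d, rev_d, orientation, trimmed)
            break
        if hit is not None:
            result.assignments[read_id] = hit
        elif pair_fail and not budget_fail:
            result.unassigned.append((read_id, "tag pair not in manifest"))
        else:
            result.unassigned.append((read_id, "tag beyond mismatch budget"))
    return result
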