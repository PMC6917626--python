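"""Small sequence helpers shared across the pipeline."""

from __future__ import annotations

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (keeps N and gap characters)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single character."""
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def validate_nucleotides(seq: str, allow_n: bool = True, allow_gap: bool = False) -> None:
    allowed = set("ACGT") | ({"N"} if allow_n else set()) | ({"-"} if allow_gap else set())
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
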