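"""Internal matcher and identity-threshold taxonomy assignment."""

import random

import numpy as np
import pytest

from biocode.tax_assign import (
    AssignmentThresholds,
    MatchResult,
    ReferenceEntry,
    align_and_score,
    assign_taxonomy,
    is_named,
)
from biocode.util import revcomp


def _random_seq(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate_interior(seq, k, rng, lo=10, hi=None):
    hi = hi if hi is not None else len(seq) - 10
    out = list(seq)
    for pos in rng.sample(range(lo, hi), k):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def _entry(i, sequence, species="Genus000 species000", genus="Genus000",
           family="Arthidae", phylum="Arthropoda"):
    return ReferenceEntry(
        entry_id=f"REF{i:04d}",
        taxonomy=(phylum, "Arthria", "Arthformes", family, genus, species),
        sequence=sequence,
    )


class TestAlignAndScore:
    def test_identical_sequences(self):
        rng = random.Random(0)
        s = _random_seq(313, rng)
        identity, cover = align_and_score(s, s)
        assert identity == pytest.approx(100.0)
        assert cover == pytest.approx(100.0)

    def test_reverse_complement_orientation_found(self):
        rng = random.Random(1)
        s = _random_seq(313, rng)
        identity, cover = align_and_score(revcomp(s), s)
        assert identity == pytest.approx(100.0)
        assert cover == pytest.approx(100.0)

    def test_interior_mismatches_counted_exactly(self):
        rng = random.Random(2)
        ref = _random_seq(313, rng)
        query = _mutate_interior(ref, 9, rng)
        identity, cover = align_and_score(query, ref)
        assert identity == pytest.approx(100 * 304 / 313, abs=1e-6)
        assert cover == pytest.approx(100.0)

    def test_partial_overlap_gives_low_cover(self):
        rng = random.Random(3)
        ref = _random_seq(400, rng)
        query = ref[:200] + _random_seq(113, rng)
        _, cover = align_and_score(query, ref)
        assert cover < 80.0

    def test_agrees_with_bruteforce_dp_on_short_instances(self):
        """Independent Gotoh local-alignment oracle on instances <= 50 bp."""

        def gotoh_local(a, b, match=1, mismatch=-1, open_=-2, extend=-1):
            n, m = len(a), len(b)
            neg = float("-inf")
            M = np.full((n + 1, m + 1), 0.0)
            X = np.full((n + 1, m + 1), neg)  # gap in b
            Y = np.full((n + 1, m + 1), neg)  # gap in a
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = match if a[i - 1] == b[j - 1] else mismatch
                    X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend)
                    Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend)
                    M[i][j] = max(0.0, M[i - 1][j - 1] + s,
                                  X[i - 1][j - 1] + s, Y[i - 1][j - 1] + s)
                    best = max(best, M[i][j], X[i][j], Y[i][j])
            return best

        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-1,
        )
        rng = random.Random(4)
        for _ in range(15):
            a = _random_seq(rng.randint(20, 50), rng)
            b = _random_seq(rng.randint(20, 50), rng)
            assert aligner.score(a, b) == pytest.approx(gotoh_local(a, b))


class TestAssignTaxonomy:
    def _db(self, rng):
        ref = _random_seq(313, rng)
        return ref, [_entry(0, ref)]

    def test_identity_bands_set_rank(self):
        rng = random.Random(5)
        ref, db = self._db(rng)
        cases = [(6, "species"), (25, "genus"), (50, "family")]
        for k, expected_rank in cases:
            query = _mutate_interior(ref, k, rng)
            m = assign_taxonomy("S", query, db)
            assert m.assigned_rank == expected_rank, k
            if k <= 25:  # sparse mismatches: alignment provably gap-free
                assert m.percent_identity == pytest.approx(100 * (313 - k) / 313, abs=1e-6)

    def test_species_level_named_match(self):
        rng = random.Random(6)
        ref, db = self._db(rng)
        m = assign_taxonomy("S", _mutate_interior(ref, 4, rng), db)
        assert m.assigned_rank == "species"
        assert m.assigned_name == "Genus000 species000"
        assert m.named_match is True

    def test_unnamed_reference_recorded_as_not_named(self):
        rng = random.Random(7)
        ref = _random_seq(313, rng)
        db = [_entry(0, ref, species="Paracalanus sp.", genus="Paracalanus")]
        m = assign_taxonomy("S", _mutate_interior(ref, 2, rng), db)
        assert m.assigned_rank == "species"
        assert m.named_match is False

    def test_low_cover_hit_ineligible(self):
        rng = random.Random(8)
        ref = _random_seq(400, rng)
        db = [_entry(0, ref)]
        query = ref[:200] + _random_seq(113, rng)
        m = assign_taxonomy("S", query, db)
        assert m.assigned_rank == "none"
        assert m.best_entry_id is None

    def test_empty_database_gives_none(self):
        assert assign_taxonomy("S", "ACGT" * 80, []).assigned_rank == "none"

    def test_equal_identity_conflicting_species_demoted_to_genus(self):
        rng = random.Random(9)
        ref = _random_seq(313, rng)
        db = [
            _entry(0, ref, species="Genus000 alpha"),
            _entry(1, ref, species="Genus000 beta"),
        ]
        m = assign_taxonomy("S", _mutate_interior(ref, 2, rng), db)
        assert m.assigned_rank == "genus"
        assert m.assigned_name == "Genus000"

    def test_equal_identity_conflicting_genera_demoted_to_family(self):
        rng = random.Random(10)
        ref = _random_seq(313, rng)
        db = [
            _entry(0, ref, species="GenusA alpha", genus="GenusA"),
            _entry(1, ref, species="GenusB beta", genus="GenusB"),
        ]
        m = assign_taxonomy("S", _mutate_interior(ref, 2, rng), db)
        assert m.assigned_rank == "family"
        assert m.assigned_name == "Arthidae"

    def test_raising_thresholds_never_raises_rank(self):
        rng = random.Random(11)
        ref, db = self._db(rng)
        order = {"none": 0, "family": 1, "genus": 2, "species": 3}
        stricter = AssignmentThresholds(species=99.0, genus=95.0, family=90.0)
        for k in (2, 10, 20, 30, 45, 60):
            query = _mutate_interior(ref, k, rng)
            lo = assign_taxonomy("S", query, db)
            hi = assign_taxonomy("S", query, db, stricter)
            assert order[hi.assigned_rank] <= order[lo.assigned_rank]

    def test_full_recall_on_clean_world(self, clean_world):
        """Complete, correctly named references with intraspecific divergence
        below the species threshold give species-level recall of 1."""
        for s in clean_world.specimens:
            m = assign_taxonomy(
                s.specimen_id,
                clean_world.haplotypes[s.specimen_id],
                clean_world.reference_entries,
            )
            assert m.assigned_rank == "species"
            assert m.assigned_name == clean_world.binomial_of(s.species_id)


def test_is_named_patterns():
    assert is_named("Atergatis floridus")
    assert not is_named("Paracalanus sp.")
    assert not is_named("uncultured zooplankton")
    assert not is_named("Genus cf. species")
    assert not is_named("")
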