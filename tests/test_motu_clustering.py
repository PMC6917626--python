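"""Distances with gaps as a fifth state, and objective (single-linkage) MOTUs."""

import math

import numpy as np
import pytest

from biocode.motu_clustering import (
    DistanceMatrix,
    align_to_anchor,
    cluster_profile,
    distance_matrix,
    exclude_gap_outliers,
    longest_internal_gap,
    objective_cluster,
    pairwise_distance,
    single_linkage_newick,
)


class TestPairwiseDistance:
    def test_identical_sequences(self):
        assert pairwise_distance("ACGT" * 30, "ACGT" * 30) == 0.0

    def test_simple_substitution(self):
        assert pairwise_distance("AAAA", "AAAT", min_overlap=1) == 0.25

    def test_internal_gap_is_a_fifth_state(self):
        assert pairwise_distance("AA-A", "AAAA", min_overlap=1) == 0.25

    def test_gap_vs_gap_matches_under_fifth_state(self):
        assert pairwise_distance("AA-A", "AA-A", min_overlap=1) == 0.0

    def test_gap_columns_can_instead_be_excluded(self):
        # pairwise deletion: the gap column leaves the comparison entirely
        assert pairwise_distance("AA-A", "AAAA", gap_fifth=False, min_overlap=1) == 0.0
        assert (
            pairwise_distance("AA-T", "AAAA", gap_fifth=False, min_overlap=1)
            == pytest.approx(1 / 3)
        )

    def test_terminal_gaps_excluded(self):
        assert pairwise_distance("--ACGT", "TTACGT", min_overlap=1) == 0.0

    def test_short_overlap_incomparable(self):
        d = pairwise_distance("A" * 50 + "-" * 100, "-" * 100 + "A" * 50, min_overlap=100)
        assert math.isnan(d)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("AAA", "AAAA")


def _matrix(ids, values):
    return DistanceMatrix(ids=ids, values=np.array(values, dtype=float))


class TestObjectiveCluster:
    def test_all_pairs_beyond_threshold_gives_singletons(self):
        d = _matrix(["A", "B", "C"], [[0, .5, .5], [.5, 0, .5], [.5, .5, 0]])
        part = objective_cluster(d, 0.03)
        assert part.n_motus == 3

    def test_single_linkage_chains_join(self):
        d = _matrix(
            ["A", "B", "C"],
            [[0, .02, .04], [.02, 0, .02], [.04, .02, 0]],
        )
        part = objective_cluster(d, 0.03)
        assert part.clusters == {"A": {"A", "B", "C"}}

    def test_matches_bruteforce_union_find_at_scale(self):
        rng = np.random.default_rng(123)
        n = 200
        raw = rng.uniform(0, 0.1, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        ids = [f"X{i:03d}" for i in range(n)]
        d = DistanceMatrix(ids=ids, values=values)
        part = objective_cluster(d, 0.03)

        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if values[i, j] <= 0.03:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(n):
            oracle.setdefault(find(i), set()).add(ids[i])
        assert set(map(frozenset, part.clusters.values())) == set(
            map(frozenset, oracle.values())
        )

    def test_partition_invariant_under_permutation(self):
        rng = np.random.default_rng(7)
        n = 30
        raw = rng.uniform(0, 0.08, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        ids = [f"X{i:02d}" for i in range(n)]
        part1 = objective_cluster(DistanceMatrix(ids, values), 0.03)
        perm = rng.permutation(n)
        part2 = objective_cluster(
            DistanceMatrix([ids[i] for i in perm], values[np.ix_(perm, perm)]), 0.03
        )
        assert part1.clusters == part2.clusters

    def test_incomparable_pairs_never_join(self):
        values = np.array([[0.0, np.nan], [np.nan, 0.0]])
        part = objective_cluster(DistanceMatrix(["A", "B"], values), 1.0)
        assert part.n_motus == 2


class TestClusterProfile:
    def test_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(11)
        n = 60
        raw = rng.uniform(0, 0.1, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        d = DistanceMatrix([f"X{i}" for i in range(n)], values)
        profile = cluster_profile(d, [0.0, 0.01, 0.02, 0.03, 0.05, 0.1])
        assert all(a >= b for a, b in zip(profile.counts, profile.counts[1:]))

    def test_zero_threshold_separates_distinct_sequences(self):
        seqs = ["ACGT" * 30, "ACGT" * 30, "TGCA" * 30]
        d = distance_matrix(["A", "B", "C"], seqs, min_overlap=10)
        part = objective_cluster(d, 0.0)
        assert part.clusters == {"A": {"A", "B"}, "C": {"C"}}

    def test_unsorted_thresholds_rejected(self):
        d = _matrix(["A"], [[0.0]])
        with pytest.raises(ValueError):
            cluster_profile(d, [0.05, 0.01])


class TestGapOutliers:
    def test_no_gaps_no_exclusions(self):
        assert exclude_gap_outliers(["A"], ["ACGT" * 40]) == []

    def test_large_internal_gap_excluded(self):
        seq = "ACGT" * 30 + "-" * 45 + "ACGT" * 30
        out = exclude_gap_outliers(["A"], [seq], max_internal_gap=30)
        assert out == [("A", "internal gap of 45 bp > 30")]

    def test_codon_length_deletion_retained(self):
        seq = "ACGT" * 30 + "---" + "ACGT" * 30
        assert exclude_gap_outliers(["A"], [seq], max_internal_gap=30) == []

    def test_terminal_gaps_not_counted(self):
        assert longest_internal_gap("-" * 50 + "ACGT" * 30) == 0


class TestAnchorAlignment:
    def test_subfragment_padded_with_terminal_gaps(self):
        anchor = "ACGTAACGTTACGGTACGTA" * 5
        sub = anchor[20:80]
        out = align_to_anchor(["a", "s"], [anchor, sub])
        assert out[0] == anchor
        assert len(out[1]) == len(anchor)
        assert out[1].strip("-") == sub

    def test_deletion_appears_as_internal_gap(self):
        anchor = "ACGTAACGTTACGGTACGTA" * 5
        q = anchor[:30] + anchor[33:]
        out = align_to_anchor(["a", "q"], [anchor, q])
        assert len(out[1]) == len(anchor)
        assert out[1].count("-") == 3
        assert longest_internal_gap(out[1]) == 3


class TestRecoveryAndExport:
    def test_world_recovered_at_threshold_inside_the_gap(self, clean_world):
        ids = [s.specimen_id for s in clean_world.specimens]
        seqs = [clean_world.haplotypes[i] for i in ids]
        d = distance_matrix(ids, seqs)
        for t in (0.02, 0.03, 0.04):
            part = objective_cluster(d, t)
            assert part.n_motus == clean_world.config.n_species
        truth = clean_world.species_of()
        part = objective_cluster(d, 0.03)
        for members in part.clusters.values():
            assert len({truth[m] for m in members}) == 1

    def test_newick_export_is_parseable(self, clean_world):
        from io import StringIO

        from Bio import Phylo

        ids = [s.specimen_id for s in clean_world.specimens]
        seqs = [clean_world.haplotypes[i] for i in ids]
        d = distance_matrix(ids, seqs)
        tree = Phylo.read(StringIO(single_linkage_newick(d)), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == set(ids)
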