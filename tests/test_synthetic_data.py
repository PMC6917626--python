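"""The synthetic world must honour its own statistical contracts."""

import numpy as np
import pytest
from Bio.Seq import Seq

from biocode.motu_clustering import pairwise_distance
from biocode.synthetic_data import (
    SimulationConfig,
    default_taxonomy,
    generate_world,
    simulate_reference_db,
    simulate_species_pool,
    simulate_specimens_and_reads,
)


def _p(a, b):
    return pairwise_distance(a, b, min_overlap=1)


class TestSpeciesPool:
    def test_single_species_needs_no_pairwise_constraint(self):
        cfg = SimulationConfig(n_species=1, seed=0)
        pool = simulate_species_pool(cfg)
        assert len(pool) == 1
        assert len(next(iter(pool.values()))) == cfg.amplicon_length

    def test_all_pairwise_distances_respect_floor(self):
        cfg = SimulationConfig(n_species=20, inter_divergence_min=0.05, seed=1)
        pool = list(simulate_species_pool(cfg).values())
        checked = 0
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                assert _p(pool[i], pool[j]) >= 0.05
                checked += 1
        assert checked == 190

    def test_sequences_are_stop_free_in_frame(self):
        cfg = SimulationConfig(n_species=10, seed=4)
        for seq in simulate_species_pool(cfg).values():
            sub = seq[: 3 * (len(seq) // 3)]
            assert "*" not in str(Seq(sub).translate(table=5))

    def test_infeasible_divergence_is_a_config_error(self):
        with pytest.raises(ValueError):
            SimulationConfig(inter_divergence_min=0.5).validate()

    def test_gap_must_exist_by_construction(self):
        with pytest.raises(ValueError):
            SimulationConfig(intra_divergence_max=0.06, inter_divergence_min=0.05).validate()


class TestSpecimensAndReads:
    def test_intraspecific_variants_within_bound(self):
        cfg = SimulationConfig(
            n_species=20, specimens_per_species=2, intra_divergence_max=0.01,
            reads_per_specimen_mean=0, seed=2,
        )
        world = generate_world(cfg)
        for s in world.specimens:
            d = _p(world.haplotypes[s.specimen_id], world.species_sequences[s.species_id])
            assert d <= 0.01

    def test_noise_free_pools_are_monomorphic(self, clean_world):
        from biocode.read_qc import rank_reads
        from biocode.pipeline import run_pipeline

        res = run_pipeline(clean_world)
        for sid, rset in res.ranked.items():
            assert rset.ratio == 0.0
            assert len(rset.unique_sequences) == 1

    def test_contaminant_share_matches_configuration(self):
        cfg = SimulationConfig(
            n_species=5, specimens_per_species=4, contamination_fraction=0.3,
            reads_per_specimen_mean=200, per_base_error=0.0, seed=7,
        )
        world = generate_world(cfg)
        shares = []
        for sid, pool in world.read_pools().items():
            if pool:
                shares.append(sum(r.true_source != sid for r in pool) / len(pool))
        assert abs(np.mean(shares) - 0.3) < 0.05

    def test_total_dropout_gives_empty_pools(self):
        cfg = SimulationConfig(n_species=3, specimens_per_species=2, dropout_rate=1.0, seed=5)
        world = generate_world(cfg)
        assert world.reads == []

    def test_every_read_traceable_to_a_specimen(self, noisy_world):
        ids = {s.specimen_id for s in noisy_world.specimens}
        for r in noisy_world.reads:
            assert r.true_source in ids
            assert r.host_specimen in ids

    def test_bit_identical_across_runs_with_same_seed(self):
        cfg = SimulationConfig(n_species=3, specimens_per_species=2,
                               reads_per_specimen_mean=30, seed=9)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert w1.species_sequences == w2.species_sequences
        assert w1.reads == w2.reads
        assert [e.taxonomy for e in w1.reference_entries] == [
            e.taxonomy for e in w2.reference_entries
        ]

    def test_codon_deletion_variant_is_shorter_by_three(self):
        cfg = SimulationConfig(n_species=3, specimens_per_species=2,
                               reads_per_specimen_mean=0,
                               codon_deletion_specimens=1, seed=6)
        world = generate_world(cfg)
        lengths = sorted(len(h) for h in world.haplotypes.values())
        assert lengths[0] == cfg.amplicon_length - 3
        assert lengths[1] == cfg.amplicon_length


class TestReferenceDb:
    def _world(self, **kw):
        cfg = SimulationConfig(
            n_species=100, specimens_per_species=1, reads_per_specimen_mean=0, **kw
        )
        pool = simulate_species_pool(cfg)
        taxonomy = default_taxonomy(list(pool))
        rng = np.random.default_rng(cfg.seed)
        return simulate_specimens_and_reads(pool, taxonomy, cfg, rng), cfg

    def test_misidentification_count_and_truth_flags(self):
        world, cfg = self._world(ref_misid_rate=0.1, seed=3)
        entries, truth = simulate_reference_db(world, cfg)
        misid = truth[truth["status"] == "misidentified"]
        assert len(misid) == 10
        by_id = {e.entry_id: e for e in entries}
        for _, row in misid.iterrows():
            assert by_id[row.entry_id].taxonomy != world.taxonomy[row.true_species]
        correct = truth[truth["status"] == "correct"]
        for _, row in correct.iterrows():
            assert by_id[row.entry_id].taxonomy == world.taxonomy[row.true_species]

    def test_unnamed_entries_get_placeholder_labels(self):
        world, cfg = self._world(named_fraction=0.8, seed=4)
        entries, truth = simulate_reference_db(world, cfg)
        unnamed = [e for e in entries if e.species_label.endswith("sp.")]
        assert len(unnamed) == 20

    def test_zero_coverage_means_empty_database(self):
        world, cfg = self._world(ref_coverage=0.0, seed=5)
        entries, truth = simulate_reference_db(world, cfg)
        assert entries == [] and truth.empty
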