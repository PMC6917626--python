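"""Ground-truthed synthetic worlds for exercising the barcoding pipeline.

The generator emulates the statistical structure a specimen-barcoding survey
assumes: a pool of species whose COI-like sequences are separated by a
barcoding gap (small intraspecific, large interspecific divergence), around
a hundred specimens sorted into phylum-level morphotypes (occasionally
mis-sorted), dual-tagged amplicon reads per specimen with sequencing error
and cross-specimen contamination at controlled rates, specimen-level
amplification dropout, and a reference database containing named species,
unnamed placeholders ("Genus sp.") and deliberately misidentified entries.

Every random draw flows from one integer seed, every read is traceable to
its true source specimen, and truth tables are emitted alongside the
pipeline inputs so recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .congruence import MORPHOTYPE_VOCABULARY
from .tag_demux import TagSet, generate_tag_set
from .tax_assign import ReferenceEntry
from .util import revcomp

# Mini-barcode PCR construct layout: tag + primer + insert + rc(primer) + rc(tag).
# Concrete primer realisations (degenerate positions fixed) - the demultiplexer
# trims them by position, so only their lengths matter downstream.
PRIMER_FWD = "GGTACAGGTTGAACTGTTTATCCTCC"
PRIMER_REV = "TAAACTTCAGGGTGACCAAAAAATCA"

STOP_CODONS_INVERTEBRATE_MITO = {"TAA", "TAG"}
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; defaults emulate the survey conditions
    the pipeline is built for (see docs/methods.md)."""

    n_species: int = 20
    specimens_per_species: int = 5
    intra_divergence_max: float = 0.01  # fraction of sites
    inter_divergence_min: float = 0.05
    amplicon_length: int = 313  # mini-barcode; 658 for the full barcode
    reads_per_specimen_mean: float = 200.0
    per_base_error: float = 0.001
    contamination_fraction: float = 0.1
    missort_rate: float = 0.0
    named_fraction: float = 1.0
    ref_misid_rate: float = 0.0
    ref_coverage: float = 1.0  # fraction of species present in the reference db
    dropout_rate: float = 0.0
    codon_deletion_specimens: int = 0  # haplotypes given one in-frame codon deletion
    translation_table: int = 5
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "intra_divergence_max": self.intra_divergence_max,
            "inter_divergence_min": self.inter_divergence_min,
            "per_base_error": self.per_base_error,
            "contamination_fraction": self.contamination_fraction,
            "missort_rate": self.missort_rate,
            "named_fraction": self.named_fraction,
            "ref_misid_rate": self.ref_misid_rate,
            "ref_coverage": self.ref_coverage,
            "dropout_rate": self.dropout_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.intra_divergence_max >= self.inter_divergence_min:
            raise ValueError(
                "intra_divergence_max must be < inter_divergence_min "
                "(a barcoding gap must exist by construction)"
            )
        if self.inter_divergence_min > 0.2:
            raise ValueError(
                "inter_divergence_min > 0.2 is infeasible for third-codon-position "
                "mutation (max attainable divergence ~1/3 of sites)"
            )
        if self.amplicon_length < 100:
            raise ValueError("amplicon_length must be >= 100")
        if self.n_species < 1 or self.specimens_per_species < 1:
            raise ValueError("need at least one species and one specimen per species")


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    species_id: str
    true_phylum: str
    morphotype: str  # assigned (possibly mis-sorted) label
    tag_fwd: str
    tag_rev: str


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str  # full tagged construct as sequenced
    host_specimen: str  # specimen whose tags it carries / pool it belongs to
    true_source: str  # specimen whose amplicon it really is
    orientation: str


@dataclass
class TrueWorld:
    """A fully specified synthetic survey with truth annotations."""

    config: SimulationConfig
    species_sequences: dict[str, str]
    taxonomy: dict[str, tuple[str, ...]]  # species_id -> 6-rank taxonomy
    specimens: list[SpecimenRecord]
    haplotypes: dict[str, str]  # specimen_id -> true amplicon sequence
    tag_set: TagSet
    reads: list[SimRead]
    reference_entries: list[ReferenceEntry] = field(default_factory=list)
    reference_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.specimen_id, s.tag_fwd, s.tag_rev, s.morphotype)
                for s in self.specimens
            ],
            columns=["specimen_id", "tag_fwd", "tag_rev", "morphotype"],
        )

    def pooled_reads(self) -> list[tuple[str, str]]:
        return [(r.read_id, r.sequence) for r in self.reads]

    def read_pools(self) -> dict[str, list[SimRead]]:
        pools: dict[str, list[SimRead]] = {s.specimen_id: [] for s in self.specimens}
        for r in self.reads:
            pools[r.host_specimen].append(r)
        return pools

    def species_of(self) -> dict[str, str]:
        return {s.specimen_id: s.species_id for s in self.specimens}

    def binomial_of(self, species_id: str) -> str:
        return self.taxonomy[species_id][-1]


# ---------------------------------------------------------------------------
# sequence construction


def _third_positions(length: int) -> np.ndarray:
    return np.arange(2, 3 * (length // 3), 3)


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    """A random in-frame sequence with no stop codons (invertebrate
    mitochondrial code: TAA/TAG)."""
    codons = []
    for _ in range(math.ceil(length / 3)):
        while True:
            codon = "".join(rng.choice(list(_BASES), size=3))
            if codon not in STOP_CODONS_INVERTEBRATE_MITO:
                codons.append(codon)
                break
    return "".join(codons)[:length]


def _mutate_site(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    """Substitute the base at ``pos`` (a third codon position) without
    creating a stop codon."""
    codon_start = pos - 2
    choices = [b for b in _BASES if b != seq[pos]]
    rng.shuffle(choices)
    for b in choices:
        codon = "".join(seq[codon_start:codon_start + 2]) + b
        if codon not in STOP_CODONS_INVERTEBRATE_MITO:
            seq[pos] = b
            return
    # all alternatives create a stop (cannot happen for TA- prefix: TAT/TAC fine)


def _p_distance(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def simulate_species_pool(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Species sequences separated by at least ``inter_divergence_min``.

    One random in-frame ancestor is mutated at third codon positions
    (substitution probability 0.7 per site) independently per species;
    candidates closer than the divergence floor to an accepted species are
    rejection-sampled away.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    length = config.amplicon_length
    ancestor = _random_coding_sequence(length, rng)
    thirds = _third_positions(length)
    species: dict[str, str] = {}
    attempts = 0
    while len(species) < config.n_species:
        attempts += 1
        if attempts > 200 * config.n_species:
            raise ValueError(
                "could not satisfy inter_divergence_min by rejection sampling; "
                "lower the divergence floor or the species count"
            )
        cand = list(ancestor)
        for pos in thirds:
            if rng.random() < 0.7:
                _mutate_site(cand, int(pos), rng)
        cand_seq = "".join(cand)
        if all(
            _p_distance(cand_seq, other) >= config.inter_divergence_min
            for other in species.values()
        ):
            species[f"S{len(species):03d}"] = cand_seq
    return species


def default_taxonomy(species_ids: list[str]) -> dict[str, tuple[str, ...]]:
    """A plausible six-rank taxonomy: phyla cycle through the morphotype
    vocabulary, each species gets its own genus, families follow phyla."""
    taxonomy = {}
    for i, sid in enumerate(species_ids):
        phylum = MORPHOTYPE_VOCABULARY[i % len(MORPHOTYPE_VOCABULARY)]
        taxonomy[sid] = (
            phylum,
            f"{phylum[:5]}ia",
            f"{phylum[:4]}formes",
            f"{phylum[:4]}idae",
            f"Genus{i:03d}",
            f"Genus{i:03d} species{i:03d}",
        )
    return taxonomy


# ---------------------------------------------------------------------------
# specimens and reads


def _haplotype(
    species_seq: str, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """An intraspecific variant within ``intra_divergence_max`` of its species."""
    kmax = int(config.intra_divergence_max * len(species_seq))
    k = int(rng.integers(0, kmax + 1)) if kmax else 0
    seq = list(species_seq)
    thirds = _third_positions(len(species_seq))
    if k:
        for pos in rng.choice(thirds, size=min(k, thirds.size), replace=False):
            _mutate_site(seq, int(pos), rng)
    return "".join(seq)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        out[pos] = _BASES[int(rng.integers(0, 4))]
    return "".join(out)


def _delete_codon(seq: str, rng: np.random.Generator) -> str:
    n_codons = len(seq) // 3
    c = int(rng.integers(n_codons // 4, 3 * n_codons // 4))  # interior codon
    return seq[: 3 * c] + seq[3 * c + 3 :]


def simulate_specimens_and_reads(
    species_sequences: dict[str, str],
    taxonomy: dict[str, tuple[str, ...]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TrueWorld:
    """Specimens, tag assignments, haplotypes and tagged read pools.

    Each non-dropout specimen receives a Poisson number of reads; a read is a
    contaminant (drawn from one randomly chosen donor specimen, emulating a
    neighbouring-well carry-over) with probability ``contamination_fraction``
    and carries the host's tag pair either way.  Per-base substitution errors
    apply to the whole construct, and the strand orientation of each read is
    random.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    species_ids = list(species_sequences)
    n_specimens = config.n_species * config.specimens_per_species

    side = math.ceil(math.sqrt(n_specimens))
    tag_seed = (config.seed * 1_000_003 + 17) % (2**31)
    tag_set = generate_tag_set(2 * side, seed=tag_seed)
    fwd_tags = [t.sequence for t in tag_set.tags[:side]]
    rev_tags = [t.sequence for t in tag_set.tags[side:]]

    specimens: list[SpecimenRecord] = []
    haplotypes: dict[str, str] = {}
    idx = 0
    for sp in species_ids:
        for _ in range(config.specimens_per_species):
            specimen_id = f"SP{idx:04d}"
            phylum = taxonomy[sp][0]
            morphotype = phylum
            if config.missort_rate and rng.random() < config.missort_rate:
                others = [p for p in MORPHOTYPE_VOCABULARY if p != phylum]
                morphotype = others[int(rng.integers(0, len(others)))]
            specimens.append(
                SpecimenRecord(
                    specimen_id=specimen_id,
                    species_id=sp,
                    true_phylum=phylum,
                    morphotype=morphotype,
                    tag_fwd=fwd_tags[idx // side],
                    tag_rev=rev_tags[idx % side],
                )
            )
            hap = _haplotype(species_sequences[sp], config, rng)
            haplotypes[specimen_id] = hap
            idx += 1
    for i in range(min(config.codon_deletion_specimens, n_specimens)):
        sid = specimens[i].specimen_id
        haplotypes[sid] = _delete_codon(haplotypes[sid], rng)

    reads: list[SimRead] = []
    counter = 0
    all_ids = [s.specimen_id for s in specimens]
    by_id = {s.specimen_id: s for s in specimens}
    for s in specimens:
        if config.dropout_rate and rng.random() < config.dropout_rate:
            continue
        n_reads = int(rng.poisson(config.reads_per_specimen_mean))
        donor = s.specimen_id
        if len(all_ids) > 1:
            while donor == s.specimen_id:
                donor = all_ids[int(rng.integers(0, len(all_ids)))]
        for _ in range(n_reads):
            source = (
                donor
                if config.contamination_fraction
                and rng.random() < config.contamination_fraction
                else s.specimen_id
            )
            construct = (
                s.tag_fwd
                + PRIMER_FWD
                + haplotypes[source]
                + revcomp(PRIMER_REV)
                + revcomp(s.tag_rev)
            )
            construct = _apply_errors(construct, config.per_base_error, rng)
            orientation = "forward"
            if rng.random() < 0.5:
                construct = revcomp(construct)
                orientation = "reverse-complement"
            reads.append(
                SimRead(
                    read_id=f"R{counter:07d}",
                    sequence=construct,
                    host_specimen=s.specimen_id,
                    true_source=source,
                    orientation=orientation,
                )
            )
            counter += 1

    return TrueWorld(
        config=config,
        species_sequences=dict(species_sequences),
        taxonomy=dict(taxonomy),
        specimens=specimens,
        haplotypes=haplotypes,
        tag_set=tag_set,
        reads=reads,
    )


# ---------------------------------------------------------------------------
# reference database


def simulate_reference_db(
    world: TrueWorld,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReferenceEntry], pd.DataFrame]:
    """A reference database with configurable coverage and imperfections.

    ``ref_coverage`` of the species appear at all; ``named_fraction`` of the
    entries carry a proper binomial (the remainder become "Genus sp.");
    ``ref_misid_rate`` of the entries are given the taxonomy string of a
    different species, with the truth recorded.  Returns the entries and a
    truth table (entry_id, true_species, status in {correct, unnamed,
    misidentified}).
    """
    config = config or world.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    species_ids = list(world.species_sequences)
    n_included = round(config.ref_coverage * len(species_ids))
    included = sorted(
        rng.choice(species_ids, size=n_included, replace=False).tolist()
    )
    n_named = round(config.named_fraction * n_included)
    named_set = set(rng.choice(included, size=n_named, replace=False).tolist()) if included else set()
    n_misid = round(config.ref_misid_rate * n_included)
    misid_set = set(rng.choice(included, size=n_misid, replace=False).tolist()) if included else set()

    entries: list[ReferenceEntry] = []
    truth_rows = []
    for j, sp in enumerate(included):
        taxonomy = world.taxonomy[sp]
        status = "correct"
        if sp in misid_set and len(species_ids) > 1:
            wrong = sp
            while wrong == sp:
                wrong = species_ids[int(rng.integers(0, len(species_ids)))]
            taxonomy = world.taxonomy[wrong]
            status = "misidentified"
        if sp not in named_set:
            taxonomy = taxonomy[:-1] + (f"{taxonomy[4]} sp.",)
            status = "unnamed" if status == "correct" else status
        entries.append(
            ReferenceEntry(
                entry_id=f"REF{j:04d}",
                taxonomy=taxonomy,
                sequence=world.species_sequences[sp],
            )
        )
        truth_rows.append((f"REF{j:04d}", sp, status))
    truth = pd.DataFrame(truth_rows, columns=["entry_id", "true_species", "status"])
    return entries, truth


def generate_world(config: SimulationConfig) -> TrueWorld:
    """Build a complete world (species, specimens, reads, reference db) from
    one seed; bit-identical across runs with the same configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = simulate_species_pool(config, rng)
    taxonomy = default_taxonomy(list(species))
    world = simulate_specimens_and_reads(species, taxonomy, config, rng)
    entries, truth = simulate_reference_db(world, config)
    world.reference_entries = entries
    world.reference_truth = truth
    return world


# ---------------------------------------------------------------------------
# file output


def write_world(world: TrueWorld, outdir) -> dict[str, str]:
    """Write pipeline inputs plus truth tables as plain-text files.

    Produces: manifest.tsv, reads.fasta, reference.fasta (headers
    ``id|phylum;class;order;family;genus;species``), species.fasta,
    truth_reads.tsv, truth_reference.tsv, config.tsv.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    manifest = world.manifest()
    truth_specimens = pd.DataFrame(
        [
            (s.specimen_id, s.species_id, s.true_phylum, s.morphotype,
             world.binomial_of(s.species_id))
            for s in world.specimens
        ],
        columns=["specimen_id", "true_species", "true_phylum", "morphotype",
                 "true_binomial"],
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    truth_specimens.to_csv(outdir / "truth_specimens.tsv", sep="\t", index=False)
    paths["manifest"] = str(outdir / "manifest.tsv")

    with open(outdir / "reads.fasta", "w") as fh:
        for r in world.reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
    paths["reads"] = str(outdir / "reads.fasta")

    with open(outdir / "reference.fasta", "w") as fh:
        for e in world.reference_entries:
            fh.write(f">{e.entry_id}|{';'.join(e.taxonomy)}\n{e.sequence}\n")
    paths["reference"] = str(outdir / "reference.fasta")

    with open(outdir / "species.fasta", "w") as fh:
        for sid, seq in world.species_sequences.items():
            fh.write(f">{sid}\n{seq}\n")

    pd.DataFrame(
        [(r.read_id, r.host_specimen, r.true_source, r.orientation) for r in world.reads],
        columns=["read_id", "host_specimen", "true_source", "orientation"],
    ).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    world.reference_truth.to_csv(outdir / "truth_reference.tsv", sep="\t", index=False)

    cfg = pd.Series({k: getattr(world.config, k) for k in vars(world.config)})
    cfg.to_csv(outdir / "config.tsv", sep="\t", header=False)
    paths["config"] = str(outdir / "config.tsv")
    return paths


def read_reference_fasta(path) -> list[ReferenceEntry]:
    """Parse a reference FASTA with ``id|rank1;...;rank6`` headers."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entry_id, _, tax = rec.description.partition("|")
        entries.append(
            ReferenceEntry(
                entry_id=entry_id.strip(),
                taxonomy=tuple(t.strip() for t in tax.split(";")),
                sequence=str(rec.seq).upper(),
            )
        )
    return entries
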