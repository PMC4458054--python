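"""Synthetic parasite-host transcriptome mixtures with ground truth.

The generator emulates the reference structure the classifier faces in a
real parasite-host interface experiment: two species-specific contig
sets sharing homologous genes at tunable identity plus species-private
genes, a genus-proxy unigene set (the parasite's genes diverged a few
percent, standing in for congeneric relatives), and a family-labelled
database (both species' genes diverged, carrying family tokens) -- and
error-bearing reads mixed at a configurable, deliberately unequal ratio
(the parasite tissue yields ~16.8-fold more RNA per unit mass than the
host, so the default parasite:host read ratio is 16.8).

Divergence is applied as uniform random substitutions without indels
(an optional indel rate exercises gapped alignment); since orthologs
then stay column-aligned, the realized identity of a pair is exact by
construction. Each output object draws from its own deterministic
random stream derived from the master seed, so e.g. adding genes does
not perturb the reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .seqio import Read, ReadPair, SequenceRecord, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")

# stream tags: each (seed, tag, ...) tuple seeds an independent generator
_STREAM_GENES = 0
_STREAM_READS = 1
_STREAM_DIVERGENCE = 2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    ``ortholog_identity`` is the (low, high) percent-identity range that
    per-gene ortholog divergence is drawn from; ``genus_divergence`` is
    the percent divergence of the genus-proxy and family-database copies;
    ``mix_ratio`` is the expected parasite:host read ratio.
    """

    seed: int
    n_genes_shared: int = 30
    n_genes_private_a: int = 10
    n_genes_private_b: int = 10
    gene_length: tuple[int, int] = (300, 3000)
    ortholog_identity: tuple[float, float] = (75.0, 95.0)
    genus_divergence: float = 5.0
    read_length: int = 100
    error_rate: float = 0.005
    indel_rate: float = 0.0
    paired: bool = False
    fragment_length: tuple[float, float] = (300.0, 50.0)  # (mean, sd)
    mix_ratio: float = 16.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        lo, hi = self.ortholog_identity
        if not (0.0 < lo <= hi <= 100.0):
            raise ValueError("ortholog identities must lie in (0, 100]")
        if not (0.0 <= self.genus_divergence < 100.0):
            raise ValueError("genus_divergence must lie in [0, 100)")
        if self.mix_ratio <= 0:
            raise ValueError("mix_ratio must be positive")


class ReadOrigin(NamedTuple):
    species: str
    gene_id: str
    position: int  # 0-based start on the source gene's forward strand
    strand: str


@dataclass
class GroundTruth:
    """Per-read origins and per-gene ortholog relations."""

    reads: dict[str, ReadOrigin] = field(default_factory=dict)
    orthologs: dict[str, tuple[str, float]] = field(default_factory=dict)

    def labels(self) -> dict[str, str]:
        return {rid: origin.species for rid, origin in self.reads.items()}


@dataclass
class SimulatedReferences:
    """All reference sets one simulation produces."""

    contigs_a: list[SequenceRecord]
    contigs_b: list[SequenceRecord]
    genus_refs: list[SequenceRecord]
    family_db: list[SequenceRecord]
    subject_to_family: dict[str, str]
    family_to_species: dict[str, str]
    truth: GroundTruth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(
    seq: str, divergence_pct: float, rng: np.random.Generator, indel_rate: float = 0.0
) -> str:
    """Substitute an exact round(L * divergence/100) positions (always to a
    different base) and optionally sprinkle 1-2 bp indels."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_sub = round(len(seq) * divergence_pct / 100.0)
    if n_sub > 0:
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub)
        idx = np.searchsorted(BASES, arr[pos])
        arr[pos] = BASES[(idx + shift) % 4]
    out = arr.tobytes().decode()
    if indel_rate > 0:
        n_indel = rng.binomial(len(out), indel_rate)
        for _ in range(n_indel):
            p = int(rng.integers(0, len(out)))
            size = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                out = out[:p] + out[p + size :]
            else:
                out = out[:p] + _random_sequence(rng, size) + out[p:]
    return out


def simulate_transcriptomes(config: SimConfig) -> SimulatedReferences:
    """Generate both species' contig sets, the genus-proxy references and
    the family-labelled database, deterministically from the seed.

    Shared genes appear in both species at a per-gene identity drawn from
    ``config.ortholog_identity`` (realized identity is exact to within
    rounding of the substitution count, i.e. within +-2 points of the
    sampled target).
    """
    contigs_a: list[SequenceRecord] = []
    contigs_b: list[SequenceRecord] = []
    genus_refs: list[SequenceRecord] = []
    family_db: list[SequenceRecord] = []
    subject_to_family: dict[str, str] = {}
    truth = GroundTruth()

    lo, hi = config.gene_length
    div_rng = np.random.default_rng([config.seed, _STREAM_DIVERGENCE])

    def gene_rng(index: int) -> np.random.Generator:
        return np.random.default_rng([config.seed, _STREAM_GENES, index])

    index = 0
    for k in range(config.n_genes_shared):
        rng = gene_rng(index)
        index += 1
        length = int(rng.integers(lo, hi + 1))
        seq_a = _random_sequence(rng, length)
        target_identity = float(div_rng.uniform(*config.ortholog_identity))
        seq_b = _mutate(seq_a, 100.0 - target_identity, rng, config.indel_rate)
        id_a, id_b = f"A_s{k:04d}", f"B_s{k:04d}"
        contigs_a.append(SequenceRecord(id_a, seq_a))
        contigs_b.append(SequenceRecord(id_b, seq_b))
        realized = 100.0 * sum(a == b for a, b in zip(seq_a, seq_b)) / max(len(seq_a), len(seq_b))
        truth.orthologs[id_a] = (id_b, realized)
        truth.orthologs[id_b] = (id_a, realized)
    for k in range(config.n_genes_private_a):
        rng = gene_rng(index)
        index += 1
        contigs_a.append(SequenceRecord(f"A_p{k:04d}", _random_sequence(rng, int(rng.integers(lo, hi + 1)))))
    for k in range(config.n_genes_private_b):
        rng = gene_rng(index)
        index += 1
        contigs_b.append(SequenceRecord(f"B_p{k:04d}", _random_sequence(rng, int(rng.integers(lo, hi + 1)))))

    # genus proxy: the parasite's genes, diverged; family database: both
    # species' genes, diverged, labelled with two family tokens
    for rec in contigs_a:
        genus_refs.append(
            SequenceRecord(f"G_{rec.id}", _mutate(rec.sequence, config.genus_divergence, div_rng))
        )
        fid = f"FA_{rec.id}"
        family_db.append(
            SequenceRecord(fid, _mutate(rec.sequence, config.genus_divergence, div_rng))
        )
        subject_to_family[fid] = "FamilyA"
    for rec in contigs_b:
        fid = f"FB_{rec.id}"
        family_db.append(
            SequenceRecord(fid, _mutate(rec.sequence, config.genus_divergence, div_rng))
        )
        subject_to_family[fid] = "FamilyB"

    return SimulatedReferences(
        contigs_a=contigs_a,
        contigs_b=contigs_b,
        genus_refs=genus_refs,
        family_db=family_db,
        subject_to_family=subject_to_family,
        family_to_species={"FamilyA": "species_a", "FamilyB": "species_b"},
        truth=truth,
    )


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(seq)) < error_rate
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n)
        idx = np.searchsorted(BASES, arr[mask])
        arr[mask] = BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def simulate_reads(
    refs: SimulatedReferences,
    config: SimConfig,
    n_reads: int = 10_000,
) -> tuple[list[Read] | list[ReadPair], GroundTruth]:
    """Sample reads (or pairs) from the two transcriptomes.

    Species is drawn per read with parasite probability
    mix_ratio / (mix_ratio + 1); the source gene is uniform within the
    species, positions are uniform along the gene, strands balanced, and
    substitution errors i.i.d. at ``config.error_rate``. Every read
    carries its ground-truth species in ``truth_label``.
    """
    rl = config.read_length
    genes = {"species_a": refs.contigs_a, "species_b": refs.contigs_b}
    shortest = min(len(g) for pool in genes.values() for g in pool)
    if rl > shortest:
        raise ValueError(f"read_length {rl} exceeds shortest gene length {shortest}")
    rng = np.random.default_rng([config.seed, _STREAM_READS])
    p_parasite = config.mix_ratio / (config.mix_ratio + 1.0)
    truth = GroundTruth(orthologs=dict(refs.truth.orthologs))
    out: list = []
    mu, sd = config.fragment_length
    for i in range(n_reads):
        species = "species_a" if rng.random() < p_parasite else "species_b"
        pool = genes[species]
        gene = pool[int(rng.integers(0, len(pool)))]
        glen = len(gene)
        strand = "+" if rng.random() < 0.5 else "-"
        if not config.paired:
            pos = int(rng.integers(0, glen - rl + 1))
            frag = gene.sequence[pos : pos + rl]
            seq = frag if strand == "+" else revcomp(frag)
            rid = f"simread{i:06d}"
            read = Read(rid, _apply_errors(seq, rng, config.error_rate),
                        quality="I" * rl, truth_label=species)
            truth.reads[rid] = ReadOrigin(species, gene.id, pos, strand)
            out.append(read)
        else:
            flen = int(np.clip(round(rng.normal(mu, sd)), rl, glen))
            pos = int(rng.integers(0, glen - flen + 1))
            frag = gene.sequence[pos : pos + flen]
            if strand == "-":
                frag = revcomp(frag)
            r1_seq = _apply_errors(frag[:rl], rng, config.error_rate)
            r2_seq = _apply_errors(revcomp(frag[-rl:]), rng, config.error_rate)
            key = f"simpair{i:06d}"
            r1 = Read(f"{key}/1", r1_seq, quality="I" * rl, truth_label=species)
            r2 = Read(f"{key}/2", r2_seq, quality="I" * rl, truth_label=species)
            truth.reads[r1.id] = ReadOrigin(species, gene.id, pos, strand)
            truth.reads[r2.id] = ReadOrigin(species, gene.id, pos, strand)
            out.append(ReadPair(r1, r2))
    return out, truth
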