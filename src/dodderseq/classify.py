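"""Stepwise classification of mixed-tissue reads by source species.

The central idea: reads sequenced from an undissectable parasite-host
interface are assigned to one of the two species by a cascade of
similarity searches, each stage consuming only what the previous stage
left unclassified.

Stage 1 maps each read against both species' own contig sets and keeps
reads mapping uniquely to one side. Stage 2 rescues reads of the species
that has genus-level references (the parasite side in the motivating
system): any passing hit against the same-genus unigene sets assigns the
read there. Stage 3 consults a family-labelled database and assigns a
read only when its top hits (five by default, ties at the cut included)
unanimously belong to one family.

The alternative `reference_based_classify` implements the conventional
subtraction approach -- map against the host reference, call everything
unmapped "parasite" -- which misassigns parasite reads homologous to host
genes and serves as the baseline the cascade is measured against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .align import (
    AlignmentHit,
    MappingParams,
    PRESETS,
    SeedExtendAligner,
    min_passing_raw_score,
    passes_predicate,
)
from .seqio import Read, ReadPair, SequenceRecord

SPECIES_A = "species_a"
SPECIES_B = "species_b"
AMBIGUOUS = "ambiguous"
UNCLASSIFIED = "unclassified"
LABELS = (SPECIES_A, SPECIES_B, AMBIGUOUS, UNCLASSIFIED)


class HitSummary(NamedTuple):
    """The slice of an alignment hit that survives a table round-trip."""

    subject_id: str
    evalue: float
    identity: float


@dataclass
class ClassificationRecord:
    """Per-read outcome of the cascade (or of reference-based mapping)."""

    read_id: str
    label: str
    stage: int | str = "none"
    best_hit: Optional[AlignmentHit | HitSummary] = None
    votes: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label in (SPECIES_A, SPECIES_B) and self.stage == "none":
            raise ValueError(f"read {self.read_id!r}: a species label requires a stage")


ClassificationTable = list[ClassificationRecord]


@dataclass(frozen=True)
class TaxonomyMap:
    """subject id -> family token, and family token -> species label."""

    subject_to_family: dict[str, str]
    family_to_species: dict[str, str]

    def __post_init__(self) -> None:
        species = set(self.family_to_species.values())
        if len(species) != len(self.family_to_species):
            raise ValueError("the two species must map to distinct families")

    def family_of(self, subject_id: str) -> str:
        try:
            return self.subject_to_family[subject_id]
        except KeyError:
            raise KeyError(f"subject {subject_id!r} missing from taxonomy") from None


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and knobs for the three-stage cascade.

    Stage 3 hits are additionally gated at ``params_stage3`` (e-value
    <= 1e-5 by default) before voting. ``require_all_topk`` demands
    unanimity among the top-k hits (the default); when off, a strict
    majority of the votes suffices.
    """

    params_stage1: MappingParams = PRESETS["ci_lenient"]
    params_stage2: MappingParams = PRESETS["genus"]
    params_stage3: MappingParams = PRESETS["contaminant"]
    top_k: int = 5
    require_all_topk: bool = True
    genus_target_label: str = SPECIES_A

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _best(hits: Sequence[AlignmentHit]) -> Optional[AlignmentHit]:
    return hits[0] if hits else None


def stage1_unique(
    read: Read,
    hits_a: Sequence[AlignmentHit],
    hits_b: Sequence[AlignmentHit],
    params: MappingParams,
) -> ClassificationRecord:
    """Unique-mapping rule over the two species' own reference sets.

    Passing hits on one side only give that species; passing hits on both
    sides give ``ambiguous`` (such reads do not proceed to later stages);
    no passing hits leave the read unclassified for stage 2.
    """
    n = len(read)
    pass_a = [h for h in hits_a if passes_predicate(h, params, n)]
    pass_b = [h for h in hits_b if passes_predicate(h, params, n)]
    if pass_a and not pass_b:
        return ClassificationRecord(read.id, SPECIES_A, 1, _best(pass_a))
    if pass_b and not pass_a:
        return ClassificationRecord(read.id, SPECIES_B, 1, _best(pass_b))
    if pass_a and pass_b:
        return ClassificationRecord(read.id, AMBIGUOUS, 1, _best(pass_a + pass_b))
    return ClassificationRecord(read.id, UNCLASSIFIED, "none")


def stage2_genus(
    read: Read,
    genus_hits: Sequence[AlignmentHit],
    params_genus: MappingParams,
    target_label: str = SPECIES_A,
) -> ClassificationRecord:
    """Any passing hit against the same-genus unigene sets assigns the
    read to the species owning those references."""
    n = len(read)
    passing = [h for h in genus_hits if passes_predicate(h, params_genus, n)]
    if passing:
        return ClassificationRecord(read.id, target_label, 2, _best(passing))
    return ClassificationRecord(read.id, UNCLASSIFIED, "none")


def stage3_family_vote(
    read: Read,
    db_hits: Sequence[AlignmentHit],
    taxonomy: TaxonomyMap,
    top_k: int = 5,
    require_all_topk: bool = True,
) -> ClassificationRecord:
    """Taxonomy vote over the top-k database hits.

    ``db_hits`` must be sorted best-first (evalue asc, bitscore desc).
    The top min(top_k, n) hits are taken, including every hit tied with
    the k-th; with fewer than k hits, all available hits vote. Under
    unanimity (default) the read is assigned only if every voting hit's
    family maps to a species; otherwise a strict majority decides.
    """
    if not db_hits:
        return ClassificationRecord(read.id, UNCLASSIFIED, "none")
    cut = min(top_k, len(db_hits))
    chosen = list(db_hits[:cut])
    key = (db_hits[cut - 1].evalue, db_hits[cut - 1].bitscore)
    for h in db_hits[cut:]:
        if (h.evalue, h.bitscore) == key:
            chosen.append(h)
        else:
            break
    votes: dict[str, int] = {}
    for h in chosen:
        fam = taxonomy.family_of(h.subject_id)
        votes[fam] = votes.get(fam, 0) + 1
    if require_all_topk:
        winners = [fam for fam in votes if votes[fam] == len(chosen)]
    else:
        winners = [fam for fam, v in votes.items() if v * 2 > len(chosen)]
    if winners:
        label = taxonomy.family_to_species.get(winners[0])
        if label is not None:
            return ClassificationRecord(read.id, label, 3, _best(chosen), votes)
    return ClassificationRecord(read.id, UNCLASSIFIED, "none", None, votes)


def run_cascade(
    reads: Sequence[Read],
    refs_a: Sequence[SequenceRecord],
    refs_b: Sequence[SequenceRecord],
    genus_refs: Sequence[SequenceRecord],
    family_db: Sequence[SequenceRecord],
    taxonomy: Optional[TaxonomyMap],
    config: CascadeConfig = CascadeConfig(),
) -> ClassificationTable:
    """Run the full three-stage cascade; every read receives exactly one
    label and a read labelled at stage k is never re-examined later.

    An empty genus reference set skips stage 2; an empty family database
    (or missing taxonomy) skips stage 3.
    """
    seen: set[str] = set()
    for r in reads:
        if r.id in seen:
            raise ValueError(f"duplicate read id: {r.id!r}")
        seen.add(r.id)

    engine_a = SeedExtendAligner(refs_a)
    engine_b = SeedExtendAligner(refs_b)
    engine_genus = SeedExtendAligner(genus_refs) if genus_refs else None
    engine_db = SeedExtendAligner(family_db) if family_db and taxonomy else None

    table: ClassificationTable = []
    for read in reads:
        n = len(read)
        gate1a = min_passing_raw_score(config.params_stage1, n, engine_a.database_len)
        gate1b = min_passing_raw_score(config.params_stage1, n, engine_b.database_len)
        rec = stage1_unique(
            read,
            engine_a.align_read(read, min_raw_score=gate1a),
            engine_b.align_read(read, min_raw_score=gate1b),
            config.params_stage1,
        )
        if rec.label == UNCLASSIFIED and engine_genus is not None:
            gate2 = min_passing_raw_score(config.params_stage2, n, engine_genus.database_len)
            rec = stage2_genus(
                read,
                engine_genus.align_read(read, min_raw_score=gate2),
                config.params_stage2,
                config.genus_target_label,
            )
        if rec.label == UNCLASSIFIED and engine_db is not None:
            gate3 = min_passing_raw_score(config.params_stage3, n, engine_db.database_len)
            db_hits = [
                h
                for h in engine_db.align_read(read, min_raw_score=gate3)
                if passes_predicate(h, config.params_stage3, n)
            ]
            rec = stage3_family_vote(
                read, db_hits, taxonomy, config.top_k, config.require_all_topk
            )
        table.append(rec)
    return table


def stage_counts(table: ClassificationTable) -> dict[str, int]:
    """Per-label and per-stage tallies of a classification table."""
    counts: dict[str, int] = {label: 0 for label in LABELS}
    for rec in table:
        counts[rec.label] += 1
        key = f"stage_{rec.stage}"
        counts[key] = counts.get(key, 0) + 1
    counts["total"] = len(table)
    return counts


def reconcile_pairs(table: ClassificationTable, pairs: Sequence[ReadPair]) -> list[str]:
    """Read ids of pairs whose mates carry the same species label.

    Pairs with any ambiguous/unclassified mate, or with disagreeing
    labels, are rejected (both mates must be labelled and identical).
    """
    by_id = {rec.read_id: rec.label for rec in table}
    selected: list[str] = []
    for pair in pairs:
        l1 = by_id.get(pair.r1.id)
        l2 = by_id.get(pair.r2.id)
        if l1 is not None and l1 == l2 and l1 in (SPECIES_A, SPECIES_B):
            selected.extend([pair.r1.id, pair.r2.id])
    return selected


def reference_based_classify(
    reads: Sequence[Read],
    host_reference: Sequence[SequenceRecord],
    params: MappingParams = PRESETS["ci_lenient"],
    host_label: str = SPECIES_B,
    parasite_label: str = SPECIES_A,
) -> ClassificationTable:
    """Conventional subtraction: reads with a passing hit to the host
    reference are host; everything else is called parasite. A strict
    two-way partition with no unclassified outcome."""
    if not host_reference:
        raise ValueError("host reference must be non-empty")
    seen: set[str] = set()
    for r in reads:
        if r.id in seen:
            raise ValueError(f"duplicate read id: {r.id!r}")
        seen.add(r.id)
    engine = SeedExtendAligner(host_reference)
    table: ClassificationTable = []
    for read in reads:
        n = len(read)
        gate = min_passing_raw_score(params, n, engine.database_len)
        passing = [
            h
            for h in engine.align_read(read, min_raw_score=gate)
            if passes_predicate(h, params, n)
        ]
        if passing:
            table.append(ClassificationRecord(read.id, host_label, "reference", _best(passing)))
        else:
            table.append(ClassificationRecord(read.id, parasite_label, "reference"))
    return table
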