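"""Per-contig read counting and RPKM under two mapping regimes.

``separate``: each species' classified reads are counted only against
that species' own contig set. ``merged``: reads are counted against the
union of both sets, and any read whose best hit lands on the other
species' contigs is excluded entirely -- the guard against residual
misclassification. When no cross-species homology exists the two regimes
produce identical tables, which is the robustness property the merged
regime is there to certify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .align import AlignmentHit, MappingParams, PRESETS, passes_predicate

REGIMES = ("separate", "merged")


@dataclass
class CountsTable:
    """contig id -> assigned read count (plus contig lengths in bp)."""

    counts: dict[str, float]
    lengths: dict[str, int]
    excluded_cross: int = 0
    unmapped: int = 0

    @property
    def total_mapped(self) -> float:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ExpressionRecord:
    contig_id: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError("rpkm must be >= 0")


def _best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def count_per_contig(
    read_hits: Mapping[str, Sequence[AlignmentHit]],
    species_of_contig: Mapping[str, str],
    own_species: str,
    regime: str,
    contig_lengths: Mapping[str, int],
    params: Optional[MappingParams] = PRESETS["expression"],
    read_lengths: Optional[Mapping[str, int]] = None,
    fractional: bool = False,
) -> CountsTable:
    """Count one library's reads per contig.

    ``read_hits`` maps each read id to its hits against the merged contig
    set; hits are filtered by ``params`` (the expression preset by
    default; pass None for pre-filtered hits). Each counted read
    contributes 1 to its best hit's contig (ties broken by lexicographic
    contig id), or, with ``fractional``, 1/n spread over its n eligible
    contigs.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    counts: dict[str, float] = {
        cid: 0.0 for cid, sp in species_of_contig.items() if regime == "merged" or sp == own_species
    }
    excluded = 0
    unmapped = 0
    for rid in sorted(read_hits):
        hits = read_hits[rid]
        if params is not None:
            rlen = read_lengths.get(rid) if read_lengths else None
            hits = [h for h in hits if passes_predicate(h, params, rlen)]
        if regime == "separate":
            hits = [h for h in hits if species_of_contig[h.subject_id] == own_species]
            if not hits:
                unmapped += 1
                continue
        else:
            if not hits:
                unmapped += 1
                continue
            if species_of_contig[_best_hit(hits).subject_id] != own_species:
                excluded += 1
                continue
            hits = [h for h in hits if species_of_contig[h.subject_id] == own_species]
        if fractional:
            for h in hits:
                counts[h.subject_id] = counts.get(h.subject_id, 0.0) + 1.0 / len(hits)
        else:
            best = _best_hit(hits)
            counts[best.subject_id] = counts.get(best.subject_id, 0.0) + 1.0
    lengths = {cid: contig_lengths[cid] for cid in counts}
    return CountsTable(counts=counts, lengths=lengths, excluded_cross=excluded, unmapped=unmapped)


def rpkm(count: float, contig_length_bp: int, total_mapped: float) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if contig_length_bp < 1:
        raise ValueError("contig_length_bp must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return count * 1e9 / (contig_length_bp * total_mapped)


def rpkm_table(counts_table: CountsTable) -> list[ExpressionRecord]:
    """RPKM for every contig in a counts table (empty if nothing mapped)."""
    total = counts_table.total_mapped
    if total < 1:
        return [ExpressionRecord(cid, 0.0) for cid in sorted(counts_table.counts)]
    return [
        ExpressionRecord(cid, rpkm(counts_table.counts[cid], counts_table.lengths[cid], total))
        for cid in sorted(counts_table.counts)
    ]
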