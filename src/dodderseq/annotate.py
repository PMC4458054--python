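"""Minimal ORF annotation used to grade contig sets.

A contig is called full-length when an open reading frame with both a
start codon (ATG) and a stop codon (TAA/TAG/TGA) is found in any of the
six frames; an ORF-length filter (>= 200 bp) separates credible coding
contigs from assembly fragments. Standard genetic code only; no
alternative start codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .seqio import SequenceRecord, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfAnnotation:
    """One ORF call; coordinates are 1-based inclusive on the contig's
    forward strand (ascending even for minus frames)."""

    contig_id: str
    frame: int
    start: int
    end: int
    length_bp: int
    has_start: bool
    has_stop: bool

    def __post_init__(self) -> None:
        if self.length_bp % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.end - self.start + 1 != self.length_bp:
            raise ValueError("coordinates inconsistent with length")

    @property
    def full_length(self) -> bool:
        return self.has_start and self.has_stop


def _frame_candidates(contig_id: str, seq: str, frame: int) -> Iterable[OrfAnnotation]:
    """Candidate stretches in one frame: for each region between stops,
    the ATG..stop ORF when both exist, else the whole open stretch
    (including a trailing stop) with flags set from what is present."""
    length = len(seq)
    oriented = seq if frame > 0 else revcomp(seq)
    offset = abs(frame) - 1
    codons = [oriented[i : i + 3] for i in range(offset, length - 2, 3)]
    n = len(codons)
    seg_start = 0
    while seg_start < n:
        stop_idx = next((i for i in range(seg_start, n) if codons[i] in STOP_CODONS), None)
        has_stop = stop_idx is not None
        seg_end = stop_idx if has_stop else n  # open codons are [seg_start, seg_end)
        atg_idx = next(
            (j for j in range(seg_start, seg_end) if codons[j] == START_CODON), None
        )
        if has_stop and atg_idx is not None:
            first, last, has_start = atg_idx, stop_idx, True
        elif has_stop:
            first, last, has_start = seg_start, stop_idx, False
        else:
            first, last = seg_start, seg_end - 1
            has_start = codons[first] == START_CODON
        o_start = offset + first * 3      # 0-based on the oriented strand
        o_end = offset + (last + 1) * 3   # exclusive
        if frame > 0:
            start, end = o_start + 1, o_end
        else:
            start, end = length - o_end + 1, length - o_start
        yield OrfAnnotation(
            contig_id=contig_id,
            frame=frame,
            start=start,
            end=end,
            length_bp=o_end - o_start,
            has_start=has_start,
            has_stop=has_stop,
        )
        seg_start = stop_idx + 1 if has_stop else n


def longest_orf(contig: SequenceRecord, min_len_bp: int = 0) -> Optional[OrfAnnotation]:
    """Longest ORF over all six frames.

    Full-length ORFs (ATG..stop) are preferred; failing that, the longest
    open stretch bounded by sequence ends/stops is returned with its
    start/stop flags. Ties break to the lowest frame index (+1, +2, +3,
    -1, -2, -3), then the smallest start. Returns None when the longest
    candidate is shorter than ``min_len_bp`` or the contig is < 3 bp.
    """
    if len(contig.sequence) < 3:
        return None
    candidates: list[tuple[int, OrfAnnotation]] = []
    for rank, frame in enumerate(FRAMES):
        for cand in _frame_candidates(contig.id, contig.sequence, frame):
            candidates.append((rank, cand))
    if not candidates:
        return None
    full = [(r, c) for r, c in candidates if c.full_length]
    pool = full if full else candidates
    rank, best = min(pool, key=lambda rc: (-rc[1].length_bp, rc[0], rc[1].start))
    if best.length_bp < min_len_bp:
        return None
    return best


def annotate_contigs(
    contigs: Iterable[SequenceRecord], min_len_bp: int = 0
) -> list[OrfAnnotation]:
    """ORF annotation for every contig that has one of at least
    ``min_len_bp``; contigs without are omitted (kept subset of annotated)."""
    out = []
    for contig in contigs:
        ann = longest_orf(contig, min_len_bp)
        if ann is not None:
            out.append(ann)
    return out
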