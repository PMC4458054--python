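"""Read-level preprocessing filters applied before classification.

Three filters, run in pipeline order: (1) removal of reads similar to a
contaminant database (rRNA/tRNA, e-value <= 1e-5); (2) removal of read
pairs whose estimated fragment span is below the assembler insert length
(175 bp by default); (3) poly-A tail trimming with discard of pairs left
shorter than 75 bp. The span and poly-A filters apply to paired data; the
poly-A step belongs to the single-species contig-building protocol and is
off by default in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import PRESETS, SeedExtendAligner, min_passing_raw_score
from .seqio import Read, ReadPair, SequenceRecord, revcomp

CONTAMINANT_MAX_EVALUE = 1e-5
DEFAULT_MIN_SPAN = 175
DEFAULT_MIN_READ_LEN = 75
MIN_OVERLAP = 10          # shortest mate overlap considered real
MAX_OVERLAP_MISMATCHES = 2
MIN_POLYA_RUN = 10        # shortest terminal A-run worth trimming


@dataclass
class FilterReport:
    """Accounting for one filter pass; removals always reconcile with
    input_count - output_count."""

    input_count: int = 0
    removed_contaminant: int = 0
    removed_short_span: int = 0
    removed_short_read: int = 0
    trimmed_polya: int = 0
    output_count: int = 0

    def __post_init__(self) -> None:
        removed = self.removed_contaminant + self.removed_short_span + self.removed_short_read
        if self.output_count != self.input_count - removed:
            raise ValueError("FilterReport counts do not reconcile")

    def as_dict(self) -> dict[str, int]:
        return {
            "input_count": self.input_count,
            "removed_contaminant": self.removed_contaminant,
            "removed_short_span": self.removed_short_span,
            "removed_short_read": self.removed_short_read,
            "trimmed_polya": self.trimmed_polya,
            "output_count": self.output_count,
        }


def contaminant_filter(
    reads: Sequence[Read],
    contaminant_db: Sequence[SequenceRecord],
    max_evalue: float = CONTAMINANT_MAX_EVALUE,
) -> tuple[list[Read], FilterReport]:
    """Remove reads with at least one hit at e-value <= ``max_evalue``
    against the contaminant database; kept reads preserve input order."""
    if not contaminant_db:
        raise ValueError("contaminant database must be non-empty")
    engine = SeedExtendAligner(contaminant_db)
    kept: list[Read] = []
    removed = 0
    for read in reads:
        gate = min_passing_raw_score(
            PRESETS["contaminant"], max(len(read), 1), engine.database_len
        )
        hits = engine.align_read(read, min_raw_score=gate)
        if any(h.evalue <= max_evalue for h in hits):
            removed += 1
        else:
            kept.append(read)
    report = FilterReport(
        input_count=len(reads), removed_contaminant=removed, output_count=len(kept)
    )
    return kept, report


def mate_overlap(r1: Read, r2: Read) -> int:
    """Longest suffix-prefix exact match (>= 10 bp, <= 2 mismatches)
    between r1 and the reverse complement of r2; 0 if none.

    In a short fragment sequenced from both ends, the tail of read 1
    re-reads the head of rc(read 2); the overlap length recovers the
    fragment length as len(r1) + len(r2) - overlap.
    """
    s1 = r1.sequence
    s2 = revcomp(r2.sequence)
    for olap in range(min(len(s1), len(s2)), MIN_OVERLAP - 1, -1):
        tail = s1[len(s1) - olap :]
        head = s2[:olap]
        mismatches = sum(a != b for a, b in zip(tail, head))
        if mismatches <= MAX_OVERLAP_MISMATCHES:
            return olap
    return 0


def pair_span_filter(
    pairs: Sequence[ReadPair], min_span: int = DEFAULT_MIN_SPAN
) -> tuple[list[ReadPair], FilterReport]:
    """Remove pairs whose estimated fragment span is below ``min_span``.

    The span is len(r1) + len(r2) - overlap, with the overlap estimated
    by :func:`mate_overlap` (0 when the mates do not overlap).
    """
    kept: list[ReadPair] = []
    removed = 0
    for pair in pairs:
        span = len(pair.r1) + len(pair.r2) - mate_overlap(pair.r1, pair.r2)
        if span < min_span:
            removed += 1
        else:
            kept.append(pair)
    report = FilterReport(
        input_count=len(pairs), removed_short_span=removed, output_count=len(kept)
    )
    return kept, report


def _terminal_run(seq: str, base: str, from_end: bool) -> int:
    """Length of the maximal terminal run of ``base`` allowing at most one
    interior non-``base`` interruption; the run must start and end on
    ``base`` and reach :data:`MIN_POLYA_RUN` to count."""
    s = seq[::-1] if from_end else seq
    best = 0
    run = 0
    interruptions = 0
    for i, c in enumerate(s):
        if c == base:
            run = i + 1
            best = max(best, run)
        else:
            interruptions += 1
            if interruptions > 1:
                break
    return best if best >= MIN_POLYA_RUN else 0


def trim_polya(read: Read) -> Read:
    """Trim terminal poly-A runs (3' A-run or 5' T-run) of >= 10 bases,
    each tolerating one interruption, repeating until no run remains so
    that trimming is idempotent. Interior runs are untouched."""
    seq = read.sequence
    quality = read.quality
    while True:
        tail = _terminal_run(seq, "A", from_end=True)
        head = _terminal_run(seq, "T", from_end=False)
        if tail == 0 and head == 0:
            break
        start, end = head, len(seq) - tail
        if start >= end:  # read is essentially all tail
            start, end = 0, max(1, len(seq) - tail)
        seq = seq[start:end]
        quality = quality[start:end] if quality else None
    if seq == read.sequence:
        return read
    return Read(
        id=read.id,
        sequence=seq,
        quality=quality,
        mate=read.mate,
        truth_label=read.truth_label,
    )


def polya_trim_min_len(
    pairs: Sequence[ReadPair], min_read_len: int = DEFAULT_MIN_READ_LEN
) -> tuple[list[ReadPair], FilterReport]:
    """Trim poly-A tails from both mates; discard pairs where one or both
    reads fall below ``min_read_len`` after trimming."""
    kept: list[ReadPair] = []
    removed = 0
    trimmed = 0
    for pair in pairs:
        t1, t2 = trim_polya(pair.r1), trim_polya(pair.r2)
        if len(t1) != len(pair.r1) or len(t2) != len(pair.r2):
            trimmed += 1
        if len(t1) < min_read_len or len(t2) < min_read_len:
            removed += 1
        else:
            kept.append(ReadPair(t1, t2))
    report = FilterReport(
        input_count=len(pairs),
        removed_short_read=removed,
        trimmed_polya=trimmed,
        output_count=len(kept),
    )
    return kept, report
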