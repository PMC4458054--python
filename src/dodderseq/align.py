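"""Local alignment of reads against reference sets.

The classifier's decisions are all phrased as threshold predicates over
local-alignment statistics (match length, mismatches, gap openings,
e-value, percent identity), mirroring how tabular BLASTN output is
consumed. This module provides

* a seed-and-extend engine (`SeedExtendAligner`) that finds candidate
  subjects by exact 11-mer seeding and scores them with an optimal local
  (Smith-Waterman, affine-gap) alignment,
* the threshold presets used throughout the pipeline (`PRESETS`) and the
  predicate that applies them (`passes_predicate`),
* reading/writing of 12-column tabular alignments (BLAST outfmt-6
  compatible), so externally produced alignments can be substituted for
  the internal engine.

Scoring is fixed at match +1, mismatch -2, gap open -5, gap extend -2
(a gap of length L costs 5 + 2L). The bit score is 2 x raw score -- about
what megablast's Karlin-Altschul parameters give per matched base -- and
the e-value is the simplified E = m * n * 2^(-bitscore). The absolute
e-values are therefore an order-consistent surrogate, not BLAST-identical
values; the pipeline only uses them as hard gates (1e-20, 1e-5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import Read, SequenceRecord, revcomp

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = 5   # cost charged once per gap, on top of per-column extension
GAP_EXTEND = 2  # cost per gap column
BITS_PER_RAW_SCORE = 2.0
DEFAULT_SEED_LENGTH = 11


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a read and a reference sequence.

    Coordinates are 1-based inclusive. On the minus strand the subject
    coordinates descend (subject_start > subject_end), as in BLAST
    tabular output; query coordinates always ascend on the read as given.
    ``match_length`` counts aligned columns including gap columns;
    ``identity`` is percent matching columns over aligned columns.
    """

    query_id: str
    subject_id: str
    identity: float
    match_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity out of range: {self.identity}")
        if self.match_length < 1:
            raise ValueError("match_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def identities(self) -> int:
        """Number of matching columns, recovered from identity and length."""
        return round(self.identity * self.match_length / 100.0)

    @property
    def gap_columns(self) -> int:
        return self.match_length - self.identities - self.mismatches


@dataclass(frozen=True)
class MappingParams:
    """A named, immutable threshold set for accepting alignments.

    Unset thresholds are ignored. ``exact_length`` demands that the
    alignment covers the full read with no gap columns (match length equal
    to the read length).
    """

    name: str
    min_match_length: Optional[int] = None
    exact_length: bool = False
    max_mismatches: Optional[int] = None
    max_gaps: Optional[int] = None
    max_evalue: Optional[float] = None
    min_identity: Optional[float] = None

    def __post_init__(self) -> None:
        for fieldname in ("min_match_length", "max_mismatches", "max_gaps", "max_evalue", "min_identity"):
            v = getattr(self, fieldname)
            if v is not None and v < 0:
                raise ValueError(f"{fieldname} must be non-negative")


#: Threshold presets. `ci_lenient` and `expression` are the >=90 bp,
#: <=1 mismatch / 1 gap settings used for classification and counting;
#: `cg_stage1` is the >=67 bp variant used for shorter (74 bp) reads;
#: `genus` swaps the mismatch cap for identity >= 90%; `strict_exact`
#: demands a full-length perfect match; `contaminant` gates only on
#: e-value <= 1e-5 (rRNA/tRNA removal).
PRESETS: dict[str, MappingParams] = {
    "ci_lenient": MappingParams(
        "ci_lenient", min_match_length=90, max_evalue=1e-20, max_mismatches=1, max_gaps=1
    ),
    "genus": MappingParams(
        "genus", min_match_length=90, max_evalue=1e-20, min_identity=90.0
    ),
    "strict_exact": MappingParams(
        "strict_exact", exact_length=True, max_mismatches=0, max_gaps=0
    ),
    "cg_stage1": MappingParams(
        "cg_stage1", min_match_length=67, max_evalue=1e-20, max_mismatches=1, max_gaps=1
    ),
    "contaminant": MappingParams("contaminant", max_evalue=1e-5),
    "expression": MappingParams(
        "expression", min_match_length=90, max_mismatches=1, max_gaps=1
    ),
}


def bitscore_of(raw_score: float) -> float:
    return BITS_PER_RAW_SCORE * raw_score


def evalue_of(bitscore: float, query_len: int, database_len: int) -> float:
    """Simplified expectation value E = m * n * 2^(-bitscore).

    Monotone decreasing in the bit score and linear in the database
    length, which is all the pipeline's hard e-value gates require.
    """
    if query_len < 1 or database_len < 1:
        raise ValueError("query_len and database_len must be >= 1")
    if not math.isfinite(bitscore):
        if bitscore > 0:
            return 0.0
        raise ValueError("bitscore must be finite or +inf")
    return float(query_len) * float(database_len) * 2.0 ** (-bitscore)


def passes_predicate(
    hit: AlignmentHit, params: MappingParams, read_length: Optional[int] = None
) -> bool:
    """True iff every threshold configured in ``params`` is satisfied.

    ``read_length`` is required by exact-length presets (the alignment
    must cover the whole read); for other presets it is ignored.
    """
    if params.exact_length:
        if read_length is None:
            raise ValueError(f"preset {params.name!r} needs the read length")
        if hit.match_length != read_length or hit.gap_columns != 0:
            return False
    if params.min_match_length is not None and hit.match_length < params.min_match_length:
        return False
    if params.max_mismatches is not None and hit.mismatches > params.max_mismatches:
        return False
    if params.max_gaps is not None and hit.gap_opens > params.max_gaps:
        return False
    if params.max_evalue is not None and hit.evalue > params.max_evalue:
        return False
    if params.min_identity is not None and hit.identity < params.min_identity:
        return False
    return True


def _hit_sort_key(hit: AlignmentHit):
    return (hit.evalue, -hit.bitscore, hit.subject_id)


def _make_pairwise_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            # N is a mismatch to everything, including itself
            matrix[a, b] = float(MATCH_SCORE) if (a == b and a != "N") else float(MISMATCH_SCORE)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


class SeedExtendAligner:
    """Seed-and-extend local aligner over a fixed target set.

    Candidate subjects are those sharing at least one exact ``seed_len``-mer
    with the query (per strand); each candidate is then aligned with an
    optimal affine-gap local alignment and reported as one hit per
    (subject, strand). Queries shorter than the seed, or sharing no seed
    with any target, are reported unaligned.
    """

    #: extra subject bases on each side of the seeded diagonal band; gaps
    #: cost 5+2L here, so alignments drifting further than this off the
    #: seed diagonals cannot score competitively
    WINDOW_SLACK = 32

    def __init__(self, targets: Sequence[SequenceRecord], seed_len: int = DEFAULT_SEED_LENGTH):
        self.seed_len = seed_len
        self.targets = {t.id: t.sequence for t in targets}
        self.database_len = sum(len(s) for s in self.targets.values())
        self._aligner = _make_pairwise_aligner()
        index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.targets.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((tid, i))
        self._index = index

    def _candidates(self, seq: str) -> dict[str, tuple[int, int]]:
        """Candidate subjects sharing a seed, with the subject window
        spanned by their seed diagonals (plus slack) for extension."""
        qlen = len(seq)
        found: dict[str, tuple[int, int]] = {}
        index = self._index
        k = self.seed_len
        for i in range(qlen - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            for tid, j in index.get(kmer, ()):
                diag = j - i
                lo, hi = found.get(tid, (diag, diag))
                found[tid] = (min(lo, diag), max(hi, diag))
        slack = self.WINDOW_SLACK
        return {
            tid: (max(0, lo - slack), min(len(self.targets[tid]), hi + qlen + slack))
            for tid, (lo, hi) in found.items()
        }

    def align_read(self, read: Read, min_raw_score: Optional[float] = None) -> list[AlignmentHit]:
        """All hits of a read, sorted by (evalue asc, bitscore desc, subject id).

        ``min_raw_score`` prunes candidates whose optimal local score falls
        below the bound (used by callers that will gate on a predicate
        anyway); by default every positive-scoring candidate is reported.
        """
        query = read.sequence
        if len(query) < self.seed_len or not self.targets:
            return []
        floor = 1.0 if min_raw_score is None else max(1.0, min_raw_score)
        hits: list[AlignmentHit] = []
        for strand in "+-":
            oriented = query if strand == "+" else revcomp(query)
            windows = self._candidates(oriented)
            for sid in sorted(windows):
                w_lo, w_hi = windows[sid]
                subject = self.targets[sid][w_lo:w_hi]
                score = self._aligner.score(oriented, subject)
                if score < floor:
                    continue
                alignment = self._aligner.align(oriented, subject)[0]
                hits.append(self._to_hit(alignment, read.id, sid, strand, len(query), w_lo))
        hits.sort(key=_hit_sort_key)
        return hits

    def _to_hit(
        self,
        alignment,
        query_id: str,
        subject_id: str,
        strand: str,
        query_len: int,
        window_offset: int = 0,
    ) -> AlignmentHit:
        counts = alignment.counts()
        identities = counts.identities
        mismatches = counts.mismatches
        gap_cols = counts.internal_gaps
        gap_opens = counts.open_internal_insertions + counts.open_internal_deletions
        match_length = identities + mismatches + gap_cols
        coords = alignment.coordinates
        q0, q1 = int(coords[0, 0]), int(coords[0, -1])
        s0, s1 = int(coords[1, 0]) + window_offset, int(coords[1, -1]) + window_offset
        if strand == "+":
            qs, qe = q0 + 1, q1
            ss, se = s0 + 1, s1
        else:
            # map back onto the forward read; subject coordinates descend
            qs, qe = query_len - q1 + 1, query_len - q0
            ss, se = s1, s0 + 1
        bitscore = bitscore_of(alignment.score)
        return AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            identity=100.0 * identities / match_length,
            match_length=match_length,
            mismatches=mismatches,
            gap_opens=gap_opens,
            query_start=qs,
            query_end=qe,
            subject_start=ss,
            subject_end=se,
            strand=strand,
            evalue=evalue_of(bitscore, query_len, self.database_len),
            bitscore=bitscore,
        )


def align_read(
    query: Read,
    targets: Sequence[SequenceRecord],
    seed_len: int = DEFAULT_SEED_LENGTH,
    min_raw_score: Optional[float] = None,
) -> list[AlignmentHit]:
    """One-shot convenience wrapper around :class:`SeedExtendAligner`."""
    return SeedExtendAligner(targets, seed_len=seed_len).align_read(query, min_raw_score)


def min_passing_raw_score(
    params: MappingParams, read_length: int, database_len: int
) -> float:
    """A conservative lower bound on the raw score of any hit that could
    pass ``params`` for a read of the given length.

    Used only to prune alignment work; a hit scoring below the bound can
    never satisfy the preset. The e-value bound is exact under this
    module's scoring; the length/mismatch/identity bounds are conservative.
    """
    bounds = [0.0]
    if params.max_evalue is not None and params.max_evalue > 0:
        # E <= max_e  <=>  bitscore >= log2(m*n/max_e)
        bits = math.log2(read_length * max(database_len, 1) / params.max_evalue)
        bounds.append(bits / BITS_PER_RAW_SCORE)
    length = read_length if params.exact_length else params.min_match_length
    if length is not None:
        if params.max_mismatches is not None:
            m = params.max_mismatches
            g = params.max_gaps or 0
            bounds.append(
                (length - m) * MATCH_SCORE + m * MISMATCH_SCORE - g * (GAP_OPEN + 2 * GAP_EXTEND)
            )
        elif params.min_identity is not None:
            frac = params.min_identity / 100.0
            bounds.append(
                length * (frac * MATCH_SCORE + (1.0 - frac) * MISMATCH_SCORE) - GAP_OPEN
            )
    return max(bounds)


# ---------------------------------------------------------------------------
# 12-column tabular alignments (BLAST outfmt-6 compatible)

_TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def write_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular format (no header, as BLAST)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            ss, se = (h.subject_start, h.subject_end)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.2f}\t{h.match_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.query_start}\t{h.query_end}\t"
                f"{ss}\t{se}\t{h.evalue:.3g}\t{h.bitscore:.6g}\n"
            )


def read_tabular(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column tabular alignments; minus strand is inferred from
    descending subject coordinates (sstart > send)."""
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 columns, got {len(parts)}")
            (qid, sid, pident, length, mism, gapo, qs, qe, ss, se, ev, bits) = parts
            ss_i, se_i = int(ss), int(se)
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    identity=float(pident),
                    match_length=int(length),
                    mismatches=int(mism),
                    gap_opens=int(gapo),
                    query_start=int(qs),
                    query_end=int(qe),
                    subject_start=ss_i,
                    subject_end=se_i,
                    strand="+" if ss_i <= se_i else "-",
                    evalue=float(ev),
                    bitscore=float(bits),
                )
            )
    return hits
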