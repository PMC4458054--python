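"""Sequence and table I/O.

Everything the pipeline reads from or writes to disk goes through this
module: FASTA reference sets, FASTQ read sets (Sanger/Phred+33), the
classification TSV, per-contig count tables, and flat metrics reports.
All tables are UTF-8 TSV with a single header line; floats are written
with six significant digits.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (a contig, unigene or database entry).

    Sequences are stored upper-case over the alphabet {A, C, G, T, N}.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Read:
    """A sequencing read; quality and ground-truth species label are optional.

    ``truth_label`` is populated only by the simulator and is never consulted
    by the classifier itself.
    """

    id: str
    sequence: str
    quality: Optional[str] = None
    mate: Optional[int] = None
    truth_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid read id: {self.id!r}")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for read {self.id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.mate not in (None, 1, 2):
            raise ValueError(f"read {self.id!r}: mate must be 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


_MATE_SUFFIX = re.compile(r"^(?P<key>.*?)(?:/(?P<mate>[12]))$")


def pair_key(read: Read) -> tuple[str, Optional[int]]:
    """Pair key and mate number for a read.

    Strips one trailing ``/1`` or ``/2`` from the id; failing that, a mate
    number given in ``read.mate`` is used with the id itself as the key.
    """
    m = _MATE_SUFFIX.match(read.id)
    if m:
        return m.group("key"), int(m.group("mate"))
    return read.id, read.mate


@dataclass
class ReadPair:
    """Two mates of one fragment; ids must share a pair key."""

    r1: Read
    r2: Read

    def __post_init__(self) -> None:
        k1, m1 = pair_key(self.r1)
        k2, m2 = pair_key(self.r2)
        if k1 != k2:
            raise ValueError(f"mates {self.r1.id!r} / {self.r2.id!r} do not share a pair key")
        if {m1, m2} != {1, 2}:
            raise ValueError(f"pair {k1!r}: mate numbers must be 1 and 2, got {m1}/{m2}")
        if m1 == 2:  # normalise order
            self.r1, self.r2 = self.r2, self.r1

    @property
    def key(self) -> str:
        return pair_key(self.r1)[0]


def pair_reads(reads: Sequence[Read]) -> tuple[list[ReadPair], list[Read]]:
    """Group reads into pairs by pair key; reads that fail to pair are
    returned separately (and are processed as single-end downstream)."""
    by_key: dict[str, list[Read]] = {}
    order: list[str] = []
    for r in reads:
        k, _ = pair_key(r)
        if k not in by_key:
            order.append(k)
        by_key.setdefault(k, []).append(r)
    pairs: list[ReadPair] = []
    singles: list[Read] = []
    for k in order:
        group = by_key[k]
        if len(group) == 2:
            mates = {pair_key(r)[1] for r in group}
            if mates == {1, 2}:
                pairs.append(ReadPair(group[0], group[1]))
                continue
        singles.extend(group)
    return pairs, singles


def _check_unique_ids(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord] | list[Read]:
    """Read a FASTA file into SequenceRecords or a FASTQ file into Reads.

    Order is preserved; multi-line FASTA records are concatenated; case is
    normalised to upper. A duplicate id is a hard error naming the id; a
    FASTQ sequence/quality length mismatch is a hard error with the record
    number.
    """
    path = Path(path)
    if format == "fasta":
        records = [
            SequenceRecord(rec.id, str(rec.seq), rec.description[len(rec.id):].strip())
            for rec in SeqIO.parse(path, "fasta")
        ]
        _check_unique_ids((r.id for r in records), "sequence")
        return records
    if format == "fastq":
        reads: list[Read] = []
        try:
            for n, rec in enumerate(SeqIO.parse(path, "fastq"), start=1):
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                reads.append(Read(rec.id, str(rec.seq), quality=qual))
        except ValueError as exc:
            raise ValueError(f"FASTQ record {len(reads) + 1} in {path}: {exc}") from exc
        _check_unique_ids((r.id for r in reads), "read")
        return reads
    raise ValueError(f"unknown format: {format!r}")


def read_reads(path: str | Path, format: str = "fastq") -> list[Read]:
    """Read sequencing reads from FASTQ (with qualities) or FASTA (without)."""
    if format == "fastq":
        return read_sequences(path, "fastq")  # type: ignore[return-value]
    records = read_sequences(path, "fasta")
    return [Read(r.id, r.sequence) for r in records]  # type: ignore[union-attr]


def write_fasta(records: Iterable[SequenceRecord | Read], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# tables


def _fmt(x: object) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


_CLASSIFICATION_COLUMNS = ["read_id", "label", "stage", "best_hit_id", "evalue", "identity"]


def write_classification(table, path: str | Path) -> None:
    """Write a classification table as TSV.

    Columns: read_id, label, stage, best_hit_id, evalue, identity. Records
    without a supporting hit get ``NA`` in the hit columns.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CLASSIFICATION_COLUMNS) + "\n")
        for rec in table:
            hit = rec.best_hit
            row = [
                rec.read_id,
                rec.label,
                str(rec.stage),
                hit.subject_id if hit is not None else "NA",
                _fmt(hit.evalue) if hit is not None else "NA",
                _fmt(hit.identity) if hit is not None else "NA",
            ]
            fh.write("\t".join(row) + "\n")


def read_classification(path: str | Path):
    """Read a classification TSV back into ClassificationRecords.

    The supporting hit is restored as a summary (subject id, e-value,
    identity only). A malformed row raises with its line number.
    """
    from .classify import ClassificationRecord, HitSummary

    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CLASSIFICATION_COLUMNS:
            raise ValueError(f"{path}: unexpected classification header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_CLASSIFICATION_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_CLASSIFICATION_COLUMNS)} "
                    f"columns, got {len(parts)}"
                )
            read_id, label, stage, hit_id, evalue, identity = parts
            hit = None
            if hit_id != "NA":
                hit = HitSummary(hit_id, float(evalue), float(identity))
            records.append(
                ClassificationRecord(
                    read_id=read_id,
                    label=label,
                    stage=int(stage) if stage.isdigit() else stage,
                    best_hit=hit,
                )
            )
    _check_unique_ids((r.read_id for r in records), "read")
    return records


def classification_rows(table) -> list[tuple]:
    """The TSV-visible fields of a classification table, for comparisons."""
    rows = []
    for rec in table:
        hit = rec.best_hit
        rows.append(
            (
                rec.read_id,
                rec.label,
                str(rec.stage),
                hit.subject_id if hit is not None else "NA",
                _fmt(hit.evalue) if hit is not None else "NA",
                _fmt(hit.identity) if hit is not None else "NA",
            )
        )
    return rows


def write_counts(counts_table, path: str | Path) -> None:
    """Write a per-contig count table (contig_id, length_bp, count)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("contig_id\tlength_bp\tcount\n")
        for cid in sorted(counts_table.counts):
            fh.write(f"{cid}\t{counts_table.lengths[cid]}\t{_fmt(counts_table.counts[cid])}\n")


def read_counts(path: str | Path):
    from .quant import CountsTable

    counts: dict[str, float] = {}
    lengths: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["contig_id", "length_bp", "count"]:
            raise ValueError(f"{path}: unexpected counts header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            cid, length, count = parts
            counts[cid] = float(count) if "." in count or "e" in count else int(count)
            lengths[cid] = int(length)
    return CountsTable(counts=counts, lengths=lengths)


def write_expression(records, path: str | Path) -> None:
    """Write per-contig RPKM values (contig_id, rpkm)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("contig_id\trpkm\n")
        for rec in records:
            fh.write(f"{rec.contig_id}\t{_fmt(rec.rpkm)}\n")


def write_metrics(metrics: dict, path: str | Path) -> None:
    """Flat key -> number report, serialised as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metrics(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def read_taxonomy_tsv(path: str | Path) -> dict[str, str]:
    """Read a subject_id -> family TSV (two columns, with header)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["subject_id", "family"]:
            raise ValueError(f"{path}: unexpected taxonomy header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            mapping[parts[0]] = parts[1]
    return mapping


def write_taxonomy_tsv(subject_to_family: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject_id\tfamily\n")
        for sid in sorted(subject_to_family):
            fh.write(f"{sid}\t{subject_to_family[sid]}\n")


def write_truth_tsv(truth: dict[str, str], path: str | Path) -> None:
    """Write read_id -> true species label."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tspecies\n")
        for rid in sorted(truth):
            fh.write(f"{rid}\t{truth[rid]}\n")


def read_truth_tsv(path: str | Path) -> dict[str, str]:
    truth: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "species"]:
            raise ValueError(f"{path}: unexpected truth header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            truth[parts[0]] = parts[1]
    return truth
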