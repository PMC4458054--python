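"""Small object factories shared across test modules."""

from dodderseq.align import AlignmentHit


def make_hit(**overrides) -> AlignmentHit:
    """A plausible full-length perfect hit, overridable per field."""
    base = dict(
        query_id="r1",
        subject_id="c1",
        identity=100.0,
        match_length=100,
        mismatches=0,
        gap_opens=0,
        query_start=1,
        query_end=100,
        subject_start=1,
        subject_end=100,
        strand="+",
        evalue=1e-50,
        bitscore=200.0,
    )
    base.update(overrides)
    return AlignmentHit(**base)
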