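import math

import numpy as np
import pytest

from dodderseq.align import (
    PRESETS,
    SeedExtendAligner,
    align_read,
    evalue_of,
    passes_predicate,
    read_tabular,
    write_tabular,
)
from dodderseq.seqio import Read, SequenceRecord, revcomp

from tests._factories import make_hit
from tests._oracles import score_from_hit, sw_score, sw_score_reference


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestEngine:
    def test_exact_substring_is_perfect_forward_hit(self):
        rng = np.random.default_rng(0)
        target = SequenceRecord("t1", _random_dna(rng, 500))
        read = Read("q", target.sequence[137:237])
        (hit,) = align_read(read, [target])
        assert (hit.identity, hit.match_length, hit.mismatches, hit.gap_opens) == (100.0, 100, 0, 0)
        assert hit.strand == "+"
        assert (hit.subject_start, hit.subject_end) == (138, 237)

    def test_reverse_complement_query_hits_minus_strand(self):
        rng = np.random.default_rng(0)
        target = SequenceRecord("t1", _random_dna(rng, 500))
        read = Read("q", revcomp(target.sequence[137:237]))
        (hit,) = align_read(read, [target])
        assert hit.strand == "-"
        assert (hit.subject_start, hit.subject_end) == (237, 138)
        assert hit.identity == 100.0

    def test_no_shared_seed_gives_empty_list(self):
        target = SequenceRecord("t1", "A" * 400)  # only A-homopolymer seeds
        read = Read("q", "C" * 60)  # neither C nor its complement G seeds match
        assert align_read(read, [target]) == []

    def test_empty_target_set_is_not_an_error(self):
        assert align_read(Read("q", "ACGT" * 30), []) == []

    def test_query_shorter_than_seed_reported_unaligned(self):
        target = SequenceRecord("t1", "ACGTACGTACGTACGT")
        assert align_read(Read("q", "ACGTACGT"), [target]) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_invariance(self, seed):
        """align_read(rc(q)) is the strand-flipped hit set of align_read(q)."""
        rng = np.random.default_rng(seed)
        targets = [SequenceRecord(f"t{i}", _random_dna(rng, 400)) for i in range(3)]
        base = targets[seed % 3].sequence[50:150]
        noisy = list(base)
        for p in rng.choice(100, size=3, replace=False):
            noisy[p] = "ACGT"[(("ACGT".index(noisy[p])) + 1) % 4]
        fwd = align_read(Read("q", "".join(noisy)), targets)
        rev = align_read(Read("q", revcomp("".join(noisy))), targets)

        def key(h):
            return (
                h.subject_id,
                min(h.subject_start, h.subject_end),
                max(h.subject_start, h.subject_end),
                h.identity,
                h.match_length,
                h.mismatches,
                h.gap_opens,
            )

        assert sorted(map(key, fwd)) == sorted(map(key, rev))
        assert {h.strand for h in fwd} == {"-" if s == "+" else "+" for s in {h.strand for h in rev}}

    @pytest.mark.parametrize("seed", range(25))
    def test_hit_statistics_match_dp_oracle(self, seed):
        """Reported (identity, length, mismatches, gaps) reproduce the score
        of an optimal local alignment on the reported subject interval."""
        rng = np.random.default_rng(100 + seed)
        target = SequenceRecord("t", _random_dna(rng, 600))
        start = int(rng.integers(0, 450))
        frag = list(target.sequence[start : start + 120])
        for p in rng.choice(len(frag), size=int(rng.integers(0, 8)), replace=False):
            frag[p] = "ACGT"[("ACGT".index(frag[p]) + int(rng.integers(1, 4))) % 4]
        if rng.random() < 0.4:  # one small indel to exercise gapped paths
            p = int(rng.integers(10, 100))
            if rng.random() < 0.5:
                del frag[p]
            else:
                frag.insert(p, "ACGT"[int(rng.integers(0, 4))])
        read = Read("q", "".join(frag))
        for hit in align_read(read, [target]):
            oriented = read.sequence if hit.strand == "+" else revcomp(read.sequence)
            lo = min(hit.subject_start, hit.subject_end) - 1
            hi = max(hit.subject_start, hit.subject_end)
            interval = target.sequence[lo:hi]
            assert score_from_hit(hit) == pytest.approx(sw_score(oriented, interval))


class TestOracleGrounding:
    @pytest.mark.parametrize("seed", range(15))
    def test_scan_gotoh_agrees_with_reference_gotoh(self, seed):
        rng = np.random.default_rng(seed)
        q = _random_dna(rng, int(rng.integers(5, 30)))
        t = _random_dna(rng, int(rng.integers(5, 60)))
        assert sw_score(q, t) == pytest.approx(sw_score_reference(q, t))

    def test_n_is_mismatch_to_everything(self):
        assert sw_score("NNNN", "NNNN") == 0.0
        assert sw_score("ACGTN", "ACGTN") == 4.0  # the N column is dropped


class TestEvalue:
    def test_direct_formula_evaluation(self):
        assert evalue_of(20, 100, 1000) == pytest.approx(100 * 1000 * 2 ** -20)
        assert evalue_of(20, 100, 1000) == pytest.approx(0.09537, rel=1e-4)

    def test_doubling_database_doubles_e(self):
        assert evalue_of(30, 100, 2000) == pytest.approx(2 * evalue_of(30, 100, 1000))

    def test_infinite_bitscore_gives_zero(self):
        assert evalue_of(math.inf, 100, 1000) == 0.0

    def test_monotone_decreasing_in_bitscore(self):
        assert evalue_of(50, 100, 1000) < evalue_of(40, 100, 1000)


class TestPredicates:
    def test_ci_lenient_accepts_papers_thresholds(self):
        hit = make_hit(match_length=95, identity=100 * 94 / 95, mismatches=1, evalue=1e-30)
        assert passes_predicate(hit, PRESETS["ci_lenient"])

    def test_ci_lenient_rejects_short_match(self):
        hit = make_hit(match_length=89, identity=100.0, mismatches=0, evalue=1e-40)
        assert not passes_predicate(hit, PRESETS["ci_lenient"])

    def test_strict_exact_needs_full_length_and_no_mismatch(self):
        perfect = make_hit(match_length=100, mismatches=0)
        assert passes_predicate(perfect, PRESETS["strict_exact"], read_length=100)
        near = make_hit(match_length=100, identity=99.0, mismatches=1)
        assert not passes_predicate(near, PRESETS["strict_exact"], read_length=100)

    def test_genus_preset_gates_on_identity(self):
        good = make_hit(match_length=95, identity=93.0, mismatches=6, evalue=1e-25)
        bad = make_hit(match_length=95, identity=85.0, mismatches=14, evalue=1e-25)
        assert passes_predicate(good, PRESETS["genus"])
        assert not passes_predicate(bad, PRESETS["genus"])

    def test_strict_pass_set_is_subset_of_lenient(self, small_sim):
        """Stringency monotonicity on real engine output."""
        _, refs, reads, _ = small_sim
        engine = SeedExtendAligner(refs.contigs_a)
        checked = 0
        for read in reads[:60]:
            for hit in engine.align_read(read):
                if passes_predicate(hit, PRESETS["strict_exact"], len(read)):
                    assert passes_predicate(hit, PRESETS["ci_lenient"], len(read))
                    checked += 1
        assert checked > 0


class TestTabular:
    def test_round_trip_including_minus_strand(self, tmp_path):
        hits = [
            make_hit(),
            make_hit(query_id="r2", subject_id="c2", subject_start=300, subject_end=201,
                     strand="-", identity=97.0, mismatches=3, evalue=1e-33, bitscore=150.0),
        ]
        path = tmp_path / "hits.tsv"
        write_tabular(hits, path)
        back = read_tabular(path)
        assert [h.strand for h in back] == ["+", "-"]
        assert [(h.query_id, h.subject_id, h.match_length, h.mismatches) for h in back] == [
            (h.query_id, h.subject_id, h.match_length, h.mismatches) for h in hits
        ]

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="line 1"):
            read_tabular(path)
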