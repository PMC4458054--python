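import numpy as np
import pytest

from dodderseq.align import PRESETS
from dodderseq.classify import (
    CascadeConfig,
    TaxonomyMap,
    reconcile_pairs,
    reference_based_classify,
    run_cascade,
    stage1_unique,
    stage2_genus,
    stage3_family_vote,
    stage_counts,
)
from dodderseq.seqio import Read, ReadPair, SequenceRecord

from tests._factories import make_hit

A, B, AMB, UNC = "species_a", "species_b", "ambiguous", "unclassified"


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def taxonomy():
    subjects = {f"conv{i}": "Convolvulaceae" for i in range(6)}
    subjects.update({f"bals{i}": "Balsaminaceae" for i in range(6)})
    return TaxonomyMap(subjects, {"Convolvulaceae": A, "Balsaminaceae": B})


class TestStage1:
    read = Read("r1", "A" * 100)
    params = PRESETS["ci_lenient"]

    def test_unique_hits_on_a_side(self):
        hits_a = [make_hit(), make_hit(subject_id="c2")]
        rec = stage1_unique(self.read, hits_a, [], self.params)
        assert (rec.label, rec.stage) == (A, 1)

    def test_hits_on_both_sides_are_ambiguous(self):
        rec = stage1_unique(self.read, [make_hit()], [make_hit(subject_id="d1")], self.params)
        assert (rec.label, rec.stage) == (AMB, 1)

    def test_no_passing_hits_leaves_unclassified(self):
        weak = make_hit(match_length=50, query_end=50, subject_end=50)
        rec = stage1_unique(self.read, [weak], [], self.params)
        assert (rec.label, rec.stage) == (UNC, "none")


class TestStage2:
    read = Read("r1", "A" * 100)

    def test_passing_genus_hit_assigns_target_species(self):
        hit = make_hit(match_length=95, identity=93.0, mismatches=6, evalue=1e-25,
                       query_end=95, subject_end=95)
        rec = stage2_genus(self.read, [hit], PRESETS["genus"])
        assert (rec.label, rec.stage) == (A, 2)

    def test_low_identity_hit_does_not_assign(self):
        hit = make_hit(match_length=95, identity=85.0, mismatches=14, evalue=1e-25,
                       query_end=95, subject_end=95)
        rec = stage2_genus(self.read, [hit], PRESETS["genus"])
        assert rec.label == UNC


class TestStage3:
    read = Read("r1", "A" * 100)

    def _hits(self, subjects, evalues=None):
        evalues = evalues or [10 ** -(50 - i) for i in range(len(subjects))]
        return [
            make_hit(subject_id=s, evalue=e, bitscore=-np.log10(e))
            for s, e in zip(subjects, evalues)
        ]

    def test_unanimous_top_five(self, taxonomy):
        rec = stage3_family_vote(self.read, self._hits([f"conv{i}" for i in range(5)]), taxonomy)
        assert (rec.label, rec.stage) == (A, 3)
        assert rec.votes == {"Convolvulaceae": 5}

    def test_split_vote_is_unclassified(self, taxonomy):
        subjects = ["conv0", "conv1", "conv2", "conv3", "bals0"]
        rec = stage3_family_vote(self.read, self._hits(subjects), taxonomy)
        assert rec.label == UNC

    def test_fewer_than_five_hits_vote_unanimously(self, taxonomy):
        rec = stage3_family_vote(self.read, self._hits(["bals0", "bals1", "bals2"]), taxonomy)
        assert (rec.label, rec.stage) == (B, 3)

    def test_tie_at_rank_five_joins_the_vote(self, taxonomy):
        subjects = ["conv0", "conv1", "conv2", "conv3", "conv4", "bals0"]
        evalues = [1e-50, 1e-49, 1e-48, 1e-47, 1e-46, 1e-46]  # rank-5 tie
        rec = stage3_family_vote(self.read, self._hits(subjects, evalues), taxonomy)
        assert rec.label == UNC  # the tied Balsaminaceae hit breaks unanimity
        assert sum(rec.votes.values()) == 6

    def test_subject_missing_from_taxonomy_is_hard_error(self, taxonomy):
        with pytest.raises(KeyError, match="mystery"):
            stage3_family_vote(self.read, self._hits(["mystery"]), taxonomy)

    def test_no_hits_is_unclassified(self, taxonomy):
        assert stage3_family_vote(self.read, [], taxonomy).label == UNC


class TestReconcilePairs:
    def _table(self, l1, l2):
        recs = []
        for rid, label in (("p/1", l1), ("p/2", l2)):
            stage = 1 if label in (A, B) else "none"
            recs.append(
                type("R", (), {"read_id": rid, "label": label, "stage": stage})()
            )
        return recs

    pair = ReadPair(Read("p/1", "ACGT" * 25), Read("p/2", "TTTT" * 25))

    @pytest.mark.parametrize(
        "l1,l2,expected",
        [
            (A, A, 2),
            (B, B, 2),
            (A, B, 0),
            (A, UNC, 0),
            (UNC, UNC, 0),
            (AMB, AMB, 0),
        ],
    )
    def test_selection_requires_identical_species_labels(self, l1, l2, expected):
        selected = reconcile_pairs(self._table(l1, l2), [self.pair])
        assert len(selected) == expected


class TestReferenceBased:
    def test_host_read_maps_host_and_alien_read_defaults_to_parasite(self):
        rng = np.random.default_rng(21)
        host = [SequenceRecord("h1", _dna(rng, 600))]
        reads = [Read("host_read", host[0].sequence[100:200]), Read("alien", _dna(rng, 100))]
        table = reference_based_classify(reads, host)
        assert [r.label for r in table] == [B, A]
        assert all(r.stage == "reference" for r in table)

    def test_parasite_read_homologous_to_host_gene_is_misclassified(self):
        """The failure mode motivating the stepwise approach: a parasite
        gene 95% identical to a host gene (divergence clustered outside
        the read) sends its reads to the host bin."""
        rng = np.random.default_rng(22)
        parasite_gene = _dna(rng, 400)
        host_gene = list(parasite_gene)
        for p in rng.choice(np.arange(300, 400), size=20, replace=False):  # 5% divergence
            host_gene[p] = "ACGT"[("ACGT".index(host_gene[p]) + 1) % 4]
        host = [SequenceRecord("h1", "".join(host_gene))]
        parasite_read = Read("p_read", parasite_gene[50:150])  # from the conserved part
        (rec,) = reference_based_classify([parasite_read], host)
        assert rec.label == B  # wrong: the read is from the parasite

    def test_empty_host_reference_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            reference_based_classify([Read("r", "ACGT" * 30)], [])


class TestCascade:
    def test_reads_drawn_from_refs_a_all_labelled_at_stage_one(self, small_sim):
        _, refs, _, _ = small_sim
        reads = [
            Read(f"self{i}", c.sequence[:100]) for i, c in enumerate(refs.contigs_a)
        ]
        table = run_cascade(reads, refs.contigs_a, refs.contigs_b, [], [], None)
        for rec in table:
            assert rec.stage == 1
            assert rec.label in (A, AMB)  # orthologs at >=75% identity never flip the label
        assert sum(rec.label == A for rec in table) >= len(table) - 1

    def test_label_partition_sums_to_input(self, small_sim):
        _, refs, reads, _ = small_sim
        taxonomy = TaxonomyMap(refs.subject_to_family, refs.family_to_species)
        table = run_cascade(
            reads, refs.contigs_a, refs.contigs_b, refs.genus_refs, refs.family_db, taxonomy
        )
        counts = stage_counts(table)
        assert counts[A] + counts[B] + counts[AMB] + counts[UNC] == len(reads)
        assert len({rec.read_id for rec in table}) == len(reads)

    def test_duplicate_read_ids_rejected(self, small_sim):
        _, refs, _, _ = small_sim
        reads = [Read("dup", "ACGT" * 30), Read("dup", "TTAC" * 30)]
        with pytest.raises(ValueError, match="dup"):
            run_cascade(reads, refs.contigs_a, refs.contigs_b, [], [], None)

    def test_byte_identical_reruns(self, small_sim, tmp_path):
        from dodderseq.seqio import write_classification

        _, refs, reads, _ = small_sim
        taxonomy = TaxonomyMap(refs.subject_to_family, refs.family_to_species)
        paths = []
        for i in range(2):
            table = run_cascade(
                reads[:80], refs.contigs_a, refs.contigs_b, refs.genus_refs,
                refs.family_db, taxonomy,
            )
            p = tmp_path / f"run{i}.tsv"
            write_classification(table, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_stage1_stringency_monotonicity(self, small_sim):
        """Raising stage-1 stringency never increases stage-1 labels."""
        _, refs, reads, _ = small_sim
        sample = reads[:80]
        lenient = run_cascade(sample, refs.contigs_a, refs.contigs_b, [], [], None)
        strict = run_cascade(
            sample, refs.contigs_a, refs.contigs_b, [], [], None,
            CascadeConfig(params_stage1=PRESETS["strict_exact"]),
        )
        n_lenient = sum(rec.stage == 1 and rec.label in (A, B) for rec in lenient)
        n_strict = sum(rec.stage == 1 and rec.label in (A, B) for rec in strict)
        assert n_strict <= n_lenient

    def test_genus_rescue_when_stage1_refs_lack_the_gene(self):
        """A read from a gene absent from both contig sets but present in
        the genus-proxy references is labelled at stage 2."""
        rng = np.random.default_rng(31)
        refs_a = [SequenceRecord("a1", _dna(rng, 500))]
        refs_b = [SequenceRecord("b1", _dna(rng, 500))]
        missing_gene = _dna(rng, 500)
        genus = [SequenceRecord("g1", missing_gene)]
        read = Read("r", missing_gene[100:200])
        (rec,) = run_cascade([read], refs_a, refs_b, genus, [], None)
        assert (rec.label, rec.stage) == (A, 2)

    def test_stepwise_beats_reference_based_with_shared_homologs(self):
        """On the same mixture, reference-based subtraction misclassifies
        at least as many reads as the cascade."""
        from dodderseq.simulate import SimConfig, simulate_reads, simulate_transcriptomes

        config = SimConfig(
            seed=5, n_genes_shared=8, n_genes_private_a=2, n_genes_private_b=2,
            gene_length=(300, 800), ortholog_identity=(75.0, 90.0), error_rate=0.02,
        )
        refs = simulate_transcriptomes(config)
        reads, truth = simulate_reads(refs, config, n_reads=400)
        labels = truth.labels()
        taxonomy = TaxonomyMap(refs.subject_to_family, refs.family_to_species)
        stepwise = run_cascade(
            reads, refs.contigs_a, refs.contigs_b, refs.genus_refs, refs.family_db, taxonomy
        )
        refbased = reference_based_classify(reads, refs.contigs_b)

        def miscalls(table):
            return sum(
                rec.label in (A, B) and rec.label != labels[rec.read_id] for rec in table
            )

        assert miscalls(refbased) >= miscalls(stepwise)
        assert miscalls(refbased) > 0  # error-bearing host reads leak to the parasite bin
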