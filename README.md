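# dodderseq

Species classification of RNA-Seq reads from mixed parasite–host tissue.

When a parasitic plant such as a dodder (*Cuscuta*) feeds on a host, the
haustorial interface is a block of intimately intermingled cells from two
species that cannot be dissected apart. Bulk RNA-Seq of that tissue yields a
mixture of reads from both transcriptomes — and for non-model species there is
no reference genome to sort them with. `dodderseq` implements a
reference-free, stepwise strategy for assigning each read to its source
species, together with the competitive-mapping framework used to quantify how
well the assignment works.

## The method

Reads are classified by a cascade of local-similarity searches, each stage
consuming only reads the previous stage left unclassified:

1. **Own contigs.** Map each read against both species' de-novo contig sets
   (assembled from "not-in-contact" single-species tissue). Reads that map
   uniquely to one side (match length ≥ 90 bp, *e* ≤ 1e-20, ≤ 1 mismatch,
   ≤ 1 gap) are assigned to that species; reads passing on both sides are
   set aside as ambiguous.
2. **Same-genus unigenes.** Remaining reads are mapped against unigene sets
   of congeneric species (available for the parasite side); any passing hit
   (≥ 90 bp, *e* ≤ 1e-20, identity ≥ 90 %) assigns the read to the parasite.
3. **Family-level vote.** Remaining reads are searched against a
   family-labelled sequence database; a read is assigned only when its top
   five hits (ties at the cut included) unanimously belong to one family.

Classification quality is measured by **competitive mapping**: single-species
read libraries are mapped against the union of both contig sets and each read
is assigned to the better-scoring side (*e*-value, then identity, then bit
score). With the library of origin as ground truth this yields read-level
counts TP/FN/FP/TN, per-library misclassification rates
(100 × cross-mapped / library total), and a single-operating-point ROC AUC

```
TPR = TP/(TP+FN),   FPR = FP/(FP+TN),   AUC = (1 + TPR − FPR)/2
```

The package also provides the conventional baseline (reference-based
subtraction against a host transcriptome), per-contig read counting and RPKM
under *separate* and *merged* mapping regimes (the merged regime drops reads
whose best hit lands on the other species), read prefilters (rRNA/tRNA
contaminant removal at *e* ≤ 1e-5, pair-span < 175 bp removal, poly-A
trimming), minimal six-frame ORF annotation, and a synthetic-data generator
that produces ground-truth-labelled mixtures with tunable ortholog identity,
sequencing error, and mixing ratio (default 16.8 : 1 parasite : host,
matching the RNA-yield asymmetry of the motivating tissue).

Alignments come from an internal seed-and-extend engine (11-mer exact
seeding, optimal affine-gap local extension; match +1 / mismatch −2 / gap
open −5 / gap extend −2) whose statistics are contract-checked against a full
dynamic-programming oracle. Externally produced 12-column tabular (BLAST
outfmt-6 style) alignments can be substituted anywhere.

## Worked example

Simulate a 2,000-read mixture (orthologs at 75–90 % identity, 0.5 %
sequencing error), classify it with the cascade, and score it against the
simulator's truth labels:

```bash
dodderseq simulate --seed 42 --n-reads 2000 --ortholog-identity 75 90 --out-dir demo/sim
dodderseq classify --reads demo/sim/reads.fastq \
    --ref-a demo/sim/contigs_a.fasta --ref-b demo/sim/contigs_b.fasta \
    --genus-refs demo/sim/genus_refs.fasta --family-db demo/sim/family_db.fasta \
    --taxonomy demo/sim/taxonomy.tsv --out-dir demo/cls
dodderseq assess --truth demo/sim/truth.tsv \
    --predicted demo/cls/classification.tsv --out demo/metrics.json
```

`demo/cls/stage_counts.json` records where each read was resolved:

```json
{"species_a": 1880, "species_b": 113, "ambiguous": 0, "unclassified": 7,
 "stage_1": 1844, "stage_2": 139, "stage_3": 10, "stage_none": 7, "total": 2000}
```

1,844 reads are settled by the species' own contigs, 139 parasite reads with
too many errors for stage 1 are rescued by the genus references, and 10 more
by the family vote; only 7 of 2,000 stay unclassified. `demo/metrics.json`
scores the result against truth:

```json
{"tp": 1880, "fn": 0, "fp": 0, "tn": 113,
 "misclassification_rate_a": 0.0, "misclassification_rate_b": 0.0,
 "tpr": 1.0, "fpr": 0.0, "auc": 1.0}
```

No read was assigned to the wrong species (rates are percent of each
library's reads cross-mapped; at realistic full scale these land in the
0.2–0.4 % range), and the single-point ROC AUC is 1.0.

## Layout

```
src/dodderseq/
  seqio.py      FASTA/FASTQ and table I/O, read pairing
  align.py      seed-and-extend aligner, threshold presets, tabular I/O
  prefilter.py  contaminant / pair-span / poly-A filters
  classify.py   the three-stage cascade + reference-based baseline
  assess.py     competitive choice, confusion matrix, rates, ROC AUC
  quant.py      per-contig counting (separate/merged) and RPKM
  annotate.py   six-frame longest-ORF annotation
  simulate.py   synthetic mixtures with ground truth
  pipeline.py   workflow runner
  cli.py        `dodderseq` command-line interface
```
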