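# Methods

## Problem and model

Bulk RNA-Seq of a parasite–host interface produces reads from two
transcriptomes at once. With no genome for either species, reads are
classified by similarity against a hierarchy of references of decreasing
specificity: the two species' own de-novo contig sets, same-genus unigene
sets, and a family-labelled database. The cascade is strictly sequential —
a read labelled (or set aside as ambiguous) at one stage is never
re-examined — so the output is a partition of the input into
`species_a`, `species_b`, `ambiguous`, and `unclassified`.

All decisions are threshold predicates over local-alignment statistics.
The presets are:

| preset        | match length | mismatches | gaps | e-value  | identity |
|---------------|--------------|------------|------|----------|----------|
| `ci_lenient`  | ≥ 90 bp      | ≤ 1        | ≤ 1  | ≤ 1e-20  | —        |
| `cg_stage1`   | ≥ 67 bp      | ≤ 1        | ≤ 1  | ≤ 1e-20  | —        |
| `genus`       | ≥ 90 bp      | —          | —    | ≤ 1e-20  | ≥ 90 %   |
| `strict_exact`| = read length| 0          | 0    | —        | —        |
| `contaminant` | —            | —          | —    | ≤ 1e-5   | —        |
| `expression`  | ≥ 90 bp      | ≤ 1        | ≤ 1  | —        | —        |

`ci_lenient` suits ~100 bp reads; `cg_stage1` is the variant for shorter
(~74 bp) single-end libraries. "Gaps" counts gap *openings* (tabular
alignment convention), not gapped columns.

## Alignment engine and scoring

The engine seeds with exact 11-mers (per strand), then computes an optimal
affine-gap local alignment (Smith–Waterman via Biopython's PairwiseAligner)
of the read against the subject window spanned by its seed diagonals plus
32 bp of slack. Restricting extension to the seeded window is part of the
seed-and-extend semantics; the reported statistics are guaranteed optimal
for the reported subject interval (checked against an independent
numpy Gotoh oracle in the test suite), and queries sharing no seed with a
subject are reported unaligned. Ties in hit ordering break on
(e-value asc, bit score desc, subject id asc) for determinism. `N` bases
are retained and score as a mismatch against everything, including `N`.

Scoring is match +1, mismatch −2, gap open −5, gap extend −2 (a gap of
length L costs 5 + 2L). The bit score is **2 × raw score** and the
expectation value is the simplified E = m·n·2^(−bitscore) with m the read
length and n the total database length. Two bits per raw-score unit is
approximately what megablast's Karlin–Altschul parameters yield per matched
base; with this scale a perfect 100 bp match against a 100 kb database has
E ≈ 1e-53 and the 1e-20 gate behaves as a hard but reachable bar, while a
bare seed-length match stays far above 1e-5. A smaller scale (e.g. half a
bit per unit) would make E ≈ 1e-8 for the same perfect hit and render the
1e-20 gate unsatisfiable for short reads, so the scale is a load-bearing
choice, exposed as `align.BITS_PER_RAW_SCORE`. Absolute e-values remain an
order-consistent surrogate rather than BLAST-identical numbers; the
pipeline only ever uses them as gates.

## Decisions where the procedure was underdetermined

* **Both-sided stage-1 hits** are labelled `ambiguous` and do not proceed
  to stage 2: later stages exist for reads that could not be mapped, not
  for reads that mapped too well.
* **"Uniquely mapped"** means across species sets (≥ 1 passing hit in one
  set and 0 in the other); multi-mapping within one species is allowed.
* **Stage-3 gate.** The family-database search needs some reporting
  threshold; hits are gated at e ≤ 1e-5 (the same similarity cutoff used
  for contaminant filtering and annotation) before voting. Configurable
  via `CascadeConfig.params_stage3`.
* **Stage-3 vote with < 5 hits** requires unanimity of all available hits
  (≥ 1); ties at rank 5 join the vote. A non-default plurality mode
  (`require_all_topk=False`) is provided but not used by the pipeline.
* **Pair reconciliation** keeps a pair only when both mates carry the same
  species label; (label, unclassified) pairs are rejected.
* **Competitive-choice ordering** is e-value first, then identity, then
  bit score: every preset gates on the e-value, so it is the primary score;
  exact ties are ambiguous and excluded from the confusion matrix (but
  tallied).
* **Pair span** is interpreted as estimated fragment length:
  len(r1) + len(r2) − overlap, with the overlap the longest suffix–prefix
  match (≥ 10 bp, ≤ 2 mismatches) between read 1 and rc(read 2). The
  175 bp threshold equals the assembler insert length the protocol uses.
* **Poly-A trimming** removes terminal A-runs (or leading T-runs) of
  ≥ 10 bases tolerating one interruption, iterated to a fixed point so the
  filter is idempotent; pairs left with a mate < 75 bp are discarded.
* **Counting** assigns each read once, to its best hit (ties to the
  lexicographically smallest contig id); fractional splitting over all
  eligible contigs is available as an option. In the merged regime a read
  whose best hit is on the other species is excluded entirely.
* **AUC** is reported to three decimals, round-half-even. The single-point
  formula (1 + TPR − FPR)/2 is the reference implementation; the
  threshold-sweep variant over continuous margins reduces to it exactly
  for hard assignments and is cross-checked against scikit-learn in tests.
* **ORF calls** use the standard genetic code only, prefer full-length
  (ATG…stop) stretches over longer open ones, and break ties to the lowest
  frame index then smallest start.

## The synthetic-data generator

The generator emulates the statistical structure the classifier faces, not
any particular organism:

* two transcriptomes with `n_genes_shared` = 30 ortholog pairs plus 10
  private genes per species, gene lengths uniform in 300–3000 bp;
* per-pair ortholog identity drawn uniformly from 75–95 % (divergence
  applied as exact-count random substitutions, so realized identity is
  exact; an optional indel rate exercises gapped alignment);
* a genus-proxy reference (the parasite's genes diverged by 5 %) and a
  family database (both species' genes diverged by 5 %, labelled with two
  family tokens);
* 100 bp reads with 0.5 % i.i.d. substitution errors, uniform positions,
  balanced strands, parasite : host mixing ratio 16.8 (the measured
  RNA-yield asymmetry of the motivating tissue); optional paired-end mode
  with fragment lengths ~ Normal(300, 50).

Each output object consumes its own random stream derived from the master
seed, so changing one knob (e.g. adding genes) does not perturb the others.
What the generator does **not** model: realistic expression-level
distributions (genes are sampled uniformly), quality-score-correlated
errors, splice variants, assembly artifacts, or chimeric contigs. Passing
recovery tests on these mixtures therefore demonstrates the logic of the
cascade under controlled homology and error, not performance on real
libraries.

## Problem sizes used by the test suite

Recovery checks run on a fixed-seed default simulation of 10,000 single-end
reads (ortholog identity capped at 90 %), on which the cascade must label
≥ 95 % of reads, misclassify < 1 %, and yield a truth-based AUC > 0.99.
The aligner is validated against the DP oracle on 1,000 random
read/target instances (reads ≤ 200 bp, targets ≤ 2 kb, with planted
mutated/indel-bearing copies and unrelated controls). Structural
invariants (partition sums, stringency monotonicity, regime convergence,
byte-level reproducibility) run on lighter 300-read mixtures. These sizes
were chosen as the smallest at which the stochastic assertions are stable
across neighbouring seeds.

## Known limitations

* E-values are surrogate-scaled; thresholds transfer as gates, not as
  absolute probabilities, and results can only be contract-reproduced
  (same decisions), not bit-reproduced, against external search tools.
* The engine reports one best local alignment per (subject, strand); a
  second, weaker HSP on the same subject is not reported.
* De-novo assembly, adapter/quality trimming, protein-level annotation and
  differential-expression testing are out of scope; the package consumes
  contigs as FASTA and emits count tables consumable by DE tools.
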