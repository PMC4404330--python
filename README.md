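# hemotyper

Blood-group phenotype calling and haplotype phasing from unphased genotypes,
driven by curated haplotype tables.

Blood groups (ABO, Rh, Dombrock, Junior, …) are fully genetically determined
traits: each system's phenotypes correspond to known allele combinations
(haplotypes) at a handful of exonic loci of one or two genes.  Variant
callers, however, report *unphased* genotypes — at a heterozygous site it is
unknown which of the two chromatids carries which allele — and with M
heterozygous sites in a gene there are 2^(M−1) possible diplotypes.
`hemotyper` solves phasing and phenotype assignment jointly:

1. **Knowledge base.** For each gene, a haplotype table H lists named
   phenotype rows over a fixed, ordered set of genomic loci; cells hold the
   expected plus-strand allele, with anchored indels written as longer or
   shorter allele strings (e.g. `GG` against reference `G`).
2. **Projection.** The sample's variants are intersected with the table's
   loci; absent loci are filled in with the reference-assembly allele.
3. **Enumeration.** All 2^(M−1) swap-distinct assignments c of the
   heterozygous alleles to chromatids A and B are generated.
4. **Scoring.** Each chromatid vector is labelled by its 1-nearest-neighbour
   row in H under Hamming distance d(·,·), where every locus compares as an
   atomic symbol (an indel mismatch costs 1, like a substitution).  The
   configuration score is d(A, H) + d(B, H).
5. **Decision.** The minimum-score configuration is the maximum-parsimony
   diplotype; its two nearest rows give the two phenotype calls.  All tied
   optima and all nearest-row ties are reported, and the prediction is
   flagged *ambiguous* whenever they disagree on the unordered phenotype
   pair — a tie is surfaced, never silently broken.

Intended users: bioinformaticians typing blood-group (or other
table-driven) phenotypes from WGS/array call sets, and method developers who
need a transparent, rule-table-based baseline for genotype-to-phenotype
inference with an explicit haplotype phase.

The package is organised around a scikit-learn-style estimator,
`DiplotypeNearestNeighbor` (`fit` on haplotype rows + labels, `predict` on
genotypes), with module-level functions (`predict`, `nearest_row`,
`enumerate_configurations`, …) as thin wrappers, plus a `hemotyper` CLI with
`predict` / `simulate` / `evaluate` subcommands.

## Worked example

The bundled demonstration table covers four ABO haplotypes over three hg19
loci of the ABO gene (minus-strand gene; alleles are plus-strand genomic):

```
#system=ABO
#gene=ABO
#assembly=hg19
#ref=G,C,G
#reference_row=O02
Phenotype	Chr9:136132908	Chr9:136131650	Chr9:136131414
A101	GG	C	G
A102	GG	T	G
O02	G	C	G
B101	GG	C	A
```

A sample homozygous for the `GG` insertion and heterozygous at the other two
loci (`sample.tsv`, tabular dialect: chromosome, position, alleles):

```
9	136132908	GG/GG
9	136131650	C/T
9	136131414	G/A
```

```sh
$ hemotyper predict --table abo.tsv --genotype sample.tsv --out out
wrote 1 predictions to out/report.tsv
$ cat out/report.tsv
sample	system	gene	phenotype_a	distance_a	phenotype_b	distance_b	total_score	n_best_configurations	ambiguous	tied_labels
sample	ABO	ABO	B101	0	A102	0	0	1	0	B101|A102
```

The unique optimal configuration concentrates the two heterozygous alternate
alleles on one chromatid, yielding an exact A102/B101 diplotype at total
distance 0 — an AB individual (dominance interpretation is left to the
user; the report carries raw allele calls).  The same result from Python:

```python
>>> import hemotyper as ht
>>> pred = ht.predict(ht.parse_genotype_tabular("sample.tsv"), ht.load_demo_table())
>>> pred.phenotype_pair, pred.total_score, pred.ambiguous
(('A102', 'B101'), 0, False)
```

A full synthetic benchmark — simulate 200 diplotypes from the table with 5%
per-locus call noise, predict, score against the planted truth:

```sh
$ hemotyper simulate --table abo.tsv --n 200 --seed 42 --noise 0.05 --out sim
$ hemotyper predict --table abo.tsv --genotype sim/genotypes --out pred
$ hemotyper evaluate --truth sim/truth.tsv --predictions pred/report.tsv --out eval.json
overall accuracy: 0.8950 (179/200)
ambiguous calls:  21 (0.1050)
  A101: 68/83
  A102: 93/102
  B101: 72/78
  O02: 81/88
```

Per-phenotype lines read "recovered/planted"; ambiguous calls (equal-score
alternatives disagreeing on the phenotype pair) always count as errors.

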