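# Methods

## Model

A gene's blood-group phenotype is assumed to be determined by the alleles at
a small, fixed set of exonic loci, and each chromatid's allele vector is
assumed to match — up to few deviations — one of the known haplotypes in a
curated table H (strong intra-gene linkage disequilibrium; no intra-gene
recombination).  Under these assumptions the unphased genotype of a sample
constrains the diplotype to the set C of 2^(M−1) swap-distinct chromatid
assignments of its M heterozygous alleles, and exactly one element of C is
the true diplotype.

Each candidate configuration c = (A, B) is scored

    score(c) = min_r d(A, r) + min_r d(B, r),   r ∈ rows(H)

with d the per-locus Hamming distance: allele strings compare as whole
categorical symbols, so a substitution and an anchored-indel mismatch each
cost 1 (times the locus weight; weights default to 1 everywhere).  The
minimum-score configuration is selected — a maximum-parsimony decision:
prefer the phasing whose chromatids require the fewest deviations from
known haplotypes.  Each chromatid is then labelled by its nearest row
(1-NN; K is fixed at 1 — distance-weighted K > 1 voting would be a
straightforward extension but the baseline method only ever consults the
closest row).

The summed-distance combination rule is a deliberate design choice: it is
the rule consistent with ranking whole configurations by distance, and the
test suite's independent brute-force oracle uses the same rule implemented
separately, so any divergence would surface there.

### Ties and ambiguity

Two distinct tie sources exist and both are surfaced rather than resolved:

- **across configurations** — several elements of C achieve the optimal
  score (`best_configurations` holds all of them, ranked canonically);
- **within a chromatid** — several rows of H sit at the same minimal
  distance (`tied_rows`, reported in table order with the first row as the
  deterministic primary label).

The prediction's `phenotype_pairs` is the set of unordered label pairs over
all optima expanded across both tie sources; `ambiguous` is true exactly
when that set has more than one element.  Evaluation counts ambiguous
predictions as errors — an equal-score call (e.g. a positive and a negative
haplotype at the same distance) is a miss, not a coin flip.

## Data model and formats

- **Haplotype table** (TSV): `#system=`, `#gene=`, `#assembly=` (default
  hg19), `#ref=` (comma-separated per-locus reference alleles),
  `#reference_row=`, optional `#weights=`; header
  `Phenotype⇥Chr<c>:<pos>…`; one row per haplotype.  Either `#ref=` or
  `#reference_row=` is required: reference fill-in (absent loci are
  homozygous reference) is part of the model, so a table without reference
  alleles is rejected at parse.  All coordinates are 1-based plus-strand
  positions of the stated assembly, also for minus-strand genes (matches
  variant-caller output and avoids per-gene reverse-complement logic);
  insertions/deletions are anchored allele strings at a single position.
  `chr9` and `9` are equivalent chromosome spellings.
- **Genotype**, tabular dialect: `chrom⇥pos⇥X/Y[⇥zygosity]`, missing marker
  `-` or `.`; zygosity is derived from the allele pair and, if the optional
  column is present, must agree.  Duplicate coordinates are rejected.
- **Genotype, VCF subset** (via pysam): CHROM/POS/REF/ALT + GT only.
  `0/0` and absent sites → reference by fill-in; `./.` → missing record;
  `1/2` → heterozygous ALT1/ALT2; haploid calls are treated as homozygous
  (dominance and X-inactivation are out of scope); symbolic ALTs are
  skipped with a warning.
- **Multi-gene systems** (Rh = RHD + RHCE): one table per gene, grouped by
  a manifest (`system⇥path` lines).  Predictions are reported per gene,
  side by side, with no cross-gene combination: interpreting the joint
  serological trait is left to the user.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `missing_policy` | `exclude-locus` | missing call at a table locus: drop the locus from distance computation for **all** rows (least biased); `as-reference` substitutes the reference allele; `fail` rejects the sample, for pipelines that exclude incomplete data outright |
| `max_het` | 20 | cap on M; 2^(M−1) ≈ 5×10⁵ configurations at the cap, with an explicit error above it (the efficiency of exhaustive enumeration rests on M staying small for exonic panels) |
| `weights` | all 1 | per-locus scoring weights; uniform weighting is the baseline (a known limitation for single high-penetrance variants, e.g. an O-determining indel outvoted by many A-supporting variants); non-uniform weights can be supplied via `#weights=` or the estimator parameter |
| K (nearest rows) | 1 (fixed) | only the closest row labels a chromatid |

The engine itself is free of randomness; all orderings (enumeration masks,
tie lists, rankings, report rows) are canonical, so outputs are
byte-reproducible.

## Numerical and implementation notes

- Alleles are integer-coded per locus; observed alleles never seen in the
  table column (nor as its reference) get a sentinel code that mismatches
  every row, which is exact for nearest-neighbour purposes.
- Configuration × row distance matrices are computed in numpy with the
  enumeration chunked (8192 configurations per block) to bound memory at
  large M; with unit (or integral) weights scores are reported as exact
  integers, with float weights a 1e-9 slack defines score ties.
- The first heterozygous locus is always assigned canonically (first
  observed allele → chromatid A), which removes the chromatid-swap symmetry
  and makes the enumeration exactly 2^(M−1).
- The full ranking of configurations is materialised on demand
  (`keep_ranking` / `predict_detailed(..., ranking=...)`); batch
  evaluation skips it.
- Degenerate inputs: an empty genotype yields the reference diplotype at
  distance 0 (when the table contains its reference row); a single-row
  table makes every call that row's label; variants at non-table positions
  never influence anything.

## Synthetic data generator

`simulate` plants ground truth under the engine's own generative
assumption: two table rows drawn with replacement (uniform by default, or
`row_weights`), unioned into an unphased genotype, with reference
homozygotes emitted as *no record* so files look like real caller output.
Three corruption mechanisms emulate real call sets, all at the
variant-call level (read-level error simulation is out of scope):

- `noise_rate` — per locus, probability that one uniformly chosen
  chromatid's allele is replaced by an allele outside the table column
  (falling back to any different base when the column exhausts A/C/G/T);
  defaults to 0, the clean whole-genome-like regime;
- `missing_rate` — per locus, probability the record becomes a no-call
  (`-/-`); defaults to 0;
- `panel_loci` — restricts emitted records to a locus subset, emulating a
  sparse genotyping array, the regime in which haplotype discrimination
  can become information-theoretically impossible.

Samples are reproducible from `(seed, index)` independently of cohort size.
What passing synthetic tests do **not** show about real data: tables here
are small and randomly generated, real curated tables have correlated rows
and shared backbones; real call sets have locus-dependent error and
missingness, strand/coordinate convention slips, and left-shifted indel
encodings (accepted at parse but not normalised); and crossover hybrids
within a gene violate the no-recombination assumption by construction.

Evaluation scores a sample as correct only when the unordered phenotype
pair matches exactly and the prediction is unambiguous, and reports
per-phenotype recall in recovered/planted form.

## Problem sizes used in the checks

The acceptance script and system tests use: the enumeration law verified
for M = 0…10 against an exhaustive labeling-plus-swap-deduplication oracle;
exact recovery over random 20-row × 10-locus tables with unique pair unions
(1,000 tables in the test suite, 200 in the script) across every unordered
row pair; 300–500 random instances against an independently implemented
brute-force minimizer; accuracy curves on 1,000–2,000-sample cohorts per
noise/panel point; and byte-comparison of two full pipeline runs.

## Known limitations

- Uniform weights let many low-impact variants outvote one fully penetrant
  variant; per-locus weights exist but no weighting scheme is shipped.
- No dominance/serological collapsing (A + O → A is the user's call), no
  cross-gene reasoning for multi-gene systems, no detection of intra-gene
  crossover hybrids, no statistical phasing from population references, no
  coordinate lift-over, and no indel left-normalisation.
- With sparse panels the engine still returns the parsimony optimum, but
  ties become frequent; population-frequency tie-breaking would be the
  natural extension and is not implemented.
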