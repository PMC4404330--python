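"""Synthetic diplotypes with planted ground truth, plus accuracy scoring.

The generative model mirrors the engine's own assumption: a sample's gene is
the union of two haplotype-table rows drawn with replacement (strong linkage
disequilibrium within the gene, no recombination).  Optional corruption
emulates real call sets at the variant-call level: per-locus categorical
noise (an allele flipped to one outside the table), per-locus no-calls, and
a sparse genotyping panel restricted to a fixed locus subset — the regime of
consumer SNP arrays, where discriminating haplotypes can become impossible.

Reference-homozygous loci are emitted as *no record*, matching the
reference fill-in convention of real variant-caller output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np

from .genotype_io import MISSING, Genotype, GenotypeRecord
from .knowledge_base import (
    HaplotypeRow,
    HaplotypeTable,
    Locus,
    normalize_chromosome,
)
from .phasing import Prediction

__all__ = [
    "SimulationSpec",
    "TruthRecord",
    "EvaluationReport",
    "sample_diplotype",
    "planted_genotype",
    "has_unique_pair_unions",
    "simulate_cohort",
    "evaluate_cohort",
    "random_table",
    "resolve_panel",
    "write_genotype_tabular",
    "write_cohort",
    "read_truth",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort.

    noise_rate and missing_rate are per-locus probabilities (defaults 0: the
    clean whole-genome-like regime); ``panel_loci`` restricts emitted records
    to a subset of table loci, emulating a sparse array.  Everything is
    reproducible from ``seed`` alone.
    """

    table: HaplotypeTable
    n_samples: int
    row_weights: Sequence[float] | None = None
    noise_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    panel_loci: Sequence[int] | None = None  # column indices into table.loci

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        for name in ("noise_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.row_weights is not None:
            w = np.asarray(self.row_weights, dtype=float)
            if w.shape != (len(self.table.rows),):
                raise ValueError("row_weights must have one entry per table row")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("row_weights must be non-negative and sum to 1")
        if self.panel_loci is not None:
            idx = sorted(set(int(i) for i in self.panel_loci))
            if idx and (idx[0] < 0 or idx[-1] >= self.table.n_loci):
                raise ValueError("panel_loci indices out of range")
            self.panel_loci = tuple(idx)


@dataclass
class TruthRecord:
    """One simulated sample: the planted row pair and the emitted genotype."""

    sample_id: str
    row_a: int
    row_b: int
    label_a: str
    label_b: str
    genotype: Genotype

    @property
    def label_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.label_a, self.label_b)))


def resolve_panel(table: HaplotypeTable, panel) -> tuple[int, ...] | None:
    """Normalize a panel specification to column indices.

    Accepts integer indices, :class:`Locus` objects, or ``"Chr9:136132908"``
    strings (chromosome names match with or without the ``chr`` prefix).
    """
    if panel is None:
        return None
    index = table.locus_index()
    out = []
    for item in panel:
        if isinstance(item, (int, np.integer)):
            out.append(int(item))
        elif isinstance(item, Locus):
            out.append(index[item.key])
        else:
            text = str(item).strip()
            chrom, _, pos = text.rpartition(":")
            key = (normalize_chromosome(chrom), int(pos))
            if key not in index:
                raise KeyError(f"panel locus {text!r} is not a table locus")
            out.append(index[key])
    return tuple(sorted(set(out)))


def _noise_allele(rng: np.random.Generator, table: HaplotypeTable, j: int, current: str) -> str:
    """A random allele outside the table's column j (fallback: any other base)."""
    column = {row.alleles[j] for row in table.rows} | {table.loci[j].reference_allele}
    choices = [b for b in _BASES if b not in column]
    if not choices:
        choices = [b for b in _BASES if b != current]
    return choices[int(rng.integers(len(choices)))]


def planted_genotype(
    table: HaplotypeTable, row_a: int, row_b: int, *, sample_id: str = "planted"
) -> Genotype:
    """The noiseless unphased genotype of the diplotype (row_a, row_b).

    Heterozygous where the two rows differ, homozygous where they agree, and
    no record at loci where both carry the reference allele.
    """
    genotype = Genotype(sample_id=sample_id, assembly=table.assembly)
    a, b = table.rows[row_a], table.rows[row_b]
    for j, locus in enumerate(table.loci):
        pair = (a.alleles[j], b.alleles[j])
        if pair == (locus.reference_allele, locus.reference_allele):
            continue
        genotype.add(GenotypeRecord(locus.chromosome, locus.position, pair[0], pair[1]))
    return genotype


def sample_diplotype(spec: SimulationSpec, index: int) -> TruthRecord:
    """Draw one sample; fully determined by ``(spec.seed, index)``.

    Two rows are drawn with replacement (``row_weights``), the per-locus
    allele pairs formed, then noise, then masking, then panel subsetting;
    zygosity is derived from the final pair.  Loci left homozygous-reference
    produce no record.
    """
    rng = np.random.default_rng((spec.seed, index))
    table = spec.table
    n_rows = len(table.rows)
    p = None if spec.row_weights is None else np.asarray(spec.row_weights, float)
    ia, ib = (int(rng.choice(n_rows, p=p)) for _ in range(2))
    row_a, row_b = table.rows[ia], table.rows[ib]

    genotype = Genotype(sample_id=f"S{index:05d}", assembly=table.assembly)
    panel = set(spec.panel_loci) if spec.panel_loci is not None else None
    for j, locus in enumerate(table.loci):
        pair = [row_a.alleles[j], row_b.alleles[j]]
        if spec.noise_rate and rng.random() < spec.noise_rate:
            side = int(rng.integers(2))
            pair[side] = _noise_allele(rng, table, j, pair[side])
        masked = bool(spec.missing_rate and rng.random() < spec.missing_rate)
        if panel is not None and j not in panel:
            continue
        if masked:
            genotype.add(
                GenotypeRecord(locus.chromosome, locus.position, MISSING, MISSING)
            )
            continue
        if pair[0] == locus.reference_allele and pair[1] == locus.reference_allele:
            continue  # reference homozygote: no record, as real callers emit
        genotype.add(
            GenotypeRecord(locus.chromosome, locus.position, pair[0], pair[1])
        )

    return TruthRecord(
        sample_id=genotype.sample_id,
        row_a=ia,
        row_b=ib,
        label_a=row_a.phenotype,
        label_b=row_b.phenotype,
        genotype=genotype,
    )


def simulate_cohort(spec: SimulationSpec) -> list[TruthRecord]:
    """``n_samples`` independent draws; reproducible and order-independent."""
    return [sample_diplotype(spec, i) for i in range(spec.n_samples)]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Cohort accuracy in the per-class-recall layout (``25/27``-style)."""

    n: int
    n_correct: int
    n_ambiguous: int
    per_phenotype: dict[str, tuple[int, int]]  # label -> (correct, total)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n if self.n else float("nan")

    @property
    def ambiguity_rate(self) -> float:
        return self.n_ambiguous / self.n if self.n else float("nan")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "n_ambiguous": self.n_ambiguous,
            "ambiguity_rate": self.ambiguity_rate,
            "per_phenotype": {
                label: {"correct": c, "total": t, "recall": (c / t if t else None)}
                for label, (c, t) in sorted(self.per_phenotype.items())
            },
        }

    def format_lines(self) -> list[str]:
        lines = [
            f"overall accuracy: {self.accuracy:.4f} ({self.n_correct}/{self.n})",
            f"ambiguous calls:  {self.n_ambiguous} ({self.ambiguity_rate:.4f})",
        ]
        for label, (c, t) in sorted(self.per_phenotype.items()):
            lines.append(f"  {label}: {c}/{t}")
        return lines


def _as_truth_pair(item) -> tuple[str, str]:
    if isinstance(item, TruthRecord):
        return item.label_pair
    a, b = item[-2], item[-1]
    return tuple(sorted((str(a), str(b))))


def _as_predicted(item) -> tuple[tuple[str, str], bool]:
    if isinstance(item, Prediction):
        return item.phenotype_pair, item.ambiguous
    a, b, ambiguous = item
    return tuple(sorted((str(a), str(b)))), bool(ambiguous)


def evaluate_cohort(truth: Sequence, predictions: Sequence) -> EvaluationReport:
    """Score predictions against planted diplotypes.

    A sample is correct when the unordered phenotype pair matches exactly
    and the prediction is unambiguous — equal-score ties count as errors,
    never as lucky guesses.  ``truth`` items are :class:`TruthRecord` or
    ``(sample, label_a, label_b)``; ``predictions`` are :class:`Prediction`
    or ``(label_a, label_b, ambiguous)``.
    """
    if len(truth) != len(predictions):
        raise ValueError(
            f"{len(truth)} truth records vs {len(predictions)} predictions"
        )
    n_correct = n_ambiguous = 0
    per: dict[str, list[int]] = {}
    for t, p in zip(truth, predictions):
        true_pair = _as_truth_pair(t)
        pred_pair, ambiguous = _as_predicted(p)
        ok = (not ambiguous) and pred_pair == true_pair
        n_correct += ok
        n_ambiguous += ambiguous
        for label in set(true_pair):
            entry = per.setdefault(label, [0, 0])
            entry[0] += ok
            entry[1] += 1
    return EvaluationReport(
        n=len(truth),
        n_correct=n_correct,
        n_ambiguous=n_ambiguous,
        per_phenotype={k: (c, t) for k, (c, t) in per.items()},
    )


# ---------------------------------------------------------------------------
# random tables for property testing
# ---------------------------------------------------------------------------


def _pair_union_signature(a: HaplotypeRow, b: HaplotypeRow) -> tuple:
    return tuple(frozenset((x, y)) for x, y in zip(a.alleles, b.alleles))


def has_unique_pair_unions(table: HaplotypeTable) -> bool:
    """True when no two distinct row pairs produce the same unphased genotype."""
    seen = set()
    rows = table.rows
    for i in range(len(rows)):
        for j in range(i, len(rows)):
            sig = _pair_union_signature(rows[i], rows[j])
            if sig in seen:
                return False
            seen.add(sig)
    return True


def random_table(
    n_rows: int,
    n_loci: int,
    rng: np.random.Generator,
    *,
    system: str = "SYN",
    gene: str = "SYN1",
    chromosome: str = "1",
    unique_unions: bool = False,
    include_reference_row: bool = False,
    max_tries: int = 500,
) -> HaplotypeTable:
    """A random haplotype table over single-base alleles.

    With ``unique_unions`` the table is resampled until every unordered row
    pair yields a distinct unphased genotype (the condition under which a
    planted diplotype is exactly recoverable).  With
    ``include_reference_row`` the first row ("REF") equals the per-locus
    reference alleles.
    """
    if n_rows > 4**n_loci:
        raise ValueError(
            f"{n_rows} distinct rows are impossible over {n_loci} single-base loci"
        )
    for _ in range(max_tries):
        ref = tuple(_BASES[i] for i in rng.integers(4, size=n_loci))
        matrix = [
            tuple(_BASES[i] for i in rng.integers(4, size=n_loci))
            for _ in range(n_rows - int(include_reference_row))
        ]
        rows = []
        if include_reference_row:
            rows.append(HaplotypeRow("REF", ref))
        rows.extend(
            HaplotypeRow(f"HAP{i + 1:02d}", alleles)
            for i, alleles in enumerate(matrix)
        )
        vectors = [r.alleles for r in rows]
        if len(set(vectors)) != len(vectors):
            continue
        table = HaplotypeTable(
            loci=tuple(
                Locus(chromosome=chromosome, position=(j + 1) * 100, reference_allele=ref[j])
                for j in range(n_loci)
            ),
            rows=tuple(rows),
            system=system,
            gene=gene,
            reference_row_label="REF" if include_reference_row else None,
        )
        if unique_unions and not has_unique_pair_unions(table):
            continue
        return table
    raise RuntimeError(
        f"could not draw a table with the requested properties in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# file emission (tabular dialect + truth TSV)
# ---------------------------------------------------------------------------

Sink = Union[str, Path, TextIO]


def write_genotype_tabular(genotype: Genotype, sink: Sink) -> None:
    """Write a genotype in the tabular dialect, sorted by coordinate."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as handle:
            write_genotype_tabular(genotype, handle)
        return
    sink.write("#chrom\tpos\talleles\tzygosity\n")
    for key in sorted(genotype.records):
        rec = genotype.records[key]
        sink.write(
            f"{rec.chromosome}\t{rec.position}\t{rec.allele_a}/{rec.allele_b}"
            f"\t{rec.zygosity.value}\n"
        )


def write_cohort(records: Sequence[TruthRecord], out_dir: str | Path) -> Path:
    """Emit ``genotypes/<sample>.tsv`` per sample plus ``truth.tsv``."""
    out_dir = Path(out_dir)
    geno_dir = out_dir / "genotypes"
    geno_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_genotype_tabular(rec.genotype, geno_dir / f"{rec.sample_id}.tsv")
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as handle:
        handle.write("sample\trow_a\trow_b\n")
        for rec in records:
            handle.write(f"{rec.sample_id}\t{rec.label_a}\t{rec.label_b}\n")
    return truth_path


def read_truth(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a truth TSV back as ``(sample, label_a, label_b)`` tuples."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("sample\t"):
            continue
        sample, a, b = line.split("\t")
        out.append((sample, a, b))
    return out
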