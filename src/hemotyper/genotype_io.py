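"""Sample genotype input: tabular dialect, a VCF subset, and locus selection.

A genotype is the set of called variants for one sample, each with explicit
zygosity.  Sites absent from the file are taken to be homozygous for the
reference-assembly allele ("reference fill-in"), which matches how variant
callers emit output.  Only variants at haplotype-table loci ever influence a
prediction; everything else is ignored.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TextIO, Union

import numpy as np

from .errors import (
    AssemblyMismatchError,
    GenotypeParseError,
    MissingDataError,
)
from .knowledge_base import HaplotypeTable, Locus, normalize_chromosome

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "Zygosity",
    "GenotypeRecord",
    "Genotype",
    "ObservedVector",
    "parse_genotype_tabular",
    "parse_genotype_vcf",
    "select_relevant",
]

#: Canonical missing-allele marker; ``.`` and ``--`` are accepted on input.
MISSING = "-"

_MISSING_TOKENS = {"-", ".", "--", ""}


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    MISSING = "missing"


def _normalize_allele(token: str) -> str:
    token = token.strip().upper()
    if token in _MISSING_TOKENS or token in {t.upper() for t in _MISSING_TOKENS}:
        return MISSING
    if not token.isalpha() or set(token) - set("ACGT"):
        raise GenotypeParseError(f"invalid allele {token!r}")
    return token


@dataclass(frozen=True)
class GenotypeRecord:
    """One called variant: coordinates plus the unordered observed allele pair."""

    chromosome: str
    position: int
    allele_a: str
    allele_b: str

    @property
    def zygosity(self) -> Zygosity:
        if self.allele_a == MISSING or self.allele_b == MISSING:
            return Zygosity.MISSING
        if self.allele_a == self.allele_b:
            return Zygosity.HOMOZYGOUS
        return Zygosity.HETEROZYGOUS

    @property
    def key(self) -> tuple[str, int]:
        return (normalize_chromosome(self.chromosome), self.position)


@dataclass
class Genotype:
    """All called variants of one sample, keyed by (chromosome, position)."""

    sample_id: str = "sample"
    assembly: str = "hg19"
    records: dict[tuple[str, int], GenotypeRecord] = field(default_factory=dict)

    def add(self, record: GenotypeRecord) -> None:
        if record.key in self.records:
            chrom, pos = record.key
            raise GenotypeParseError(
                f"duplicate genotype record at {chrom}:{pos} for sample "
                f"{self.sample_id!r}"
            )
        self.records[record.key] = record

    def get(self, chromosome: str, position: int) -> GenotypeRecord | None:
        return self.records.get((normalize_chromosome(chromosome), position))

    def __len__(self) -> int:
        return len(self.records)


Source = Union[str, Path, TextIO]


def _iter_lines(source: Source):
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from enumerate(handle, 1)
    else:
        yield from enumerate(source, 1)


_ZYGOSITY_ALIASES = {
    "hom": Zygosity.HOMOZYGOUS,
    "homozygous": Zygosity.HOMOZYGOUS,
    "het": Zygosity.HETEROZYGOUS,
    "heterozygous": Zygosity.HETEROZYGOUS,
    "missing": Zygosity.MISSING,
}


def parse_genotype_tabular(
    source: Source, *, sample_id: str = "sample", assembly: str = "hg19"
) -> Genotype:
    """Parse the tab-separated genotype dialect.

    Columns: ``chrom  pos  alleles  [zygosity]`` with alleles written
    ``X/Y`` (missing marker ``-`` or ``.``).  Zygosity is derived from the
    allele pair; if the optional fourth column is present it must agree.
    A header line whose second field is not an integer is skipped; ``#``
    lines are comments.
    """
    genotype = Genotype(sample_id=sample_id, assembly=assembly)
    for lineno, line in _iter_lines(source):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise GenotypeParseError(
                f"line {lineno}: expected 'chrom<TAB>pos<TAB>alleles', got {line!r}"
            )
        chrom, pos_text, allele_text = cells[0].strip(), cells[1].strip(), cells[2].strip()
        if not pos_text.lstrip("-").isdigit():
            if lineno == 1 or pos_text.lower() in {"pos", "position"}:
                continue  # header line
            raise GenotypeParseError(f"line {lineno}: malformed position {pos_text!r}")
        position = int(pos_text)
        if position < 1:
            raise GenotypeParseError(f"line {lineno}: position must be >= 1")
        if "/" not in allele_text:
            raise GenotypeParseError(
                f"line {lineno}: alleles must be written 'X/Y', got {allele_text!r}"
            )
        left, _, right = allele_text.partition("/")
        record = GenotypeRecord(
            chromosome=chrom,
            position=position,
            allele_a=_normalize_allele(left),
            allele_b=_normalize_allele(right),
        )
        if len(cells) >= 4 and cells[3].strip():
            declared = _ZYGOSITY_ALIASES.get(cells[3].strip().lower())
            if declared is None:
                raise GenotypeParseError(
                    f"line {lineno}: unknown zygosity {cells[3].strip()!r}"
                )
            if declared is not record.zygosity:
                raise GenotypeParseError(
                    f"line {lineno}: declared zygosity {declared.value} conflicts "
                    f"with allele pair {record.allele_a}/{record.allele_b}"
                )
        genotype.add(record)
    return genotype


def parse_genotype_vcf(
    path: str | Path, *, sample: str | None = None, assembly: str = "hg19"
) -> Genotype:
    """Read a single sample's genotype from a VCF 4.x file via pysam.

    Only CHROM, POS, REF, ALT and the GT format field are consulted.
    ``0/0`` sites and sites absent from the file are not recorded (reference
    by fill-in); ``./.`` becomes a missing record; ``1/2`` a heterozygous
    ALT1/ALT2 pair; haploid calls are treated as homozygous.  Symbolic ALT
    alleles (``<DEL>`` etc.) are skipped with a logged warning.  A
    multi-sample VCF requires ``sample=``.
    """
    import pysam

    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise GenotypeParseError(f"{path}: VCF has no sample columns (GT needed)")
        if sample is None:
            if len(samples) > 1:
                raise GenotypeParseError(
                    f"{path}: multi-sample VCF ({len(samples)} samples); "
                    "pass sample= to select one"
                )
            sample = samples[0]
        elif sample not in samples:
            raise GenotypeParseError(f"{path}: no sample {sample!r} in VCF")

        genotype = Genotype(sample_id=sample, assembly=assembly)
        for rec in vcf:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or len(gt) == 0:
                continue
            if len(gt) == 1:  # haploid / hemizygous: duplicate the allele
                gt = (gt[0], gt[0])
            if any(i is None for i in gt):
                genotype.add(
                    GenotypeRecord(rec.chrom, rec.pos, MISSING, MISSING)
                )
                continue
            if gt == (0, 0):
                continue
            alleles = []
            skip = False
            for i in gt:
                allele = rec.ref if i == 0 else (rec.alts or [None] * i)[i - 1]
                if allele is None or set(allele.upper()) - set("ACGT"):
                    logger.warning(
                        "skipping record %s:%d with symbolic or unusable allele %r",
                        rec.chrom,
                        rec.pos,
                        allele,
                    )
                    skip = True
                    break
                alleles.append(allele.upper())
            if skip:
                continue
            genotype.add(GenotypeRecord(rec.chrom, rec.pos, alleles[0], alleles[1]))
    return genotype


# ---------------------------------------------------------------------------
# locus selection and reference fill-in
# ---------------------------------------------------------------------------


@dataclass
class ObservedVector:
    """A genotype projected onto one table's loci, with reference fill-in.

    ``states_a``/``states_b`` hold the per-locus allele pair; at heterozygous
    loci the two alleles are not yet assigned to chromatids — phasing decides
    that.  ``n_hom``/``n_het`` are the N and M of the enumeration (counted
    over records present at table loci); ``missing_mask`` marks loci excluded
    from distance computation under the ``exclude-locus`` policy.
    """

    loci: tuple[Locus, ...]
    states_a: tuple[str, ...]
    states_b: tuple[str, ...]
    het_mask: np.ndarray
    missing_mask: np.ndarray
    n_hom: int
    n_het: int
    n_missing: int

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.states_a, self.states_b))


def select_relevant(
    genotype: Genotype,
    table: HaplotypeTable,
    *,
    missing_policy: str = "exclude-locus",
) -> ObservedVector:
    """Project a genotype onto a table's loci.

    Records at non-table positions are ignored; table loci without a record
    are filled with the reference allele on both sides.  ``missing_policy``
    governs loci whose record has a missing allele:

    - ``"exclude-locus"`` (default): drop the locus from distance
      computation for every haplotype row — the least biased choice;
    - ``"as-reference"``: substitute the reference allele;
    - ``"fail"``: raise :class:`MissingDataError` naming the sample, for
      pipelines that would rather exclude such samples outright.
    """
    if missing_policy not in {"exclude-locus", "as-reference", "fail"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if genotype.assembly.lower() != table.assembly.lower():
        raise AssemblyMismatchError(
            f"genotype assembly {genotype.assembly!r} != table assembly "
            f"{table.assembly!r}; no silent lift-over"
        )

    n = table.n_loci
    states_a = list(table.reference_alleles)
    states_b = list(table.reference_alleles)
    het = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)
    n_hom = n_het = n_missing = 0

    for i, locus in enumerate(table.loci):
        record = genotype.records.get(locus.key)
        if record is None:
            continue
        zyg = record.zygosity
        if zyg is Zygosity.MISSING:
            n_missing += 1
            if missing_policy == "fail":
                raise MissingDataError(
                    f"sample {genotype.sample_id!r} has a missing call at "
                    f"{locus} (policy=fail)"
                )
            if missing_policy == "as-reference":
                continue  # keep the reference fill-in
            states_a[i] = states_b[i] = MISSING
            missing[i] = True
        elif zyg is Zygosity.HOMOZYGOUS:
            n_hom += 1
            states_a[i] = states_b[i] = record.allele_a
        else:
            n_het += 1
            states_a[i], states_b[i] = record.allele_a, record.allele_b
            het[i] = True

    return ObservedVector(
        loci=table.loci,
        states_a=tuple(states_a),
        states_b=tuple(states_b),
        het_mask=het,
        missing_mask=missing,
        n_hom=n_hom,
        n_het=n_het,
        n_missing=n_missing,
    )
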