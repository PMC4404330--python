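"""Curated haplotype tables: the genotype-to-phenotype knowledge base.

A haplotype table describes, for one gene of one blood-group system, the
allele combinations (haplotypes) known to produce each named phenotype.
Columns are genomic loci of the reference assembly; rows are phenotypes; each
cell holds the plus-strand allele string expected on one chromatid at that
locus.  Insertions and deletions are encoded as anchored allele strings of a
different length than the reference allele (e.g. ``GG`` against reference
``G``), and every cell is treated downstream as an atomic categorical symbol
— the engine never aligns allele strings character by character.

File dialect (UTF-8, tab-separated)::

    #system=ABO
    #gene=ABO
    #assembly=hg19
    #ref=G,C,G
    #reference_row=O02
    Phenotype	Chr9:136132908	Chr9:136131650	Chr9:136131414
    A101	GG	C	G
    ...

Per-locus reference alleles come either from ``#ref=`` or from the row named
by ``#reference_row=``; one of the two is required, because loci absent from
a sample's genotype are filled in with the reference allele.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence, TextIO, Union

from .errors import TableParseError, TableValidationError

__all__ = [
    "Locus",
    "HaplotypeRow",
    "HaplotypeTable",
    "Diagnostic",
    "parse_haplotype_table",
    "validate_table",
    "write_haplotype_table",
    "table_to_string",
    "parse_manifest",
    "load_manifest",
    "load_demo_table",
    "normalize_chromosome",
]

_ALLELE_RE = re.compile(r"[ACGT]+\Z")
_LOCUS_HEADER_RE = re.compile(r"chr([^:\s]+):(\d+)\Z", re.IGNORECASE)


def normalize_chromosome(name: str) -> str:
    """Normalize a chromosome name: ``"chr9"`` and ``"9"`` are equivalent."""
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


def _check_allele(allele: str) -> str:
    if not _ALLELE_RE.match(allele):
        raise TableValidationError(
            f"allele {allele!r} contains characters outside {{A,C,G,T}}"
        )
    return allele


@dataclass(frozen=True)
class Locus:
    """One genomic position of a haplotype table.

    Coordinates are 1-based on the plus strand of the stated assembly, even
    for genes transcribed from the minus strand (ABO, for one, lies on the
    minus strand of chromosome 9); this matches variant-caller output.
    """

    chromosome: str
    position: int
    reference_allele: str
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise TableValidationError(
                f"locus position must be >= 1, got {self.position}"
            )
        _check_allele(self.reference_allele)

    @property
    def chrom_norm(self) -> str:
        return normalize_chromosome(self.chromosome)

    @property
    def key(self) -> tuple[str, int]:
        """Normalized (chromosome, position) key used for genotype lookup."""
        return (self.chrom_norm, self.position)

    def __str__(self) -> str:  # the header spelling
        return f"Chr{self.chromosome}:{self.position}"


@dataclass(frozen=True)
class HaplotypeRow:
    """One named haplotype: a phenotype label plus one allele per table locus."""

    phenotype: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phenotype:
            raise TableValidationError("phenotype label must be non-empty")
        object.__setattr__(self, "alleles", tuple(self.alleles))
        for a in self.alleles:
            _check_allele(a)


@dataclass
class HaplotypeTable:
    """Knowledge base for one gene: ordered loci and named haplotype rows.

    ``weights`` are optional per-locus scoring weights; they default to 1.0
    everywhere because uniform weighting is the method's baseline behaviour
    (non-uniform weights are an extension hook, off unless the table file
    sets ``#weights=``).
    """

    loci: tuple[Locus, ...]
    rows: tuple[HaplotypeRow, ...]
    system: str | None = None
    gene: str | None = None
    reference_row_label: str | None = None
    weights: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.rows = tuple(self.rows)
        if self.weights is not None:
            self.weights = tuple(float(w) for w in self.weights)
        self._validate_invariants()

    def _validate_invariants(self) -> None:
        if not self.loci:
            raise TableValidationError("a haplotype table needs at least one locus")
        if not self.rows:
            raise TableValidationError("a haplotype table needs at least one row")
        keys = [locus.key for locus in self.loci]
        if len(set(keys)) != len(keys):
            raise TableValidationError("duplicate (chromosome, position) among loci")
        assemblies = {locus.assembly for locus in self.loci}
        if len(assemblies) > 1:
            raise TableValidationError(f"mixed assemblies in one table: {assemblies}")
        for row in self.rows:
            if len(row.alleles) != len(self.loci):
                raise TableValidationError(
                    f"row {row.phenotype!r} has {len(row.alleles)} alleles "
                    f"for {len(self.loci)} loci"
                )
        pairs = [(r.phenotype, r.alleles) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise TableValidationError(
                f"duplicate (phenotype, allele-vector) rows: {dupes}"
            )
        if self.weights is not None:
            if len(self.weights) != len(self.loci):
                raise TableValidationError("weights length must match locus count")
            if any(w < 0 for w in self.weights):
                raise TableValidationError("weights must be non-negative")
        if self.reference_row_label is not None:
            ref = self.reference_alleles
            matches = [
                r
                for r in self.rows
                if r.phenotype == self.reference_row_label and r.alleles == ref
            ]
            if not matches:
                raise TableValidationError(
                    f"reference row {self.reference_row_label!r} does not match "
                    f"the per-locus reference alleles {ref}"
                )

    # -- convenience -------------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def assembly(self) -> str:
        return self.loci[0].assembly

    @property
    def reference_alleles(self) -> tuple[str, ...]:
        return tuple(locus.reference_allele for locus in self.loci)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.phenotype for r in self.rows)

    def locus_index(self) -> dict[tuple[str, int], int]:
        """Map normalized (chromosome, position) to column index."""
        return {locus.key: i for i, locus in enumerate(self.loci)}

    def canonicalized(self) -> "HaplotypeTable":
        """Equivalent table with loci sorted by (chromosome, position).

        Allele vectors (and weights) are permuted consistently, so a table
        whose file listed columns in a different order compares equal to this
        one after canonicalization.
        """
        order = sorted(
            range(self.n_loci), key=lambda i: (self.loci[i].chrom_norm, self.loci[i].position)
        )
        return HaplotypeTable(
            loci=tuple(self.loci[i] for i in order),
            rows=tuple(
                HaplotypeRow(r.phenotype, tuple(r.alleles[i] for i in order))
                for r in self.rows
            ),
            system=self.system,
            gene=self.gene,
            reference_row_label=self.reference_row_label,
            weights=None if self.weights is None else tuple(self.weights[i] for i in order),
        )


class Diagnostic(NamedTuple):
    """A non-fatal table finding reported by :func:`validate_table`."""

    kind: str  # "duplicate_row" | "non_discriminative_locus" | "ambiguous_rows"
    message: str


def validate_table(table: HaplotypeTable) -> list[Diagnostic]:
    """Report curation hazards in a parsed table.

    Diagnostics only — nothing here rejects the table.  Flags rows that share
    an allele vector but carry different phenotype labels (the engine would
    surface these as nearest-row ties), and loci whose allele is identical in
    every row (they can never discriminate between phenotypes).
    """
    out: list[Diagnostic] = []
    by_vector: dict[tuple[str, ...], list[str]] = {}
    for row in table.rows:
        by_vector.setdefault(row.alleles, []).append(row.phenotype)
    for vector, labels in by_vector.items():
        if len(labels) > 1:
            out.append(
                Diagnostic(
                    "ambiguous_rows",
                    f"rows {sorted(set(labels))} share the allele vector {vector}",
                )
            )
    if len(table.rows) > 1:
        for i, locus in enumerate(table.loci):
            column = {r.alleles[i] for r in table.rows}
            if len(column) == 1:
                out.append(
                    Diagnostic(
                        "non_discriminative_locus",
                        f"locus {locus} carries {next(iter(column))!r} in every row",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

Source = Union[str, Path, TextIO]


def _open_text(source: Source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def parse_haplotype_table(source: Source) -> HaplotypeTable:
    """Parse a haplotype table from the tab-separated dialect.

    ``source`` may be a path or an open text stream.  See the module
    docstring for the format.  Raises :class:`TableParseError` for syntax
    problems (naming the offending row or column) and
    :class:`TableValidationError` for invariant violations such as allele
    characters outside {A,C,G,T}.
    """
    handle = _open_text(source)
    close = isinstance(source, (str, Path))
    try:
        meta: dict[str, str] = {}
        header: list[str] | None = None
        raw_rows: list[tuple[int, list[str]]] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip().lower()] = value.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                raw_rows.append((lineno, cells))
    finally:
        if close:
            handle.close()

    if header is None:
        raise TableParseError("no header line found")
    if len(header) < 2:
        raise TableParseError("header needs a phenotype column and at least one locus")

    assembly = meta.get("assembly", "hg19")
    locus_coords: list[tuple[str, int]] = []
    for col, cell in enumerate(header[1:], start=2):
        m = _LOCUS_HEADER_RE.match(cell.strip())
        if not m:
            raise TableParseError(
                f"malformed locus header in column {col}: {cell!r} "
                "(expected Chr<name>:<position>)"
            )
        locus_coords.append((m.group(1), int(m.group(2))))
    n_loci = len(locus_coords)

    rows: list[HaplotypeRow] = []
    for lineno, cells in raw_rows:
        if len(cells) != n_loci + 1:
            raise TableParseError(
                f"ragged row {cells[0]!r} (line {lineno}): "
                f"{len(cells) - 1} alleles for {n_loci} loci"
            )
        rows.append(HaplotypeRow(cells[0].strip(), tuple(c.strip().upper() for c in cells[1:])))
    if not rows:
        raise TableParseError("table has no haplotype rows")

    reference_row_label = meta.get("reference_row") or None
    if "ref" in meta:
        refs = tuple(a.strip().upper() for a in meta["ref"].split(","))
        if len(refs) != n_loci:
            raise TableParseError(
                f"#ref= lists {len(refs)} alleles for {n_loci} loci"
            )
    elif reference_row_label is not None:
        candidates = [r for r in rows if r.phenotype == reference_row_label]
        if not candidates:
            raise TableParseError(
                f"#reference_row={reference_row_label!r} names no row in the table"
            )
        refs = candidates[0].alleles
    else:
        raise TableParseError(
            "no per-locus reference alleles: supply #ref= or #reference_row= "
            "(required for reference fill-in of loci absent from a genotype)"
        )

    weights = None
    if "weights" in meta:
        try:
            weights = tuple(float(w) for w in meta["weights"].split(","))
        except ValueError as exc:
            raise TableParseError(f"malformed #weights=: {meta['weights']!r}") from exc

    loci = tuple(
        Locus(chromosome=c, position=p, reference_allele=r, assembly=assembly)
        for (c, p), r in zip(locus_coords, refs)
    )
    return HaplotypeTable(
        loci=loci,
        rows=tuple(rows),
        system=meta.get("system") or None,
        gene=meta.get("gene") or None,
        reference_row_label=reference_row_label,
        weights=weights,
    )


def write_haplotype_table(table: HaplotypeTable, sink: Source) -> None:
    """Write ``table`` in the tab-separated dialect; write→parse round-trips."""
    handle: TextIO
    if isinstance(sink, (str, Path)):
        handle = open(sink, "w", encoding="utf-8")
        close = True
    else:
        handle, close = sink, False
    try:
        if table.system:
            handle.write(f"#system={table.system}\n")
        if table.gene:
            handle.write(f"#gene={table.gene}\n")
        handle.write(f"#assembly={table.assembly}\n")
        handle.write("#ref=" + ",".join(table.reference_alleles) + "\n")
        if table.reference_row_label:
            handle.write(f"#reference_row={table.reference_row_label}\n")
        if table.weights is not None:
            handle.write("#weights=" + ",".join(repr(w) for w in table.weights) + "\n")
        handle.write("Phenotype\t" + "\t".join(str(l) for l in table.loci) + "\n")
        for row in table.rows:
            handle.write(row.phenotype + "\t" + "\t".join(row.alleles) + "\n")
    finally:
        if close:
            handle.close()


def table_to_string(table: HaplotypeTable) -> str:
    buf = io.StringIO()
    write_haplotype_table(table, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# system manifests
# ---------------------------------------------------------------------------


def parse_manifest(path: str | Path) -> dict[str, list[Path]]:
    """Read a system manifest: tab-separated ``system<TAB>table-path`` lines.

    Relative table paths are resolved against the manifest's directory.
    Multi-gene systems (Rh = RhD + RhCE) simply list several tables under the
    same system name.
    """
    path = Path(path)
    out: dict[str, list[Path]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TableParseError(
                f"manifest line {lineno}: expected 'system<TAB>path', got {line!r}"
            )
        system, table_path = parts[0].strip(), Path(parts[1].strip())
        if not table_path.is_absolute():
            table_path = path.parent / table_path
        out.setdefault(system, []).append(table_path)
    if not out:
        raise TableParseError(f"manifest {path} lists no tables")
    return out


def load_manifest(path: str | Path) -> dict[str, list[HaplotypeTable]]:
    """Parse every table referenced by a manifest, grouped by system name."""
    out: dict[str, list[HaplotypeTable]] = {}
    for system, paths in parse_manifest(path).items():
        tables = []
        for p in paths:
            table = parse_haplotype_table(p)
            if table.system is None:
                table = replace_system(table, system)
            tables.append(table)
        out[system] = tables
    return out


def replace_system(table: HaplotypeTable, system: str) -> HaplotypeTable:
    return HaplotypeTable(
        loci=table.loci,
        rows=table.rows,
        system=system,
        gene=table.gene,
        reference_row_label=table.reference_row_label,
        weights=table.weights,
    )


def load_demo_table() -> HaplotypeTable:
    """Load the small bundled ABO demonstration table.

    Four haplotypes (A101, A102, O02, B101) over three exonic loci of the ABO
    gene on chromosome 9 (hg19 plus-strand coordinates).  The O02 row equals
    the hg19 reference; the ``GG`` cells encode an anchored frameshift
    insertion relative to the reference ``G``.
    """
    from importlib.resources import files

    resource = files("hemotyper").joinpath("data/abo_demo.tsv")
    with resource.open("r", encoding="utf-8") as handle:
        return parse_haplotype_table(handle)
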