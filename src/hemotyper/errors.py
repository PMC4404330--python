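"""Exception hierarchy.

All package-specific failures derive from :class:`HemotyperError` so callers
(and the CLI, which maps them to distinct exit codes) can distinguish parse
problems from algorithmic limits.
"""


class HemotyperError(Exception):
    """Base class for all package errors."""


class TableParseError(HemotyperError):
    """A haplotype-table file is syntactically malformed."""


class TableValidationError(HemotyperError):
    """A parsed haplotype table violates a structural invariant."""


class GenotypeParseError(HemotyperError):
    """A genotype file (tabular or VCF) is malformed or inconsistent."""


class AssemblyMismatchError(HemotyperError):
    """Genotype and haplotype table refer to different reference assemblies."""


class MissingDataError(HemotyperError):
    """A sample has missing calls at table loci under the ``fail`` policy."""


class EnumerationCapError(HemotyperError):
    """Too many heterozygous loci: configuration enumeration would exceed the cap."""
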