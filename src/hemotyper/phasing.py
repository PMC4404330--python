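"""Joint haplotype phasing and phenotype calling by exhaustive enumeration.

With M heterozygous loci at a gene, the unphased genotype is compatible with
``2^(M-1)`` distinct assignments of alleles to the two chromatids (the
chromatid-swap symmetry halves the naive ``2^M``).  Each configuration's two
allele vectors are scored independently against the haplotype table by
1-nearest-neighbour Hamming distance — allele strings compare as atomic
symbols, so an indel mismatch costs the same 1 as a substitution — and the
configuration minimising the summed distance is the maximum-parsimony
diplotype: the phasing that requires the fewest deviations from known
haplotypes.  Exhaustive enumeration is affordable because the tables hold
only the few exonic loci known to determine each phenotype, and strong
linkage disequilibrium within a gene keeps M small.

Ties are never resolved silently: every configuration at the optimal score
is reported, every nearest-row tie is listed, and the prediction is flagged
ambiguous whenever the optima disagree on the unordered phenotype pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import EnumerationCapError
from .genotype_io import Genotype, ObservedVector, select_relevant
from .knowledge_base import HaplotypeRow, HaplotypeTable

__all__ = [
    "Configuration",
    "ChromatidCall",
    "Prediction",
    "PredictionFailure",
    "RankedConfiguration",
    "enumerate_configurations",
    "hamming_distance",
    "nearest_row",
    "score_configuration",
    "predict",
    "predict_system",
    "DEFAULT_MAX_HET",
]

#: Default cap on heterozygous loci (2^19 configurations at the cap).
DEFAULT_MAX_HET = 20


@dataclass(frozen=True)
class Configuration:
    """One assignment of heterozygous alleles to the two chromatids.

    ``assignment_mask[k]`` is True when the k-th heterozygous locus sent its
    first observed allele to chromatid A.  The first heterozygous locus is
    always assigned canonically (mask True), which eliminates the A/B swap
    symmetry from the enumeration.
    """

    vector_a: tuple[str, ...]
    vector_b: tuple[str, ...]
    assignment_mask: tuple[bool, ...]


@dataclass(frozen=True)
class ChromatidCall:
    """Nearest haplotype row for one chromatid's allele vector."""

    phenotype: str
    row_index: int
    distance: float
    tied_rows: tuple[str, ...]


class RankedConfiguration(NamedTuple):
    total_score: float
    assignment_mask: tuple[bool, ...]


@dataclass(frozen=True)
class PredictionFailure:
    """Recorded per-gene failure inside :func:`predict_system`."""

    error: str
    exception: Exception | None = None


@dataclass
class Prediction:
    """The maximum-parsimony diplotype call for one gene.

    ``call_a``/``call_b`` belong to the first optimal configuration in
    canonical enumeration order (deterministic); ``best_configurations``
    holds every configuration at the optimal summed distance; ``ambiguous``
    is set when the optima do not agree on a single unordered phenotype pair
    (including nearest-row ties within one chromatid, as when a positive and
    a negative haplotype sit at the same distance).
    """

    call_a: ChromatidCall
    call_b: ChromatidCall
    total_score: float
    best_configurations: tuple[Configuration, ...]
    ambiguous: bool
    ranking: tuple[RankedConfiguration, ...]
    phenotype_pairs: frozenset[tuple[str, str]]
    n_hom: int
    n_het: int
    n_missing: int

    @property
    def phenotype_pair(self) -> tuple[str, str]:
        """Unordered (sorted) phenotype pair of the primary call."""
        return tuple(sorted((self.call_a.phenotype, self.call_b.phenotype)))


# ---------------------------------------------------------------------------
# elementary operations (pure-Python reference surface)
# ---------------------------------------------------------------------------


def _active_mask(n: int, active_loci) -> np.ndarray:
    if active_loci is None:
        return np.ones(n, dtype=bool)
    arr = np.asarray(active_loci)
    if arr.dtype == bool:
        if arr.shape != (n,):
            raise ValueError("boolean active_loci mask has wrong length")
        return arr
    mask = np.zeros(n, dtype=bool)
    mask[arr.astype(int)] = True
    return mask


def hamming_distance(
    vector: Sequence[str],
    row: HaplotypeRow | Sequence[str],
    active_loci=None,
    weights: Sequence[float] | None = None,
) -> float:
    """Weighted Hamming distance between an allele vector and a haplotype row.

    Each locus contributes ``weight[i]`` when the allele strings differ as
    whole symbols (substitution or indel alike), 0 otherwise.  With the
    default unit weights the result is an exact integer count.
    """
    alleles = row.alleles if isinstance(row, HaplotypeRow) else tuple(row)
    if len(vector) != len(alleles):
        raise ValueError(
            f"vector has {len(vector)} loci but row has {len(alleles)}"
        )
    mask = _active_mask(len(alleles), active_loci)
    if weights is None:
        return int(
            sum(1 for i in range(len(alleles)) if mask[i] and vector[i] != alleles[i])
        )
    if len(weights) != len(alleles):
        raise ValueError("weights length must match locus count")
    return float(
        sum(
            weights[i]
            for i in range(len(alleles))
            if mask[i] and vector[i] != alleles[i]
        )
    )


def nearest_row(
    vector: Sequence[str],
    table: HaplotypeTable,
    active_loci=None,
    weights: Sequence[float] | None = None,
) -> ChromatidCall:
    """1-nearest-neighbour call: the minimal-distance table row.

    Ties are kept in table order; the reported phenotype is the first tied
    row's label, which makes the call deterministic.
    """
    if weights is None:
        weights = table.weights
    distances = [
        hamming_distance(vector, row, active_loci, weights) for row in table.rows
    ]
    dmin = min(distances)
    tied = [i for i, d in enumerate(distances) if d <= dmin + 1e-12]
    return ChromatidCall(
        phenotype=table.rows[tied[0]].phenotype,
        row_index=tied[0],
        distance=dmin,
        tied_rows=tuple(table.rows[i].phenotype for i in tied),
    )


def score_configuration(
    config: Configuration,
    table: HaplotypeTable,
    active_loci=None,
    weights: Sequence[float] | None = None,
) -> tuple[ChromatidCall, ChromatidCall, float]:
    """Score one configuration: independent 1-NN call per chromatid, summed."""
    call_a = nearest_row(config.vector_a, table, active_loci, weights)
    call_b = nearest_row(config.vector_b, table, active_loci, weights)
    return call_a, call_b, call_a.distance + call_b.distance


# ---------------------------------------------------------------------------
# configuration enumeration
# ---------------------------------------------------------------------------


def _het_indices(observed: ObservedVector) -> np.ndarray:
    return np.flatnonzero(observed.het_mask)


def _check_cap(m: int, max_het: int) -> None:
    if m > max_het:
        raise EnumerationCapError(
            f"{m} heterozygous loci exceed the enumeration cap of {max_het} "
            f"(2^{m - 1} configurations); restrict the table's loci or raise "
            "max_het explicitly"
        )


def _materialize(observed: ObservedVector, het: np.ndarray, mask_id: int) -> Configuration:
    va = list(observed.states_a)
    vb = list(observed.states_b)
    assignment = [True]
    for k, j in enumerate(het[1:]):
        keep = not ((mask_id >> k) & 1)
        assignment.append(keep)
        if not keep:
            va[j], vb[j] = vb[j], va[j]
    if len(het) == 0:
        assignment = []
    return Configuration(tuple(va), tuple(vb), tuple(assignment))


def enumerate_configurations(
    observed: ObservedVector, max_het: int = DEFAULT_MAX_HET
) -> list[Configuration]:
    """All swap-distinct chromatid assignments, in canonical order.

    Exactly ``2^(M-1)`` configurations for M >= 1 heterozygous loci and a
    single configuration for M = 0.  Raises :class:`EnumerationCapError`
    beyond ``max_het``.
    """
    het = _het_indices(observed)
    _check_cap(len(het), max_het)
    n_cfg = 1 << max(len(het) - 1, 0)
    return [_materialize(observed, het, i) for i in range(n_cfg)]


# ---------------------------------------------------------------------------
# vectorized solver
# ---------------------------------------------------------------------------


class TableIndex:
    """Integer-coded view of a haplotype table for fast batch scoring.

    Alleles are coded per locus; observed alleles never seen in the table
    (or at the reference) get the sentinel code -1, which mismatches every
    row.  Built once per table and reused across samples.
    """

    def __init__(self, table: HaplotypeTable, weights: Sequence[float] | None = None):
        self.table = table
        n_loci = table.n_loci
        self.symbols: list[dict[str, int]] = []
        for j in range(n_loci):
            codes: dict[str, int] = {}
            for row in table.rows:
                codes.setdefault(row.alleles[j], len(codes))
            codes.setdefault(table.loci[j].reference_allele, len(codes))
            self.symbols.append(codes)
        self.R = np.array(
            [[self.symbols[j][row.alleles[j]] for j in range(n_loci)] for row in table.rows],
            dtype=np.int32,
        )
        if weights is None:
            weights = table.weights
        self.weights = (
            np.ones(n_loci) if weights is None else np.asarray(weights, dtype=float)
        )
        if self.weights.shape != (n_loci,):
            raise ValueError("weights length must match locus count")
        self.integral = bool(np.all(self.weights == np.round(self.weights)))
        self.labels = table.labels

    def encode_vector(self, states: Sequence[str]) -> np.ndarray:
        return np.array(
            [self.symbols[j].get(a, -1) for j, a in enumerate(states)], dtype=np.int32
        )


def _config_code_matrices(
    a: np.ndarray, b: np.ndarray, het: np.ndarray, mask_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n = len(mask_ids)
    mat_a = np.repeat(a[None, :], n, axis=0)
    mat_b = np.repeat(b[None, :], n, axis=0)
    for k, j in enumerate(het[1:]):
        swap = ((mask_ids >> k) & 1).astype(bool)
        mat_a[swap, j] = b[j]
        mat_b[swap, j] = a[j]
    return mat_a, mat_b


def _row_distances(x: np.ndarray, index: TableIndex, wa: np.ndarray) -> np.ndarray:
    """Distances of configuration matrix ``x`` (n, L) to every table row."""
    return (x[:, None, :] != index.R[None, :, :]) @ wa


class _Solved(NamedTuple):
    totals: np.ndarray  # per configuration, canonical order
    best_score: float
    best_ids: np.ndarray
    a_codes: np.ndarray
    b_codes: np.ndarray
    het: np.ndarray
    wa: np.ndarray  # weights * active mask


def _solve(
    index: TableIndex,
    observed: ObservedVector,
    *,
    max_het: int = DEFAULT_MAX_HET,
    chunk: int = 8192,
) -> _Solved:
    het = _het_indices(observed)
    _check_cap(len(het), max_het)
    wa = index.weights * ~observed.missing_mask
    a = index.encode_vector(observed.states_a)
    b = index.encode_vector(observed.states_b)
    n_cfg = 1 << max(len(het) - 1, 0)
    totals = np.empty(n_cfg)
    for start in range(0, n_cfg, chunk):
        ids = np.arange(start, min(start + chunk, n_cfg))
        mat_a, mat_b = _config_code_matrices(a, b, het, ids)
        totals[ids] = _row_distances(mat_a, index, wa).min(axis=1)
        totals[ids] += _row_distances(mat_b, index, wa).min(axis=1)
    best = totals.min()
    best_ids = np.flatnonzero(totals <= best + 1e-9)
    return _Solved(totals, float(best), best_ids, a, b, het, wa)


def _tied_labels(x: np.ndarray, index: TableIndex, wa: np.ndarray) -> tuple[int, float, list[int]]:
    d = (x[None, :] != index.R) @ wa
    dmin = float(d.min())
    tied = np.flatnonzero(d <= dmin + 1e-9)
    return int(tied[0]), dmin, list(tied)


def _codes_for_mask(
    solved: _Solved, mask_id: int
) -> tuple[np.ndarray, np.ndarray]:
    a = solved.a_codes.copy()
    b = solved.b_codes.copy()
    for k, j in enumerate(solved.het[1:]):
        if (mask_id >> k) & 1:
            a[j], b[j] = b[j], a[j]
    return a, b


def _as_score(value: float, index: TableIndex) -> float:
    return int(round(value)) if index.integral else value


def predict_observed(
    observed: ObservedVector,
    table: HaplotypeTable,
    *,
    max_het: int = DEFAULT_MAX_HET,
    weights: Sequence[float] | None = None,
    keep_ranking: bool = True,
    _index: TableIndex | None = None,
) -> Prediction:
    """Run the solver on an already-projected :class:`ObservedVector`."""
    index = _index if _index is not None else TableIndex(table, weights)
    solved = _solve(index, observed, max_het=max_het)

    best_configs = tuple(
        _materialize(observed, solved.het, int(i)) for i in solved.best_ids
    )

    # Per-chromatid calls for every optimal configuration, collecting the set
    # of unordered phenotype pairs over all nearest-row ties as we go.
    labels = index.labels
    pairs: set[tuple[str, str]] = set()
    call_a = call_b = None
    for mask_id in solved.best_ids:
        a, b = _codes_for_mask(solved, int(mask_id))
        ia, da, tied_a = _tied_labels(a, index, solved.wa)
        ib, db, tied_b = _tied_labels(b, index, solved.wa)
        for i in tied_a:
            for j in tied_b:
                pairs.add(tuple(sorted((labels[i], labels[j]))))
        if call_a is None:
            call_a = ChromatidCall(
                labels[ia], ia, _as_score(da, index),
                tuple(labels[i] for i in tied_a),
            )
            call_b = ChromatidCall(
                labels[ib], ib, _as_score(db, index),
                tuple(labels[j] for j in tied_b),
            )
    ambiguous = len(pairs) > 1

    if keep_ranking:
        order = np.lexsort((np.arange(len(solved.totals)), solved.totals))
        ranking = tuple(
            RankedConfiguration(
                _as_score(solved.totals[i], index),
                _materialize(observed, solved.het, int(i)).assignment_mask,
            )
            for i in order
        )
    else:
        ranking = ()

    return Prediction(
        call_a=call_a,
        call_b=call_b,
        total_score=_as_score(solved.best_score, index),
        best_configurations=best_configs,
        ambiguous=ambiguous,
        ranking=ranking,
        phenotype_pairs=frozenset(pairs),
        n_hom=observed.n_hom,
        n_het=observed.n_het,
        n_missing=observed.n_missing,
    )


def predict(
    genotype: Genotype,
    table: HaplotypeTable,
    *,
    missing_policy: str = "exclude-locus",
    max_het: int = DEFAULT_MAX_HET,
    weights: Sequence[float] | None = None,
    keep_ranking: bool = True,
) -> Prediction:
    """Phase a genotype against one haplotype table and call both chromatids.

    Thin wrapper over :class:`hemotyper.estimator.DiplotypeNearestNeighbor`'s
    solving core: projects the genotype onto the table loci (reference
    fill-in, missingness policy), enumerates chromatid assignments, and
    returns the maximum-parsimony prediction with ranked alternatives.
    """
    observed = select_relevant(genotype, table, missing_policy=missing_policy)
    return predict_observed(
        observed, table, max_het=max_het, weights=weights, keep_ranking=keep_ranking
    )


def predict_system(
    genotype: Genotype,
    tables_by_system: Mapping[str, Sequence[HaplotypeTable]],
    **options,
) -> dict[str, dict[str, Prediction | PredictionFailure]]:
    """One prediction per gene, grouped by blood-group system.

    Multi-gene systems (Rh: RhD and RhCE) get side-by-side per-gene
    predictions with no cross-gene combination — interpreting the joint
    trait is deliberately left to the user.  A failure for one gene is
    recorded as :class:`PredictionFailure` and does not stop the others.
    """
    if not tables_by_system:
        raise ValueError("empty system manifest")
    out: dict[str, dict[str, Prediction | PredictionFailure]] = {}
    for system, tables in tables_by_system.items():
        per_gene: dict[str, Prediction | PredictionFailure] = {}
        for i, table in enumerate(tables):
            gene = table.gene or f"gene{i + 1}"
            if gene in per_gene:  # two tables for one gene symbol: keep both
                gene = f"{gene}.{i + 1}"
            try:
                per_gene[gene] = predict(genotype, table, **options)
            except Exception as exc:  # recorded per gene, others proceed
                per_gene[gene] = PredictionFailure(
                    error=f"{type(exc).__name__}: {exc}", exception=exc
                )
        out[system] = per_gene
    return out
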