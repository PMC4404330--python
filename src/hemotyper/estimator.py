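"""Scikit-learn–style estimator wrapping the phasing/calling core.

``DiplotypeNearestNeighbor`` is a classifier in the sklearn sense: ``fit``
takes the haplotype knowledge (one allele vector per known haplotype plus
its phenotype label) and ``predict`` maps unphased genotypes to unordered
phenotype pairs.  It composes with ``sklearn.base.clone`` and
``get_params``/``set_params``, so the caller can grid over the engine's few
knobs (missingness policy, enumeration cap, per-locus weights) with the
usual model-selection machinery.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import HemotyperError
from .genotype_io import Genotype, ObservedVector, select_relevant
from .knowledge_base import HaplotypeRow, HaplotypeTable, Locus
from .phasing import (
    DEFAULT_MAX_HET,
    Prediction,
    TableIndex,
    predict_observed,
)

__all__ = ["DiplotypeNearestNeighbor"]


class DiplotypeNearestNeighbor(BaseEstimator, ClassifierMixin):
    """Joint phasing + 1-NN phenotype caller as a sklearn estimator.

    Parameters
    ----------
    loci : sequence of Locus, optional
        Genomic loci of the feature columns.  When omitted at ``fit``,
        placeholder loci ``1:1 .. 1:L`` are synthesized, which is convenient
        for purely synthetic experiments.
    reference_alleles : sequence of str, optional
        Per-locus reference-assembly alleles used for fill-in of loci absent
        from a genotype.  Defaults to the first fitted row's alleles (tables
        conventionally list the reference haplotype when no explicit
        reference is given); pass them explicitly for real tables.
    missing_policy : {"exclude-locus", "as-reference", "fail"}
        How missing calls at table loci are handled (see
        :func:`hemotyper.genotype_io.select_relevant`).
    max_het : int
        Cap on heterozygous loci; enumeration is ``2^(M-1)``.
    weights : sequence of float, optional
        Per-locus scoring weights; uniform (all 1) by default, which is the
        method's baseline behaviour.

    Attributes
    ----------
    table_ : HaplotypeTable
        The fitted knowledge base.
    index_ : TableIndex
        Integer-coded table reused across predictions.
    classes_ : ndarray
        Sorted unique phenotype labels.
    """

    def __init__(
        self,
        loci: Sequence[Locus] | None = None,
        reference_alleles: Sequence[str] | None = None,
        missing_policy: str = "exclude-locus",
        max_het: int = DEFAULT_MAX_HET,
        weights: Sequence[float] | None = None,
    ):
        self.loci = loci
        self.reference_alleles = reference_alleles
        self.missing_policy = missing_policy
        self.max_het = max_het
        self.weights = weights

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "DiplotypeNearestNeighbor":
        """Fit on the haplotype knowledge.

        ``X`` is (n_haplotypes, n_loci) allele strings, ``y`` the phenotype
        labels.  There is no optimisation: fitting validates and indexes the
        table.
        """
        X = np.asarray(X, dtype=object)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (haplotypes x loci)")
        y = np.asarray(y, dtype=object)
        if y.shape != (X.shape[0],):
            raise ValueError("y must hold one phenotype label per haplotype row")
        n_loci = X.shape[1]

        if self.loci is not None:
            loci = tuple(self.loci)
            if len(loci) != n_loci:
                raise ValueError("loci length does not match X columns")
        else:
            refs = (
                tuple(str(a).upper() for a in self.reference_alleles)
                if self.reference_alleles is not None
                else tuple(str(a).upper() for a in X[0])
            )
            if len(refs) != n_loci:
                raise ValueError("reference_alleles length does not match X columns")
            loci = tuple(
                Locus(chromosome="1", position=j + 1, reference_allele=refs[j])
                for j in range(n_loci)
            )

        rows = tuple(
            HaplotypeRow(str(label), tuple(str(a).upper() for a in alleles))
            for label, alleles in zip(y, X)
        )
        self.table_ = HaplotypeTable(loci=loci, rows=rows, weights=None)
        self.index_ = TableIndex(self.table_, self.weights)
        self.classes_ = np.array(sorted(set(map(str, y))), dtype=object)
        self.n_features_in_ = n_loci
        return self

    @classmethod
    def from_table(cls, table: HaplotypeTable, **params) -> "DiplotypeNearestNeighbor":
        """Fitted estimator directly from a parsed :class:`HaplotypeTable`."""
        est = cls(loci=table.loci, **params)
        est.table_ = table
        est.index_ = TableIndex(table, est.weights)
        est.classes_ = np.array(sorted(set(table.labels)), dtype=object)
        est.n_features_in_ = table.n_loci
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise HemotyperError("estimator is not fitted; call fit() first")

    # -- prediction --------------------------------------------------------

    def _as_observed(self, sample) -> ObservedVector:
        if isinstance(sample, ObservedVector):
            return sample
        if isinstance(sample, Genotype):
            return select_relevant(
                sample, self.table_, missing_policy=self.missing_policy
            )
        raise TypeError(
            f"samples must be Genotype or ObservedVector, got {type(sample).__name__}"
        )

    def predict_detailed(self, X, *, ranking: bool = True) -> list[Prediction]:
        """Full :class:`Prediction` per sample.

        ``ranking=False`` skips materialising the full configuration ranking
        (ties, optima and scores are unaffected), which matters in large
        batch experiments.
        """
        self._check_fitted()
        return [
            predict_observed(
                self._as_observed(sample),
                self.table_,
                max_het=self.max_het,
                weights=self.weights,
                keep_ranking=ranking,
                _index=self.index_,
            )
            for sample in X
        ]

    def predict(self, X) -> np.ndarray:
        """Unordered phenotype pair per sample, shape (n_samples, 2).

        Pairs are sorted lexicographically; ties and ranking detail are
        available from :meth:`predict_detailed`.
        """
        self._check_fitted()
        out = np.empty((len(X), 2), dtype=object)
        for i, sample in enumerate(X):
            pred = predict_observed(
                self._as_observed(sample),
                self.table_,
                max_het=self.max_het,
                weights=self.weights,
                keep_ranking=False,
                _index=self.index_,
            )
            out[i] = pred.phenotype_pair
        return out

    def score(self, X, y) -> float:
        """Fraction of samples whose unordered phenotype pair is recovered.

        ``y`` is (n_samples, 2) true label pairs, order-insensitive.
        Ambiguous predictions (tied optima disagreeing on the pair) count as
        errors, mirroring how equal-score calls are scored as misses.
        """
        self._check_fitted()
        y = np.asarray(y, dtype=object)
        if y.shape != (len(X), 2):
            raise ValueError("y must be (n_samples, 2) phenotype-label pairs")
        detailed = self.predict_detailed(X)
        correct = 0
        for pred, truth in zip(detailed, y):
            if pred.ambiguous:
                continue
            if pred.phenotype_pair == tuple(sorted(map(str, truth))):
                correct += 1
        return correct / len(X) if len(X) else float("nan")
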