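"""Core engine: enumeration, Hamming scoring, 1-NN calls and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genotype
from helpers import brute_force_optimum, naive_distance, observed_pairs, swap_deduplicated
from hemotyper.errors import EnumerationCapError
from hemotyper.genotype_io import Genotype, select_relevant
from hemotyper.knowledge_base import HaplotypeRow, HaplotypeTable, Locus
from hemotyper.phasing import (
    PredictionFailure,
    enumerate_configurations,
    hamming_distance,
    nearest_row,
    predict,
    predict_system,
    score_configuration,
)
from hemotyper.simulate import planted_genotype, random_table


def fully_het_observed(n_loci):
    """An observed vector heterozygous A/C at every one of n_loci loci."""
    loci = tuple(Locus("1", (j + 1) * 10, "A") for j in range(n_loci))
    table = HaplotypeTable(loci=loci, rows=(HaplotypeRow("REF", ("A",) * n_loci),))
    genotype = make_genotype([("1", (j + 1) * 10, "A", "C") for j in range(n_loci)])
    return select_relevant(genotype, table)


class TestHammingDistance:
    def test_demo_table_counts(self, abo_table):
        a101, a102, o02, b101 = abo_table.rows
        assert hamming_distance(a101.alleles, a102) == 1
        assert hamming_distance(o02.alleles, b101) == 2  # one indel + one SNV
        assert hamming_distance(a102.alleles, a102) == 0

    def test_indel_mismatch_costs_one_like_a_substitution(self):
        assert hamming_distance(("GG", "C"), ("G", "C")) == 1

    def test_active_loci_mask_excludes_positions(self):
        assert hamming_distance(("A", "C"), ("T", "G"), active_loci=[1]) == 1

    def test_weights_scale_each_mismatch(self):
        d = hamming_distance(("A", "C"), ("T", "G"), weights=[0.5, 2.0])
        assert d == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance(("A",), ("A", "C"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms_under_unit_weights(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        bases = np.array(list("ACGT"))
        x, y, z = (tuple(bases[rng.integers(4, size=n)]) for _ in range(3))
        assert hamming_distance(x, y) == hamming_distance(y, x)
        assert hamming_distance(x, y) == naive_distance(x, y)
        assert hamming_distance(x, z) <= hamming_distance(x, y) + hamming_distance(y, z)
        assert (hamming_distance(x, y) == 0) == (x == y)


class TestNearestRow:
    def test_exact_matches_hit_their_rows(self, abo_table):
        call = nearest_row(("GG", "T", "G"), abo_table)
        assert (call.phenotype, call.distance) == ("A102", 0)
        call = nearest_row(("G", "C", "G"), abo_table)
        assert (call.phenotype, call.distance) == ("O02", 0)

    def test_tie_keeps_table_order_and_lists_all(self, abo_table):
        # (G, T, G) is 1 away from A102 (GG) and from O02 (T≠C).
        call = nearest_row(("G", "T", "G"), abo_table)
        assert call.distance == 1
        assert call.tied_rows == ("A102", "O02")
        assert call.phenotype == "A102"
        assert call.phenotype in call.tied_rows


class TestEnumeration:
    @pytest.mark.parametrize("m", range(0, 9))
    def test_count_and_content_match_swap_dedup_oracle(self, m):
        if m == 0:
            observed = select_relevant(
                Genotype(),
                HaplotypeTable(
                    loci=(Locus("1", 10, "A"),), rows=(HaplotypeRow("REF", ("A",)),)
                ),
            )
        else:
            observed = fully_het_observed(m)
        configs = enumerate_configurations(observed)
        assert len(configs) == max(1, 2 ** (m - 1))
        ours = {tuple(sorted([c.vector_a, c.vector_b])) for c in configs}
        oracle = swap_deduplicated(list(zip(observed.states_a, observed.states_b)))
        assert ours == oracle
        assert len(ours) == len(configs)  # no duplicates, no swapped twins

    def test_first_het_locus_assignment_is_canonical(self):
        observed = fully_het_observed(3)
        for config in enumerate_configurations(observed):
            assert config.assignment_mask[0] is True
            assert config.vector_a[0] == observed.states_a[0]

    def test_het_cap_raises_with_advice(self):
        observed = fully_het_observed(6)
        with pytest.raises(EnumerationCapError, match="cap"):
            enumerate_configurations(observed, max_het=5)

    def test_hom_loci_identical_on_both_chromatids(self, abo_table, ab_diplotype_genotype):
        observed = select_relevant(ab_diplotype_genotype, abo_table)
        for config in enumerate_configurations(observed):
            assert config.vector_a[0] == config.vector_b[0] == "GG"
            assert {config.vector_a[1], config.vector_b[1]} == {"C", "T"}


class TestScoreConfiguration:
    def test_sum_of_chromatid_distances(self, abo_table, ab_diplotype_genotype):
        observed = select_relevant(ab_diplotype_genotype, abo_table)
        configs = enumerate_configurations(observed)
        scores = sorted(score_configuration(c, abo_table)[2] for c in configs)
        assert scores == [0, 1]  # concentrated split is optimal, the other costs 1

    def test_splitting_a_known_haplotype_scores_worse(self, abo_table):
        genotype = planted_genotype(abo_table, 2, 3)  # O02 (reference) x B101
        observed = select_relevant(genotype, abo_table)
        best = {}
        for config in enumerate_configurations(observed):
            _, _, score = score_configuration(config, abo_table)
            best[config.assignment_mask] = score
        concentrated = min(best.values())
        assert concentrated == 0
        assert sorted(best.values())[1] > concentrated


class TestPredict:
    def test_planted_diplotype_recovered_at_zero(self, abo_table, ab_diplotype_genotype):
        pred = predict(ab_diplotype_genotype, abo_table)
        assert pred.phenotype_pair == ("A102", "B101")
        assert pred.total_score == 0
        assert not pred.ambiguous
        assert len(pred.best_configurations) == 1

    def test_empty_genotype_calls_reference_row_twice(self, abo_table):
        pred = predict(Genotype(), abo_table)
        assert pred.phenotype_pair == ("O02", "O02")
        assert pred.total_score == 0
        assert pred.call_a.distance == 0 == pred.call_b.distance

    def test_ranking_is_sorted_and_exhaustive(self, abo_table, ab_diplotype_genotype):
        pred = predict(ab_diplotype_genotype, abo_table)
        scores = [r.total_score for r in pred.ranking]
        assert scores == sorted(scores)
        assert len(pred.ranking) == 2  # M=2 -> 2^(M-1)
        assert pred.ranking[0].total_score == pred.total_score

    def test_swap_symmetry_of_input_allele_order(self, abo_table):
        forward = make_genotype(
            [("9", 136132908, "GG", "GG"), ("9", 136131650, "C", "T"),
             ("9", 136131414, "G", "A")]
        )
        flipped = make_genotype(
            [("9", 136132908, "GG", "GG"), ("9", 136131650, "T", "C"),
             ("9", 136131414, "A", "G")]
        )
        pa, pb = predict(forward, abo_table), predict(flipped, abo_table)
        assert pa.phenotype_pair == pb.phenotype_pair
        assert pa.total_score == pb.total_score

    def test_ambiguity_flagged_on_row_label_collision(self):
        loci = tuple(Locus("1", (j + 1) * 10, "A") for j in range(3))
        table = HaplotypeTable(
            loci=loci,
            rows=(
                HaplotypeRow("REF", ("A", "A", "A")),
                HaplotypeRow("X", ("C", "C", "A")),
                HaplotypeRow("Y", ("C", "C", "A")),
            ),
        )
        pred = predict(planted_genotype(table, 0, 1), table)
        assert pred.ambiguous
        assert {("REF", "X"), ("REF", "Y")} <= set(pred.phenotype_pairs)

    def test_missing_locus_excluded_from_all_rows(self, abo_table):
        genotype = make_genotype(
            [("9", 136132908, "-", "-"), ("9", 136131650, "C", "T")]
        )
        pred = predict(genotype, abo_table)
        # with locus 1 dropped, A101 and O02 collapse: the A102/x optimum ties
        assert pred.total_score == 0
        assert pred.n_missing == 1

    def test_monotone_in_table_rows(self, abo_table, ab_diplotype_genotype):
        smaller = HaplotypeTable(
            loci=abo_table.loci,
            rows=abo_table.rows[:2],  # drop O02 and B101
            system=abo_table.system,
        )
        assert (
            predict(ab_diplotype_genotype, smaller).total_score
            >= predict(ab_diplotype_genotype, abo_table).total_score
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_optimum_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(int(rng.integers(2, 10)), int(rng.integers(2, 7)), rng)
        i, j = rng.integers(len(table.rows), size=2)
        genotype = planted_genotype(table, int(i), int(j))
        pred = predict(genotype, table)
        score, pairs = brute_force_optimum(observed_pairs(genotype, table), table)
        assert pred.total_score == score
        assert pred.phenotype_pairs == frozenset(pairs)
        assert pred.ambiguous == (len(pairs) > 1)


class TestPredictSystem:
    def test_multi_gene_system_reports_side_by_side(self, abo_table, ab_diplotype_genotype):
        rhd = HaplotypeTable(
            loci=abo_table.loci, rows=abo_table.rows, system="Rh", gene="RHD"
        )
        rhce = HaplotypeTable(
            loci=abo_table.loci, rows=abo_table.rows, system="Rh", gene="RHCE"
        )
        out = predict_system(
            ab_diplotype_genotype, {"ABO": [abo_table], "Rh": [rhd, rhce]}
        )
        assert sorted(out) == ["ABO", "Rh"]
        assert sorted(out["Rh"]) == ["RHCE", "RHD"]
        assert out["Rh"]["RHD"].phenotype_pair == ("A102", "B101")

    def test_per_gene_failure_does_not_stop_others(self, abo_table, ab_diplotype_genotype):
        bad = HaplotypeTable(
            loci=tuple(
                Locus(l.chromosome, l.position, l.reference_allele, assembly="hg38")
                for l in abo_table.loci
            ),
            rows=abo_table.rows,
            gene="BAD",
        )
        out = predict_system(ab_diplotype_genotype, {"S": [bad, abo_table]})
        assert isinstance(out["S"]["BAD"], PredictionFailure)
        assert "Assembly" in out["S"]["BAD"].error
        assert out["S"]["ABO"].total_score == 0

    def test_empty_manifest_rejected(self, ab_diplotype_genotype):
        with pytest.raises(ValueError):
            predict_system(ab_diplotype_genotype, {})
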