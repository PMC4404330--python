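"""Independent brute-force oracles for the phasing engine.

Everything here is deliberately naive pure Python over allele strings —
no shared code with the package's vectorized solver — so it can stand as an
independent check of enumeration counts, distances and optima.
"""

from itertools import product


def naive_distance(vector, alleles, active=None, weights=None):
    """Hamming distance by direct per-locus string comparison."""
    if active is None:
        active = [True] * len(alleles)
    if weights is None:
        weights = [1] * len(alleles)
    total = 0
    for v, a, act, w in zip(vector, alleles, active, weights):
        if act and v != a:
            total += w
    return total


def all_labelings(pairs):
    """Every one of the 2^M chromatid labelings of the heterozygous loci."""
    het = [i for i, (a, b) in enumerate(pairs) if a != b]
    base_a = [a for a, _ in pairs]
    base_b = [b for _, b in pairs]
    out = []
    for bits in product((0, 1), repeat=len(het)):
        va, vb = list(base_a), list(base_b)
        for bit, i in zip(bits, het):
            if bit:
                va[i], vb[i] = vb[i], va[i]
        out.append((tuple(va), tuple(vb)))
    return out


def swap_deduplicated(pairs):
    """Distinct labelings after identifying (A,B) with (B,A)."""
    return {tuple(sorted([va, vb])) for va, vb in all_labelings(pairs)}


def brute_force_optimum(pairs, table, active=None, weights=None):
    """Minimize summed per-chromatid 1-NN distance over all 2^M labelings.

    Returns ``(best_score, phenotype_pairs)`` where ``phenotype_pairs`` is
    the set of unordered label pairs over every optimal labeling, expanded
    across nearest-row ties within each chromatid.
    """
    rows = [(r.phenotype, r.alleles) for r in table.rows]

    def nearest(vector):
        distances = [naive_distance(vector, alleles, active, weights) for _, alleles in rows]
        dmin = min(distances)
        return dmin, [label for (label, _), d in zip(rows, distances) if d == dmin]

    best_score = None
    optima = []
    for va, vb in all_labelings(pairs):
        da, tied_a = nearest(va)
        db, tied_b = nearest(vb)
        score = da + db
        if best_score is None or score < best_score:
            best_score = score
            optima = [(tied_a, tied_b)]
        elif score == best_score:
            optima.append((tied_a, tied_b))
    phenotype_pairs = {
        tuple(sorted((a, b)))
        for tied_a, tied_b in optima
        for a in tied_a
        for b in tied_b
    }
    return best_score, phenotype_pairs


def observed_pairs(genotype, table):
    """Reference-filled per-locus allele pairs, independent of the package."""
    out = []
    for locus in table.loci:
        rec = genotype.get(locus.chromosome, locus.position)
        if rec is None:
            out.append((locus.reference_allele, locus.reference_allele))
        else:
            out.append((rec.allele_a, rec.allele_b))
    return out
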