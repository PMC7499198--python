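"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's index structures and closed forms:
points are compared against every interval by linear scan, the Fisher p is
an exact integer enumeration, and the chi-square p is checked by
permutation sampling of the table under fixed margins.
"""

from math import comb

import numpy as np


def brute_locate(genes, chrom, pos):
    """Linear-scan point location over all genes and exon intervals."""
    exon_genes, span_genes = [], []
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.span[0] <= pos < g.span[1]:
            span_genes.append(g.gene_id)
            for xs, xe in g.exons:
                if xs <= pos < xe:
                    exon_genes.append(g.gene_id)
                    break
    if exon_genes:
        return "exon", sorted(exon_genes)
    if span_genes:
        return "intron", sorted(span_genes)
    return "intergenic", []


def brute_nearest(genes, chrom, pos):
    """Exhaustive nearest-gene scan; ties by span start then gene_id."""
    best = None
    for g in genes:
        if g.chrom != chrom:
            continue
        s, e = g.span
        d = 0 if s <= pos < e else (s - pos if pos < s else pos - e + 1)
        key = (d, s, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g)
    if best is None:
        raise LookupError(chrom)
    return best[1], best[0][0]


def brute_classify(genes, sv):
    """Enumerate every exon/intron interval relation for one SV.

    Returns a sorted list of (region_class, gene_id, distance) triples,
    matching the package's classification contract.
    """
    if sv.sv_type == "BND":
        cls, hit = brute_locate(genes, sv.chrom, sv.start)
        if cls == "exon":
            return sorted(("exonic", g, 0) for g in hit)
        if cls == "intron":
            return sorted(("intronic", g, 0) for g in hit)
        g, d = brute_nearest(genes, sv.chrom, sv.start)
        return [("intergenic", g.gene_id, d)]
    s, e = sv.start, sv.end
    p1, p2 = s, e - 1
    out = []
    overlapped = [g for g in genes
                  if g.chrom == sv.chrom and g.span[0] < e and s < g.span[1]]
    if not overlapped:
        mid = (s + e) // 2
        g, d = brute_nearest(genes, sv.chrom, mid)
        return [("intergenic", g.gene_id, d)]
    for g in overlapped:
        def in_exon(p):
            return any(xs <= p < xe for xs, xe in g.exons)

        def in_gene(p):
            return g.span[0] <= p < g.span[1]

        edges = [x for iv in g.exons for x in iv]
        crossed = any(s < x < e for x in edges)
        if in_exon(p1) and in_exon(p2):
            out.append(("exonic", g.gene_id, 0))
            if crossed:
                out.append(("splicing", g.gene_id, 0))
        elif crossed:
            out.append(("splicing", g.gene_id, 0))
        elif in_gene(p1) and in_gene(p2):
            out.append(("intronic", g.gene_id, 0))
        else:
            out.append(("splicing", g.gene_id, 0))
    return sorted(out)


def fisher_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration.

    With margins fixed, every table in the conditional family shares the
    denominator C(N, a+c), so probabilities compare exactly as the integer
    numerators C(r1, k) * C(r2, a+c-k).
    """
    r1, r2, c1 = a + b, c + d, a + c
    num_obs = comb(r1, a) * comb(r2, c)
    total = 0
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        nk = comb(r1, k) * comb(r2, c1 - k)
        total += nk
        if nk <= num_obs:
            acc += nk
    return acc / total


def permutation_chi2_p(a, b, c, d, n_perm=100_000, seed=0, strict=False):
    """Monte-Carlo permutation p for the Pearson chi-square statistic.

    Shuffling case/control labels with margins fixed makes the case-carrier
    count hypergeometric; the p-value is the fraction of permuted tables
    with a statistic at least as large as observed (strictly larger with
    ``strict=True``, giving the other side of the discrete step).
    """
    rng = np.random.default_rng(seed)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def stat(av):
        av = np.asarray(av, dtype=float)
        bv, cv, dv = r1 - av, c1 - av, r2 - (c1 - av)
        num = n * (av * dv - bv * cv) ** 2
        den = r1 * r2 * c1 * (n - c1)
        return num / den

    obs = stat(np.array([a]))[0]
    draws = rng.hypergeometric(r1, r2, c1, size=n_perm)
    if strict:
        return float((stat(draws) > obs + 1e-12).mean())
    return float((stat(draws) >= obs - 1e-12).mean())
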