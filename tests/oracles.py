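"""Independent brute-force oracles used to check the implementation.

Everything here is written as directly as possible (full scans, per-site
loops, explicit pair enumeration) and shares no code path with the package
internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from polyweave import _seq


def bruteforce_map(read_codes, reference, max_mismatch, masked_by_chrom):
    """All-positions scan over both strands under the unique-best rule.

    Returns (chrom, start, strand, mismatches) or None.
    """
    # one hit per (chrom, start) location, minimized over the two strands
    by_loc = {}
    for strand, query in (("+", read_codes),
                          ("-", _seq.revcomp(read_codes))):
        L = query.shape[0]
        for chrom, ref in reference.items():
            masked = set(masked_by_chrom.get(chrom, []))
            for start in range(ref.shape[0] - L + 1):
                mm = 0
                for j in range(L):
                    if start + j in masked:
                        continue
                    if query[j] != ref[start + j]:
                        mm += 1
                prev = by_loc.get((chrom, start))
                if prev is None or mm < prev[0]:
                    by_loc[(chrom, start)] = (mm, strand)
    if not by_loc:
        return None
    best = min(mm for mm, _ in by_loc.values())
    if best > max_mismatch:
        return None
    winners = [(c, s, strand) for (c, s), (mm, strand) in by_loc.items()
               if mm == best]
    if len(winners) != 1:
        return None
    chrom, start, strand = winners[0]
    return chrom, start, strand, best


def bruteforce_genotype(counts, min_allele_cov, min_freq):
    """Per-site genotype call by explicit threshold checks."""
    depth = sum(counts)
    alleles = []
    for b in range(4):
        if depth > 0 and counts[b] >= min_allele_cov and \
                counts[b] / depth >= min_freq:
            alleles.append(b)
    if not alleles:
        return "."
    if len(alleles) == 1:
        return _seq.BASES[alleles[0]]
    if len(alleles) == 2:
        return f"{_seq.BASES[alleles[0]]}/{_seq.BASES[alleles[1]]}"
    return "amb"


def bruteforce_allele_snps(values, maf_filter):
    """Row-wise allele-SNP filter over a (sites, taxa) call-string array.

    Returns the list of retained row indices with their MAFs.
    """
    out = []
    for i, row in enumerate(values):
        calls = [c for c in row if c in "ACGT"]
        if not calls:
            continue
        uniq = sorted(set(calls))
        if len(uniq) < 2:
            continue
        top = max(calls.count(u) for u in uniq)
        maf = (len(calls) - top) / len(calls)
        if maf >= maf_filter - 1e-12:
            out.append((i, maf))
    return out


def bruteforce_diversity(values):
    """Mean over pairs of differing/co-covered polymorphic sites."""
    n_sites, n_taxa = values.shape
    poly = []
    for i in range(n_sites):
        calls = [c for c in values[i] if c in "ACGT"]
        if len(set(calls)) >= 2:
            poly.append(i)
    if not poly:
        return 0.0
    ratios = []
    for a, b in itertools.combinations(range(n_taxa), 2):
        co = [i for i in poly
              if values[i, a] in "ACGT" and values[i, b] in "ACGT"]
        if not co:
            continue
        diff = sum(values[i, a] != values[i, b] for i in co)
        ratios.append(diff / len(co))
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


def bruteforce_distance(values, taxa):
    """All-pairs recount of the SNP distance matrix."""
    n = len(taxa)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            co = [i for i in range(values.shape[0])
                  if values[i, a] in "ACGT" and values[i, b] in "ACGT"]
            d = sum(values[i, a] != values[i, b] for i in co) / len(co)
            D[a, b] = D[b, a] = d
    return D


def least_squares_quartet(dm):
    """Best of the three quartet topologies by ordinary least squares.

    For four taxa 0..3 and each pairing ((i,j),(k,l)), fit the five branch
    lengths minimizing squared error to the six pairwise distances and
    return the pairing with the smallest residual.
    """
    import numpy.linalg as la

    pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    best = None
    for (i, j), (k, l) in pairs:
        # branches: e_i, e_j, e_k, e_l, internal m
        rows = []
        y = []
        for a, b in itertools.combinations(range(4), 2):
            row = [0.0] * 5
            row[a] = 1.0
            row[b] = 1.0
            same_side = {a, b} in ({i, j}, {k, l})
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            y.append(dm[a, b])
        beta, res, *_ = la.lstsq(np.array(rows), np.array(y), rcond=None)
        rss = float(np.sum((np.array(rows) @ beta - np.array(y)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, ((i, j), (k, l)))
    return best[1]
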