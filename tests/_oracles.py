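"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain-Python loops
and the ``math`` module only, transcribed directly from first principles,
so they can arbitrate the vectorized implementations.
"""

import math


def wc_fst_oracle(pop_genotypes, average="mean_of_ratios"):
    """Weir & Cockerham (1984) mean per-allele FST, transcribed line by line.

    ``pop_genotypes``: list (one entry per population) of lists of
    2-tuples, each tuple one diploid individual's two alleles (any
    hashable allele labels).
    """
    pops = [genos for genos in pop_genotypes if len(genos) > 0]
    r = len(pops)
    if r < 2:
        return float("nan")
    alleles = sorted({a for genos in pops for g in genos for a in g})
    n = [len(genos) for genos in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    ratios = []
    total_a = 0.0
    total_abc = 0.0
    for allele in alleles:
        p = []
        h = []
        for genos in pops:
            copies = 0
            hets = 0
            for g in genos:
                copies += (g[0] == allele) + (g[1] == allele)
                hets += (g[0] == allele) != (g[1] == allele)
            p.append(copies / (2 * len(genos)))
            h.append(hets / len(genos))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        if a + b + c != 0.0:
            ratios.append(a / (a + b + c))
            total_a += a
            total_abc += a + b + c
    if not ratios:
        return float("nan")
    if average == "ratio_of_means":
        return total_a / total_abc
    return sum(ratios) / len(ratios)


def informativeness_oracle(rows):
    """Term-by-term evaluation of the assignment-informativeness sum."""
    k = len(rows)
    n = len(rows[0])
    total = 0.0
    for j in range(n):
        pbar = sum(rows[i][j] for i in range(k)) / k
        term = -pbar * math.log(pbar) if pbar > 0 else 0.0
        for i in range(k):
            pij = rows[i][j]
            if pij > 0:
                term += (pij / k) * math.log(pij)
        total += term
    return total


def amplicon_bounds_oracle(first, last, delta, min_length, chrom_length):
    """Step-wise amplicon interval construction.

    Extends base by base: delta on each side, then one base at a time
    (right first) until min_length is reached, then resolves boundary
    clipping by shifting one base at a time toward the open side.
    """
    start = first - delta
    end = last + delta
    left_added = right_added = 0
    while end - start + 1 < min_length:
        if right_added <= left_added:
            end += 1
            right_added += 1
        else:
            start -= 1
            left_added += 1
    while start < 1:
        start += 1
        if end < chrom_length:
            end += 1
    while end > chrom_length:
        end -= 1
        if start > 1:
            start -= 1
    return start, end


def closest_gap_oracle(spans):
    """All-pairs closest non-overlapping gap for 1-based inclusive spans.

    Returns a list parallel to ``spans`` (all assumed on one chromosome);
    ``None`` where no non-overlapping partner exists.
    """
    result = []
    for i, (s1, e1) in enumerate(spans):
        best = None
        for j, (s2, e2) in enumerate(spans):
            if i == j:
                continue
            if s2 <= e1 and s1 <= e2:
                continue
            gap = (s2 - e1 - 1) if s2 > e1 else (s1 - e2 - 1)
            if best is None or gap < best:
                best = gap
        result.append(best)
    return result
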