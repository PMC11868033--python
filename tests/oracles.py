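"""Independent brute-force oracles used to validate the estimators.

Everything here is written from first principles (explicit loops, factorial
arithmetic, exhaustive enumeration) and deliberately shares no code with
the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -9


def wc_theta_oracle(pops: list[np.ndarray]) -> tuple[float, float, float]:
    """Textbook Weir-Cockerham (1984) estimators by direct transcription.

    ``pops``: list of (n_i, L) dosage arrays, no missing data handling
    beyond skipping MISSING entries.  Returns multi-locus (theta, f, F) as
    ratios of component sums.
    """
    L = pops[0].shape[1]
    A = B = C = 0.0
    for l in range(L):
        samples = []
        for d in pops:
            col = [g for g in d[:, l] if g != MISSING]
            if len(col) >= 2:
                samples.append(col)
        r = len(samples)
        if r < 2:
            continue
        n_i = [len(s) for s in samples]
        p_i = [sum(s) / (2 * n) for s, n in zip(samples, n_i)]
        h_i = [sum(1 for g in s if g == 1) / n for s, n in zip(samples, n_i)]
        nbar = sum(n_i) / r
        nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    tot = A + B + C
    return A / tot, 1 - C / (B + C), 1 - C / tot


def nei_da_oracle(x: list[float], y: list[float]) -> float:
    """Da between two frequency vectors, explicit loop over loci/alleles."""
    acc = 0.0
    for xi, yi in zip(x, y):
        acc += math.sqrt(xi * yi) + math.sqrt((1 - xi) * (1 - yi))
    return 1.0 - acc / len(x)


def hwe_exact_oracle(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact HWE p by multinomial enumeration with factorial arithmetic."""
    n = n_het + n_hom_ref + n_hom_alt
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    if n == 0 or n_ref == 0 or n_alt == 0:
        return 1.0
    rare = min(n_ref, n_alt)

    def weight(h: int) -> float:
        hr = (n_ref - h) // 2
        ha = (n_alt - h) // 2
        return (2 ** h) * math.factorial(n) / (
            math.factorial(hr) * math.factorial(h) * math.factorial(ha)
        )

    support = [h for h in range(rare % 2, rare + 1, 2)]
    weights = {h: weight(h) for h in support}
    total = sum(weights.values())
    obs = weights[n_het]
    return min(1.0, sum(w for w in weights.values() if w <= obs * (1 + 1e-12)) / total)


def chi2_oracle(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square by hand: sum (O-E)^2/E with E from the margins."""
    table = np.asarray(table, float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r via covariance / stdev computed with plain sums."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def rarefaction_oracle(counts: list[int], g: int) -> float:
    """Expected allele count in subsamples of size g, by exhaustive
    enumeration of all C(total, g) subsets of the gene copies."""
    copies = []
    for allele, c in enumerate(counts):
        copies.extend([allele] * c)
    total = 0
    n_sub = 0
    for sub in itertools.combinations(range(len(copies)), g):
        total += len({copies[i] for i in sub})
        n_sub += 1
    return total / n_sub


def wilcoxon_exact_oracle(diff: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = [x for x in diff if x != 0]
    n = len(d)
    ranks = {}
    srt = sorted(range(n), key=lambda i: abs(d[i]))
    # midranks for ties
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(d[srt[j + 1]]) == abs(d[srt[i]]):
            j += 1
        for k in range(i, j + 1):
            ranks[srt[k]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = min(sum(ranks[i] for i in range(n) if d[i] > 0),
                sum(ranks[i] for i in range(n) if d[i] < 0))
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = min(sum(ranks[i] for i in range(n) if signs[i]),
                sum(ranks[i] for i in range(n) if not signs[i]))
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2 ** n
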