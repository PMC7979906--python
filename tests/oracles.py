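"""Brute-force / closed-form oracles, independent of the library code paths.

Everything here is written as directly as possible — explicit loops over
samples and sites — so it can serve as a cross-check for the vectorised
implementations in radpop.
"""

import itertools

import numpy as np


def ibs_distance_pair(gi, gj):
    """Mean IBS distance over co-called sites, one pair, by explicit loop."""
    num, den = 0.0, 0
    for a, b in zip(gi, gj):
        if a < 0 or b < 0:
            continue
        num += 1.0 - abs(a - b) / 2.0
        den += 1
    if den == 0:
        raise ValueError("no co-called sites")
    return 1.0 - num / den


def conserved_het_pair(gi, gj):
    """(n_conserved, n_denominator) by explicit enumeration."""
    conserved = denom = 0
    for a, b in zip(gi, gj):
        if a < 0 or b < 0:
            continue
        if a == 1 or b == 1:
            denom += 1
            if a == 1 and b == 1:
                conserved += 1
    return conserved, denom


def upgma(d):
    """O(N^3) average-linkage clustering on a dense distance matrix.

    Returns a list of merges (members_left, members_right, height) with
    members given as frozensets of original leaf indices, in merge order.
    """
    d = np.asarray(d, dtype=float)
    clusters = {i: frozenset([i]) for i in range(len(d))}
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            ci, cj = clusters[i], clusters[j]
            h = np.mean([d[a, b] for a in ci for b in cj])
            if best is None or h < best[0] - 1e-12:
                best = (h, i, j)
        h, i, j = best
        merges.append((clusters[i], clusters[j], h))
        clusters[min(i, j)] = clusters[i] | clusters[j]
        del clusters[max(i, j)]
    return merges


def f3_single_block(freq_a, freq_b, freq_c, n_ind_a):
    """f3 estimate on a tiny frequency table by explicit per-site sum.

    Applies the same finite-sample correction as the implementation:
    subtract a(1-a)/(n_alleles - 1) per site.
    """
    total, n = 0.0, 0
    for a, b, c, ni in zip(freq_a, freq_b, freq_c, n_ind_a):
        na = 2 * ni
        total += (a - b) * (a - c) - a * (1 - a) / (na - 1)
        n += 1
    return total / n


def delete_one_jackknife_se(values):
    """Classic delete-one jackknife SE of the mean, explicit loop."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    loo = np.array([np.delete(values, i).mean() for i in range(n)])
    return np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum())


def wc_theta(genotypes1, genotypes2):
    """Weir–Cockerham theta for two populations, explicit per-site loop.

    ``genotypes1/2``: (n_ind, n_sites) arrays of 0/1/2 codes, -1 missing.
    """
    sum_a = sum_abc = 0.0
    for l in range(genotypes1.shape[1]):
        g1 = genotypes1[:, l]
        g2 = genotypes2[:, l]
        g1, g2 = g1[g1 >= 0], g2[g2 >= 0]
        n1, n2 = len(g1), len(g2)
        if n1 < 1 or n2 < 1 or (n1 + n2) / 2 <= 1:
            continue
        p1, p2 = g1.sum() / (2 * n1), g2.sum() / (2 * n2)
        h1, h2 = (g1 == 1).mean(), (g2 == 1).mean()
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def balding_nichols_fst_oracle(f1, f2, n_per_pop, n_sites, rng, maf_range=(0.05, 0.5)):
    """Monte-Carlo expectation of Weir–Cockerham Fst for two drifted pops.

    Draws ancestral frequencies, Balding–Nichols population frequencies and
    Hardy–Weinberg genotypes at a large number of sites, then computes theta
    with the explicit-loop estimator above.
    """
    p = rng.uniform(*maf_range, size=n_sites)
    flip = rng.random(n_sites) < 0.5
    p = np.where(flip, 1 - p, p)

    def pop_freq(f):
        if f == 0:
            return p.copy()
        s = (1 - f) / f
        return rng.beta(p * s, (1 - p) * s)

    q1, q2 = pop_freq(f1), pop_freq(f2)
    g1 = rng.binomial(1, q1, size=(n_per_pop, n_sites)) + rng.binomial(
        1, q1, size=(n_per_pop, n_sites)
    )
    g2 = rng.binomial(1, q2, size=(n_per_pop, n_sites)) + rng.binomial(
        1, q2, size=(n_per_pop, n_sites)
    )
    return wc_theta(g1, g2)
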