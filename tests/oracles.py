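"""Independent brute-force oracles used only by the test suite."""

import itertools

import numpy as np


def enumerate_gamete_distribution(hap_row, segmap, junction_r):
    """Exact gamete mean and variance by enumerating all 2^S phase vectors.

    Junction flips are treated as independent with probability
    ``junction_r[s]`` between segments s and s+1 on the same chromosome;
    the first segment of every chromosome is a fair coin.  Valid for the
    Poisson and map crossover laws.
    """
    h = np.asarray(hap_row, dtype=float)
    S = h.shape[0]
    chrom_start = np.zeros(S, dtype=bool)
    chrom_start[0] = True
    chrom_start[1:] = np.diff(segmap.chrom) != 0
    mean = 0.0
    m2 = 0.0
    for phases in itertools.product((0, 1), repeat=S):
        p = 1.0
        for s in range(S):
            if chrom_start[s]:
                p *= 0.5
            else:
                r = junction_r[s - 1]
                p *= r if phases[s] != phases[s - 1] else 1.0 - r
        v = sum(h[s, phases[s]] for s in range(S))
        mean += p * v
        m2 += p * v * v
    return mean, m2 - mean * mean


def tabular_a_matrix(ped):
    """Full additive relationship matrix by the tabular method."""
    n = ped.n_animals
    A = np.zeros((n, n))
    for i in ped.topological_order:
        s, d = ped.sire[i], ped.dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in ped.topological_order:
            if j == i:
                break
            v = 0.0
            if s >= 0:
                v += 0.5 * A[s, j]
            if d >= 0:
                v += 0.5 * A[d, j]
            A[i, j] = A[j, i] = v
    return A


def two_pass_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def mean_sd(values):
    """Textbook two-pass mean and N-1 standard deviation."""
    v = np.asarray(values, dtype=float)
    m = v.sum() / v.size
    return m, float(np.sqrt(((v - m) ** 2).sum() / (v.size - 1)))
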