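"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (loops over samples,
pairs, and enumerations), deliberately avoiding the package's vectorized
code paths so the two can disagree.
"""

import itertools

import numpy as np


def theta_pi_pairwise(alleles: np.ndarray) -> float:
    """Mean pairwise mismatch summed over sites, via an explicit pair loop.

    ``alleles``: (sites, samples), -1 missing. Sites with <2 calls skipped.
    """
    total = 0.0
    for row in alleles:
        calls = row[row >= 0]
        n = len(calls)
        if n < 2:
            continue
        mism = 0
        npairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                npairs += 1
                mism += int(calls[i] != calls[j])
        total += mism / npairs
    return total


def watterson(alleles: np.ndarray, n: int) -> float:
    s = 0
    for row in alleles:
        calls = row[row >= 0]
        if len(calls) >= 2 and 0 < calls.sum() < len(calls):
            s += 1
    a1 = sum(1.0 / i for i in range(1, n))
    return s / a1


def tajima_d_direct(alleles: np.ndarray, n: int) -> float:
    """Tajima's D computed from scratch with explicit constant sums."""
    pi = theta_pi_pairwise(alleles)
    s = 0
    for row in alleles:
        calls = row[row >= 0]
        if len(calls) >= 2 and 0 < calls.sum() < len(calls):
            s += 1
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def hudson_fst_site(c1: int, n1: int, c2: int, n2: int):
    p1, p2 = c1 / n1, c2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def dxy_interpair(a1: np.ndarray, a2: np.ndarray, window_bp: int) -> float:
    """Mean per-bp mismatch over all inter-group sample pairs.

    ``a1``: (sites, n1) group-1 alleles without missing data; ``a2`` same
    for group 2.
    """
    n1, n2 = a1.shape[1], a2.shape[1]
    total = 0.0
    for i in range(n1):
        for j in range(n2):
            total += np.sum(a1[:, i] != a2[:, j]) / window_bp
    return total / (n1 * n2)


def ld_2x2(x: np.ndarray, y: np.ndarray):
    """r² and D' from the explicit 2x2 haplotype table."""
    n = len(x)
    n11 = sum(1 for i in range(n) if x[i] == 1 and y[i] == 1)
    pa = sum(x) / n
    pb = sum(y) / n
    pab = n11 / n
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return r2, 0.0
    return r2, abs(d) / dmax


def vst_direct(cn_row, idx1, idx2) -> float:
    x1 = [cn_row[i] for i in idx1]
    x2 = [cn_row[i] for i in idx2]
    xall = x1 + x2
    def var(v):
        m = sum(v) / len(v)
        return sum((u - m) ** 2 for u in v) / (len(v) - 1)
    vt = var(xall)
    if vt == 0:
        return float("nan")
    vs = (var(x1) * len(x1) + var(x2) * len(x2)) / (len(x1) + len(x2))
    return (vt - vs) / vt


def pic_direct(cn_row) -> float:
    vals = list(cn_row)
    ps = [vals.count(v) / len(vals) for v in sorted(set(vals))]
    return 1.0 - sum(p * p for p in ps)


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values via the explicit step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def clr_site_prob(j: int, n: int, dist: float, alpha: float, q: np.ndarray,
                  folded: bool) -> float:
    """Sweep-model site probability by explicit enumeration.

    ``q``: background probabilities for derived counts 1..n-1 (index 0 is
    class 1). Enumerates the number of escaping lineages k (binomial), the
    background sample of size k+1 (explicit hypergeometric sums), and the
    uniformly chosen sweep-ancestor lineage. Conditioned on polymorphism.
    """
    from math import comb, exp

    pe = 1 - exp(-alpha * dist)
    pe = min(max(pe, 1e-12), 1 - 1e-12)
    full = np.zeros(n + 1)  # probability of final derived count 0..n
    for k in range(n + 1):
        wk = comb(n, k) * pe ** k * (1 - pe) ** (n - k)
        if k == n:
            for jj in range(1, n):
                full[jj] += wk * q[jj - 1]
            continue
        size = k + 1
        for jj in range(1, n):   # true background class
            for m in range(0, size + 1):  # derived among the k+1 draws
                hyp = comb(jj, m) * comb(n - jj, size - m) / comb(n, size)
                if hyp == 0:
                    continue
                pr = wk * q[jj - 1] * hyp
                # ancestor derived with prob m/size
                if m > 0:
                    full[m - 1 + n - k] += pr * (m / size)
                full[m] += pr * (1 - m / size)
    norm = full[1:n].sum()
    if folded:
        jf = min(j, n - j)
        val = full[jf] + (full[n - jf] if jf != n - jf else 0.0)
    else:
        val = full[j]
    return val / norm
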