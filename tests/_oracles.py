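"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives an expected value from first principles (exhaustive
enumeration, naive dynamic programming, permutation resampling) without
touching the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

# ---------------------------------------------------------------------------
# hypergeometric upper tail by exact enumeration
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), as an exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(acc)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up from the definition
# ---------------------------------------------------------------------------

def bh_stepup(p):
    """padj_i = min over j with p_(j) >= p_(i) of m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


# ---------------------------------------------------------------------------
# exhaustive seed-site scan, window by window
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGU", "UGCA")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def window_scan(mirna: str, target: str):
    """All seed sites by checking every window of every class separately.

    Returns {(start, end, class)} where each 6mer core occurrence appears
    once with its strongest class (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    m = mirna.upper().replace("T", "U")
    t = target.upper().replace("T", "U")
    p6 = _rc(m[1:7])
    p7m8 = _rc(m[1:8])
    p7a1 = p6 + "A"
    p8 = p7m8 + "A"
    hits = {}
    # index by the 6mer-core anchor position on the target
    for i in range(len(t) - 5):
        if t[i:i + 6] != p6:
            continue
        if t[i - 1:i + 7] == p8 and i >= 1:
            hits[i] = (i - 1, i + 7, "8mer")
        elif t[i - 1:i + 6] == p7m8 and i >= 1:
            hits[i] = (i - 1, i + 6, "7mer-m8")
        elif t[i:i + 7] == p7a1:
            hits[i] = (i, i + 7, "7mer-A1")
        else:
            hits[i] = (i, i + 6, "6mer")
    return set(hits.values())


# ---------------------------------------------------------------------------
# local anti-parallel duplex alignment by naive recursion (tiny inputs)
# ---------------------------------------------------------------------------

def duplex_dp(mirna: str, window: str, match=5.0, wobble=1.0, mismatch=-3.0,
              gap_open=-8.0, gap_extend=-2.0) -> float:
    """Gotoh local alignment of mirna vs reversed window, pair-scored."""
    a = mirna.upper().replace("T", "U")
    b = window.upper().replace("T", "U")[::-1]
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "U"), ("U", "G")}

    def s(x, y):
        if (x, y) in pairs:
            return match
        if (x, y) in wob:
            return wobble
        return mismatch

    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend)
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                              Iy[i - 1][j - 1]) + s(a[i - 1], b[j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


# ---------------------------------------------------------------------------
# Pearson p-value by permutation
# ---------------------------------------------------------------------------

def pearson_perm_p(x, y, n_perm: int = 100_000, seed: int = 0) -> float:
    """Two-sided permutation p for the Pearson coefficient."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = np.corrcoef(x, y)[0, 1]
    perms = np.tile(y, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    xc = x - x.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_null = (pc @ xc) / (np.sqrt((pc ** 2).sum(axis=1)) *
                          np.sqrt((xc ** 2).sum()))
    return float((np.abs(r_null) >= abs(r_obs) - 1e-12).mean())


# ---------------------------------------------------------------------------
# two-sample KS distance between hit and miss rank distributions
# ---------------------------------------------------------------------------

def ks_hit_miss(hit_mask) -> float:
    hit = np.asarray(hit_mask, dtype=bool)
    ranks = np.arange(hit.size)
    from scipy.stats import ks_2samp
    return float(ks_2samp(ranks[hit], ranks[~hit]).statistic)
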