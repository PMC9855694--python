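"""Independent brute-force oracles used to validate the implementations."""

from fractions import Fraction
from functools import lru_cache
from math import comb, sqrt


def spearman_rho_oracle(x, y):
    """Rank-then-Pearson with hand-rolled average ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    xr, yr = ranks(list(x)), ranks(list(y))
    mx = sum(xr) / len(xr)
    my = sum(yr) / len(yr)
    num = sum((a - mx) * (b - my) for a, b in zip(xr, yr))
    den = sqrt(sum((a - mx) ** 2 for a in xr) * sum((b - my) ** 2 for b in yr))
    return num / den


def hypergeom_tail_oracle(k, N, K, n):
    """Exact P(X >= k) by enumerating the hypergeometric pmf."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(min(total, Fraction(1)))


def local_align_oracle(mirna, window, match=5.0, wobble=2.0, mismatch=-3.0,
                       gap_open=-9.0, gap_extend=-4.0, seed_scale=2.0,
                       seed=(1, 8)):
    """Memoized-recursion Gotoh local alignment of a miRNA against the
    reverse of a window (complementarity scoring, seed positions scaled)."""
    enc = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
    q = [enc[c] for c in mirna.upper()]
    w = [enc[c] for c in window.upper()][::-1]
    wc = {(0, 3), (3, 0), (1, 2), (2, 1)}
    gu = {(2, 3), (3, 2)}

    def sub(i, j):
        pair = (q[i - 1], w[j - 1])
        s = match if pair in wc else wobble if pair in gu else mismatch
        return s * (seed_scale if seed[0] <= i - 1 < seed[1] else 1.0)

    @lru_cache(maxsize=None)
    def M(i, j):
        if i == 0 or j == 0:
            return -1e18
        return sub(i, j) + max(0.0, M(i - 1, j - 1), E(i - 1, j - 1), F(i - 1, j - 1))

    @lru_cache(maxsize=None)
    def E(i, j):
        if i == 0 or j == 0:
            return -1e18
        return max(M(i, j - 1) + gap_open, E(i, j - 1) + gap_extend)

    @lru_cache(maxsize=None)
    def F(i, j):
        if i == 0 or j == 0:
            return -1e18
        return max(M(i - 1, j) + gap_open, F(i - 1, j) + gap_extend)

    best = 0.0
    for i in range(1, len(q) + 1):
        for j in range(1, len(w) + 1):
            best = max(best, M(i, j))
    M.cache_clear(), E.cache_clear(), F.cache_clear()
    return best
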