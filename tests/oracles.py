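"""Independent brute-force oracles used across the test suite.

Every oracle here is deliberately naive — integer combinatorics, all-pairs
loops, sliding-window scans — and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct summation of exact pmf terms."""
    hi = min(n, K)
    if k <= 0:
        return 1.0
    if k > hi:
        return 0.0
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, hi + 1)
        if n - i <= N - K
    )
    return float(Fraction(num, math.comb(N, n)))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = sum(
        w
        for i in range(lo, hi + 1)
        if (w := math.comb(r1, i) * math.comb(r2, c1 - i)) <= obs
    )
    return float(Fraction(total, math.comb(n, c1)))


def brute_force_overlaps(queries, subjects, min_bp: int = 1) -> set[tuple[str, str]]:
    """All-pairs O(n*m) overlap pair set, by name."""
    pairs = set()
    for q in queries:
        for s in subjects:
            if q.chrom != s.chrom:
                continue
            if min(q.end, s.end) - max(q.start, s.start) >= min_bp:
                pairs.add((q.name, s.name))
    return pairs


def naive_seed_scan(seed: str, target: str) -> list[tuple[int, str]]:
    """Sliding-window scan of the target and its minus strand."""
    rc = revcomp(seed)
    L = len(seed)
    out = []
    for i in range(len(target) - L + 1):
        window = target[i : i + L]
        if window == rc:
            out.append((i, "sense"))
        if window == seed:
            out.append((i, "antisense"))
    return sorted(out)


def random_intervals(rng: np.random.Generator, n: int, n_chroms: int = 4,
                     span: int = 10_000, max_len: int = 300):
    """n random named intervals for overlap-engine stress tests."""
    from srnalink.intervals import GenomicInterval

    chroms = rng.integers(1, n_chroms + 1, size=n)
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return [
        GenomicInterval(f"chr{c}", int(s), int(s + ln), name=f"iv{i}")
        for i, (c, s, ln) in enumerate(zip(chroms, starts, lengths))
    ]
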