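"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own scanning/alignment code paths:
plain Python loops over every candidate, feasible only on small inputs.
"""

from __future__ import annotations

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def _min_period(unit: str) -> int:
    n = len(unit)
    return next(p for p in range(1, n + 1) if n % p == 0 and unit[:p] * (n // p) == unit)


def brute_force_ssrs(seq: str, thresholds: dict[int, int]) -> list[tuple[int, int, str, int]]:
    """Every maximal perfect tandem repeat by trying each (start, period):
    extend greedily, keep run-starts only, unit at its minimal period."""
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    out = []
    for p in range(1, 7):
        for start in range(n - p + 1):
            if not all(valid[start + t] for t in range(p)):
                continue
            # must be the start of its maximal run
            if (start >= 1 and start - 1 + p < n and valid[start - 1]
                    and valid[start - 1 + p] and seq[start - 1] == seq[start - 1 + p]):
                continue
            length = p
            while (start + length < n and valid[start + length]
                   and seq[start + length] == seq[start + length - p]):
                length += 1
            repeats = length // p
            unit = seq[start : start + p]
            if repeats >= thresholds[p] and _min_period(unit) == p:
                out.append((start, start + repeats * p, unit, repeats))
    return sorted(out)


def longest_inverted_repeat(seq: str) -> int:
    """Length of the longest pair of disjoint exact reverse-complementary
    segments, by exhaustive diagonal scan of seq against its reverse
    complement (O(n^2); linear, adequate for small fixtures).

    A segment seq[a:a+m] == rc(seq[b:b+m]) appears as an m-long match
    between seq and r = rc(seq) starting at (a, n-b-m); every such match
    lies on one diagonal of the comparison matrix.
    """
    import numpy as np

    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    r = np.frombuffer(rc(seq).encode(), dtype=np.uint8)
    best = 0
    for d in range(-(n - 1), n):  # diagonal pairs (i, i - d) of s vs r
        if d >= 0:
            eq = s[d:] == r[: n - d]
            off_a = d
        else:
            eq = s[: n + d] == r[-d:]
            off_a = 0
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            m = int(run_end - run_start)
            a = off_a + int(run_start)
            rb = a - d
            b = n - rb - m
            lo, hi = sorted((a, b))
            if hi >= lo + m:
                cand = m  # disjoint pair
            else:
                # self-overlapping (palindromic) run: the longest disjoint
                # sub-pair inside it has length (hi + m - lo) // 2
                cand = (hi + m - lo) // 2
            best = max(best, cand)
    return best
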