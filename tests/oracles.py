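"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive (double loops, exhaustive
enumeration, O(4^n) recursion) and independent of the library code paths it
cross-checks.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

FEM = {
    0: {"A": -2.63},
    1: {"A": -2.20},
    2: {"G": -3.14},
    3: {"G": -3.14},
    4: {"A": -1.65},
}


def naive_score(window: str) -> float:
    """Per-position lookup-sum of the free-energy matrix."""
    return sum(FEM[i].get(b, 0.0) for i, b in enumerate(window))


def naive_scan(seq: str) -> list[tuple[int, float]]:
    """Double-loop re-scan: every 5-nt window with a strictly negative score."""
    out = []
    for start in range(len(seq) - 4):
        score = naive_score(seq[start : start + 5])
        if score < 0:
            out.append((start, score))
    return out


def naive_pairs(starts: list[int]) -> list[tuple[int, int]]:
    """All ordered pairs of site starts with non-overlapping 5-nt windows."""
    out = []
    for i, a in enumerate(starts):
        for b in starts[i + 1 :]:
            lo, hi = min(a, b), max(a, b)
            if hi - lo >= 5:
                out.append((lo, hi))
    return out


# --- simplified-energy secondary-structure oracle ---------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_PAIR_ENERGY = {("G", "C"): -2, ("C", "G"): -2}  # others -1
MIN_HAIRPIN = 3


def _pair_energy(a: str, b: str) -> int:
    return _PAIR_ENERGY.get((a, b), -1)


def enumerate_structures(seq: str, forbidden: frozenset[int] = frozenset()):
    """All pseudoknot-free structures as frozensets of (i, j) pairs.

    Pairs touching a forbidden (forced-unpaired) position are disallowed;
    the minimum hairpin loop is 3 nt.  Exponential: use on short strings.
    """

    def rec(lo: int, hi: int):
        if lo >= hi:
            yield frozenset()
            return
        # lo unpaired
        for rest in rec(lo + 1, hi):
            yield rest
        if lo in forbidden:
            return
        for j in range(lo + MIN_HAIRPIN + 1, hi + 1):
            if j in forbidden or (seq[lo], seq[j]) not in _PAIRS:
                continue
            for inner in rec(lo + 1, j - 1):
                for outer in rec(j + 1, hi):
                    yield inner | outer | {(lo, j)}

    yield from rec(0, len(seq) - 1)


def brute_force_mfe(seq: str, forbidden: frozenset[int] = frozenset()) -> int:
    """Minimum simplified energy over all constraint-respecting structures."""
    best = 0
    for struct in enumerate_structures(seq, forbidden):
        e = sum(_pair_energy(seq[i], seq[j]) for i, j in struct)
        if e < best:
            best = e
    return best


def nussinov_mfe(seq: str, forbidden: frozenset[int] = frozenset()) -> int:
    """Dynamic-programming minimum of the same simplified energy model."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def E(lo: int, hi: int) -> int:
        if lo >= hi:
            return 0
        best = E(lo + 1, hi)
        if lo not in forbidden:
            for j in range(lo + MIN_HAIRPIN + 1, hi + 1):
                if j in forbidden or (seq[lo], seq[j]) not in _PAIRS:
                    continue
                best = min(best, _pair_energy(seq[lo], seq[j]) + E(lo + 1, j - 1) + E(j + 1, hi))
        return best

    return E(0, n - 1)


# --- exact hypergeometric tails by rational enumeration ---------------------


def hypergeom_tail_exact(N: int, K: int, n: int, k: int, tail: str) -> float:
    """Tail probability summed exactly over binomial coefficients."""
    denom = comb(N, n)
    ks = range(k, min(n, K) + 1) if tail == "upper" else range(max(0, n - (N - K)), k + 1)
    total = Fraction(0)
    for x in ks:
        if x > K or n - x > N - K or x < 0 or n - x < 0:
            continue
        total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)
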