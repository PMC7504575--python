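"""Independent brute-force oracles used by the test suite.

These are deliberately simple, separately coded implementations (top-down
enumeration / exact combinatorics) kept apart from the package's optimized
paths so each test compares two independent routes to the same quantity.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb
from statistics import median

_PAIRS = {
    ("A", "T"), ("T", "A"), ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"), ("G", "U"), ("U", "G"),
}


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pairing count by top-down recursion on the first base."""
    seq = seq.upper()
    n = len(seq)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        # i unpaired, or i paired with some k
        res = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                res = max(res, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return res

    return best(0, n - 1)


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _duplex_cost(m: str, s: str) -> float:
    m = m.replace("U", "T")
    s = s.replace("U", "T")
    if m not in _COMP or s not in _COMP:
        return 1.0
    if _COMP[m] == s:
        return 0.0
    if (m, s) in (("G", "T"), ("T", "G")):
        return 0.5
    return 1.0


def _w(pos: int) -> float:
    return 2.0 if 2 <= pos <= 13 else 1.0


def brute_duplex_penalty(mirna: str, site: str) -> float:
    """Minimum duplex penalty by direct enumeration of all <=1-gap alignments.

    The site is 5'->3' on the transcript; its reversal aligns index-wise with
    the miRNA.  Allowed alignments: gapless (equal lengths); one deleted
    miRNA base k, weight at position k (site one shorter); one inserted site
    base after i consumed miRNA bases, weight at position min(i+1, L) (site
    one longer).
    """
    mirna = mirna.upper().replace("U", "T")
    t = site.upper().replace("U", "T")[::-1]
    L, M = len(mirna), len(t)
    options = []
    if M == L:
        options.append(sum(_duplex_cost(mirna[i], t[i]) * _w(i + 1) for i in range(L)))
    elif M == L - 1:
        for k in range(1, L + 1):  # miRNA position k unpaired (gap in site)
            cost = 2.0 * _w(k)
            j = 0
            for i in range(1, L + 1):
                if i == k:
                    continue
                cost += _duplex_cost(mirna[i - 1], t[j]) * _w(i)
                j += 1
            options.append(cost)
    elif M == L + 1:
        for slot in range(0, L + 1):  # extra site base after `slot` miRNA bases
            cost = 2.0 * _w(min(slot + 1, L))
            j = 0
            for i in range(1, L + 1):
                if j == slot:
                    j += 1  # skip the inserted site base
                cost += _duplex_cost(mirna[i - 1], t[j]) * _w(i)
                j += 1
            options.append(cost)
    else:
        raise ValueError("site length outside miRNA length +/- 1")
    return min(options)


def brute_category(position: int, counts: dict[int, int]) -> int | None:
    """Cleavage category from the stated decision table, coded via rank logic."""
    r = counts.get(position, 0)
    occupied = sorted(c for c in counts.values() if c > 0)
    if r == 0:
        return None
    if r == 1:
        return 4
    peak = occupied[-1]
    if r == peak:
        n_at_peak = sum(1 for c in occupied if c == peak)
        return 0 if n_at_peak == 1 else 1
    if r > median(occupied):
        return 2
    return 3


def exact_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P[X >= k] for X ~ Hypergeom(N, K, n) by exact rational enumeration."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(n, K) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return total


def brute_venn_regions(membership: dict[str, set[str]], levels: list[str]) -> dict[frozenset, int]:
    """Exact-region Venn counts by direct subset enumeration."""
    from itertools import combinations

    regions: dict[frozenset, int] = {}
    for r in range(1, len(levels) + 1):
        for combo in combinations(levels, r):
            want = set(combo)
            regions[frozenset(combo)] = sum(
                1 for s in membership.values() if set(s) == want
            )
    return regions


def brute_triple_join(
    mirna_features: set[str],
    gene_features: set[str],
    evidenced_pairs: set[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Pairs supported by all three layers, by literal set intersection."""
    return {
        (m, g)
        for (m, g) in evidenced_pairs
        if m in mirna_features and g in gene_features
    }
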