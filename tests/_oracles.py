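"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with pure-Python scalar arithmetic
and string operations, independent of the vectorized implementations in
``komagen``, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

MASK64 = (1 << 64) - 1
_SPLITMIX_GAMMA = 0x9E3779B97F4A7C15
_MIX_C1 = 0xBF58476D1CE4E5B9
_MIX_C2 = 0x94D049BB133111EB

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGT", "TGCA")


def splitmix64(x: int, seed: int) -> int:
    """Reference scalar implementation of the sketch hash function."""
    z = (x ^ ((seed & MASK64) * _SPLITMIX_GAMMA & MASK64)) & MASK64
    z ^= z >> 30
    z = (z * _MIX_C1) & MASK64
    z ^= z >> 27
    z = (z * _MIX_C2) & MASK64
    z ^= z >> 31
    return z


def pack_kmer(kmer: str) -> int:
    v = 0
    for base in kmer:
        v = v * 4 + _CODE[base]
    return v


def canonical_kmer_set(seq: str, k: int) -> set[int]:
    """All distinct canonical k-mers (packed) by direct string enumeration."""
    out = set()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(b not in _CODE for b in kmer):
            continue
        rc = kmer.translate(_COMP)[::-1]
        out.add(min(pack_kmer(kmer), pack_kmer(rc)))
    return out


def bottom_s_hashes(seq: str, k: int, s: int, seed: int) -> list[int]:
    """Brute-force bottom-s sketch: hash every canonical k-mer, keep s smallest."""
    hashes = sorted({splitmix64(x, seed) for x in canonical_kmer_set(seq, k)})
    return hashes[:s]


def mash_from_jaccard(j: float, k: int) -> float:
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / k)


def exact_mash_distance(a: str, b: str, k: int) -> float:
    """Mash-formula distance from the exact Jaccard of full canonical k-mer sets."""
    sa, sb = canonical_kmer_set(a, k), canonical_kmer_set(b, k)
    if not sa and not sb:
        return 0.0
    j = len(sa & sb) / len(sa | sb)
    return mash_from_jaccard(j, k)


def connected_components(labels: list[str], edges: set[tuple[str, str]]) -> list[tuple[str, ...]]:
    """Brute-force union-find connected components, sorted like the package."""
    parent = {l: l for l in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for l in labels:
        comps.setdefault(find(l), []).append(l)
    out = [tuple(sorted(c)) for c in comps.values()]
    out.sort(key=lambda c: (-len(c), c[0]))
    return out


def bh_stepup(pvalues: list[float]) -> list[float]:
    """q(i) = min over j >= i of m p(j)/j, straight from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for rank_idx, i in enumerate(order):
        candidates = [
            m * pvalues[order[j]] / (j + 1) for j in range(rank_idx, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def quantile_type7(values: list[float], q: float) -> float:
    """Sort-and-linear-interpolate quantile (type-7 convention)."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
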