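"""MinHash sketching, Mash distance estimation, and neighbor-joining trees.

A *sketch* is the bottom-``s`` set of 64-bit hash values over the distinct
canonical k-mers of a nucleotide sequence (canonical = lexicographic minimum
of a k-mer and its reverse complement, so sketches are strand-symmetric).
Two sketches give a Jaccard estimate

    j = |X ∩ A ∩ B| / |X|,   X = bottom-s of (A ∪ B)

which the Mash transform converts into an approximate per-base divergence

    d = -(1/k) * ln(2j / (1 + j)),   d = 1 when j = 0,  d = 0 when j = 1.

Hashing uses a fixed, documented 64-bit finalizer (the splitmix64 mixing
steps) applied to the 2-bit-packed canonical k-mer XOR a seed-derived
constant, so sketches are bit-identical across platforms and runs.

The neighbor-joining implementation is the classical Q-matrix agglomeration
with two determinism rules: labels are sorted lexicographically before
construction, and among tied Q minima the lowest (row, col) index pair wins.
Negative branch lengths are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SketchParams",
    "Sketch",
    "DistanceMatrix",
    "sketch_sequence",
    "sketch_fasta",
    "mash_distance",
    "distance_matrix",
    "nj_tree",
    "canonical_kmers",
]

#: Default k-mer size; modest enough that small plasmids are not starved of
#: distinct k-mers while still giving near-unique 32-bit packings.
DEFAULT_K = 16
#: Default sketch sizes: plasmids are small (tens of kb), chromosomes are Mb.
PLASMID_SKETCH_SIZE = 1000
CHROMOSOME_SKETCH_SIZE = 2000

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX_C1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX_C2 = np.uint64(0x94D049BB133111EB)

# base byte -> 2-bit code; 4 marks non-ACGT (k-mers containing it are skipped)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGTacgt", (0, 1, 2, 3, 0, 1, 2, 3)):
    _ENCODE[_b] = _c


@dataclass(frozen=True)
class SketchParams:
    k: int = DEFAULT_K
    s: int = PLASMID_SKETCH_SIZE
    hash_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 31):
            raise ValueError(f"k must be in [1, 31], got {self.k}")
        if self.s < 1:
            raise ValueError(f"sketch size s must be >= 1, got {self.s}")


@dataclass(frozen=True)
class Sketch:
    name: str
    params: SketchParams
    hashes: np.ndarray  # sorted, strictly increasing uint64
    n_kmers: int  # total distinct canonical k-mers hashed

    def __post_init__(self) -> None:
        h = np.asarray(self.hashes, dtype=np.uint64)
        object.__setattr__(self, "hashes", h)
        if h.size > 1 and not np.all(h[1:] > h[:-1]):
            raise ValueError("sketch hashes must be strictly increasing")
        if h.size != min(self.params.s, self.n_kmers):
            raise ValueError("|hashes| must equal min(s, n_kmers)")


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Fixed 64-bit mixing function (splitmix64 finalizer) with a seed."""
    with np.errstate(over="ignore"):
        z = x.astype(np.uint64) ^ (np.uint64(seed & 0xFFFFFFFFFFFFFFFF) * _SPLITMIX_GAMMA)
        z ^= z >> np.uint64(30)
        z *= _MIX_C1
        z ^= z >> np.uint64(27)
        z *= _MIX_C2
        z ^= z >> np.uint64(31)
    return z


def canonical_kmers(seq: str, k: int, chunk: int = 1_000_000) -> np.ndarray:
    """Distinct canonical k-mers of ``seq`` as 2-bit-packed uint64 values.

    The canonical form of a k-mer is the lexicographic minimum of the k-mer
    and its reverse complement under the packing A<C<G<T.  K-mers containing
    any non-ACGT base are skipped entirely.  Processing is chunked so Mb-
    scale sequences do not materialize a dense windows-x-k uint64 array.
    """
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    fwd_pow = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    rev_pow = fwd_pow[::-1]
    out: list[np.ndarray] = []
    step = max(chunk, k)
    for start in range(0, len(codes) - k + 1, step):
        block = codes[start : start + step + k - 1]
        if block.size < k:
            break
        win = np.lib.stride_tricks.sliding_window_view(block, k)
        valid = ~(win == 4).any(axis=1)
        if not valid.any():
            continue
        w = win[valid].astype(np.uint64)
        with np.errstate(over="ignore"):
            f = (w * fwd_pow).sum(axis=1, dtype=np.uint64)
            r = ((np.uint64(3) - w) * rev_pow).sum(axis=1, dtype=np.uint64)
        out.append(np.minimum(f, r))
    if not out:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(out))


def sketch_sequence(seq: str, params: SketchParams, name: str = "") -> Sketch:
    """Bottom-s MinHash sketch of a nucleotide sequence.

    Raises ``ValueError("sequence shorter than k")`` when ``len(seq) < k``.
    """
    kmers = canonical_kmers(seq, params.k)
    hashes = np.unique(_mix64(kmers, params.hash_seed))
    # hash collisions merge k-mers; n_kmers counts the distinct hash images
    # so the |hashes| = min(s, n_kmers) invariant holds exactly
    n_kmers = int(hashes.size)
    return Sketch(name=name, params=params, hashes=hashes[: params.s], n_kmers=n_kmers)


def sketch_fasta(path: str | Path, params: SketchParams) -> list[Sketch]:
    """Sketch every record of a (multi-)FASTA file separately."""
    from Bio import SeqIO

    return [
        sketch_sequence(str(rec.seq), params, name=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def _check_params(a: Sketch, b: Sketch) -> None:
    for fld in ("k", "s", "hash_seed"):
        if getattr(a.params, fld) != getattr(b.params, fld):
            raise ValueError(
                f"sketch parameter mismatch: {fld} differs "
                f"({getattr(a.params, fld)} vs {getattr(b.params, fld)})"
            )


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance between two sketches built with identical parameters."""
    _check_params(a, b)
    union = np.union1d(a.hashes, b.hashes)
    x = union[: a.params.s]
    if x.size == 0:
        return 0.0
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    j = np.intersect1d(x, shared, assume_unique=True).size / x.size
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    d = -np.log(2.0 * j / (1.0 + j)) / a.params.k
    return float(min(max(d, 0.0), 1.0))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.d[np.ix_(idx, idx)])


def distance_matrix(sketches: Sequence[Sketch]) -> DistanceMatrix:
    """All-by-all Mash distance matrix over a list of sketches."""
    if len(sketches) < 2:
        raise ValueError("need at least 2 sketches")
    labels = tuple(s.name for s in sketches)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sketch names")
    n = len(sketches)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mash_distance(sketches[i], sketches[j])
    return DistanceMatrix(labels, d)


def _fmt_len(x: float) -> str:
    return format(max(x, 0.0), ".10g")


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree of a distance matrix, as a Newick string.

    Deterministic: taxa are processed in lexicographic label order and ties
    in the Q matrix are broken by the lowest (row, col) index pair.  Negative
    branch lengths are clamped to zero.  The final join leaves an unrooted
    tree written with a multifurcation at the last agglomerated node.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float).copy()

    # (newick fragment without trailing length, is_internal)
    nodes: list[str] = list(labels)
    internal: list[bool] = [False] * len(labels)

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) among ties, row-major
        flat = int(np.argmin(q))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        new = f"({nodes[i]}:{_fmt_len(li)},{nodes[j]}:{_fmt_len(lj)})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        nd = np.zeros((n - 1, n - 1))
        nd[:-1, :-1] = d[np.ix_(keep, keep)]
        nd[-1, :-1] = nd[:-1, -1] = dk[keep]
        d = nd
        nodes = [nodes[x] for x in keep] + [new]
        internal = [internal[x] for x in keep] + [True]

    # two nodes remain; at least one is internal (we started with >= 3)
    a, b = nodes
    dist = _fmt_len(d[0, 1])
    if internal[1]:
        inner = b[1:-1]  # strip enclosing parens, graft a into the join
        return f"({inner},{a}:{dist});"
    inner = a[1:-1]
    return f"({inner},{b}:{dist});"
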