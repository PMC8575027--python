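"""MinHash sketches of assemblies and Mash-style pairwise distances.

Each assembly is reduced to a bottom-s sketch: the ``sketch_size``
smallest 64-bit hashes over its canonical k-mers (lexicographic minimum
of a k-mer and its reverse complement; k-mers containing N are skipped).
The Jaccard index between two assemblies is estimated from the merged
bottom-s sketch, and converted to a distance with the Mash formula
d = -(1/k) * ln(2j / (1 + j)), capped at 1.  Defaults follow common
practice for assembly comparison: k = 31, sketch size 100 000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import Contig

logger = logging.getLogger("asmconcord")

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c


@dataclass(eq=False)
class MinHashSketch:
    k: int
    sketch_size: int
    seed: int
    hashes: np.ndarray  # sorted, distinct uint64, at most sketch_size
    n_kmers_seen: int

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MinHashSketch)
            and self.k == other.k
            and self.sketch_size == other.sketch_size
            and self.seed == other.seed
            and np.array_equal(self.hashes, other.hashes)
        )


def _mix64(x: np.ndarray) -> np.ndarray:
    """64-bit finalizer (murmur3-style avalanche), vectorised on uint64."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xFF51AFD7ED558CCD)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xC4CEB9FE1A85EC53)
    x ^= x >> np.uint64(33)
    return x


def _seed_constant(seed: int) -> np.uint64:
    return _mix64(np.array([seed], dtype=np.uint64))[0]


def _canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Integer codes of the canonical k-mers of one sequence.

    Bases are 2-bit encoded with A<C<G<T, so comparing the base-4 integer
    of a k-mer with that of its reverse complement is exactly the
    lexicographic comparison; windows containing N are dropped.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    window_valid = (
        np.convolve(valid.astype(np.int64), np.ones(k, dtype=np.int64), mode="valid")
        == k
    )
    codes64 = np.where(valid, codes, 0).astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    windows = np.lib.stride_tricks.sliding_window_view(codes64, k)
    fwd = windows @ powers
    rc_codes64 = (np.uint64(3) - codes64[::-1]) % np.uint64(4)
    rc_windows = np.lib.stride_tricks.sliding_window_view(rc_codes64, k)
    rev = (rc_windows @ powers)[::-1]
    canon = np.minimum(fwd, rev)
    return canon[window_valid]


def sketch(
    contigs: Sequence[Contig],
    k: int = 31,
    sketch_size: int = 100_000,
    seed: int = 42,
) -> MinHashSketch:
    """Bottom-s MinHash sketch over the canonical k-mers of an assembly."""
    if k < 1 or sketch_size < 1:
        raise ValueError("sketch: k and sketch_size must be >= 1")
    if 4**k > 2**62:
        raise ValueError("sketch: k too large for 2-bit packing (max 31)")
    const = _seed_constant(seed)
    all_hashes: list[np.ndarray] = []
    n_seen = 0
    for contig in contigs:
        codes = _canonical_kmer_codes(contig.sequence, k)
        n_seen += len(codes)
        if len(codes):
            all_hashes.append(_mix64(codes ^ const))
    if not all_hashes:
        logger.warning("sketch: no k-mers of length %d found; empty sketch", k)
        return MinHashSketch(k, sketch_size, seed, np.empty(0, dtype=np.uint64), 0)
    merged = np.unique(np.concatenate(all_hashes))
    return MinHashSketch(k, sketch_size, seed, merged[:sketch_size], n_seen)


def mash_distance(s1: MinHashSketch, s2: MinHashSketch) -> float:
    """Mash distance from the merged bottom-s Jaccard estimate.

    j is the fraction of the s' = min(sketch_size, |hash union|) smallest
    merged hashes present in both sketches; d = -(1/k) ln(2j/(1+j)),
    capped at 1, and 1 exactly when j = 0.
    """
    if s1.k != s2.k:
        raise ValueError(f"mash_distance: k mismatch ({s1.k} vs {s2.k})")
    if s1.seed != s2.seed:
        raise ValueError("mash_distance: sketches built with different hash seeds")
    if len(s1.hashes) == 0 and len(s2.hashes) == 0:
        logger.warning("mash_distance: two empty sketches; distance 0 by convention")
        return 0.0
    union = np.union1d(s1.hashes, s2.hashes)
    s_prime = min(min(s1.sketch_size, s2.sketch_size), len(union))
    bottom = union[:s_prime]
    shared = int(
        np.sum(np.isin(bottom, s1.hashes) & np.isin(bottom, s2.hashes))
    )
    if shared == 0:
        return 1.0
    j = shared / s_prime
    if j >= 1.0:
        return 0.0
    return min(1.0, -np.log(2 * j / (1 + j)) / s1.k)


def pairwise_matrix(
    assembly_sets: Mapping[str, Sequence[Contig]],
    k: int = 31,
    sketch_size: int = 100_000,
    seed: int = 42,
) -> tuple[list[str], np.ndarray]:
    """Symmetric, zero-diagonal Mash distance matrix between assemblies."""
    labels = sorted(assembly_sets)
    if len(labels) < 2:
        raise ValueError("pairwise_matrix: need at least two assemblies")
    sketches = {lab: sketch(assembly_sets[lab], k, sketch_size, seed) for lab in labels}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = mash_distance(sketches[labels[i]], sketches[labels[j]])
            mat[i, j] = mat[j, i] = d
    return labels, mat
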