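"""k-mer hash indexes with a pre-allocated memory pool.

The index is a chained hash table laid out in two fixed-size arrays:

* ``buckets`` — one-dimensional array indexed by hash key, holding the pool
  offset of the head of that bucket's chain (or -1);
* a *memory pool* of entries, one per k-mer occurrence, each holding the
  occurrence position and the pool offset of the next entry in the chain.

The pool is allocated once, sized exactly to the number of k-mers in the
indexed window (a linear function of reference length), and never grows
during the build — dynamic reallocation is the dominant cost in naive
hash-table builds over genome-scale references, so it is designed out.

Hashing is a polynomial (Rabin–Karp) rolling hash over raw character
codes, so sliding the k-window by one position costs O(1) instead of O(k).
Hash collisions are resolved by chaining and every lookup verifies
candidate positions by direct character comparison, so a lookup never
reports a false position regardless of the modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

from sympy import nextprime

from .encoding import DegenerateInputError, Sequence, UsageError

#: Counts calls to :func:`build_global_index`; batch pipelines amortize one
#: global build across many records, which tests assert via this counter.
_global_builds = 0


def global_build_count() -> int:
    """Number of global index builds performed so far in this process."""
    return _global_builds


@dataclass(frozen=True)
class IndexParams:
    """Parameters of the rolling-hash index.

    ``table_size``/``hash_modulus`` may be left ``None`` and are then
    resolved at build time to a prime of roughly four times the number of
    indexed k-mers (load factor ~0.25).  The hash base (default 131)
    exceeds the size of the extended DNA alphabet, and the modulus always
    equals the table size so hash values index buckets directly.
    """

    k: int = 16
    table_size: Optional[int] = None
    hash_base: int = 131
    hash_modulus: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise UsageError(f"k must be >= 1, got {self.k}")
        if self.table_size is not None and self.table_size < 1:
            raise UsageError("table_size must be >= 1")
        if self.hash_modulus is not None and not (
            self.hash_modulus > self.hash_base
        ):
            raise UsageError("hash_modulus must exceed hash_base")

    def resolved(self, n_kmers: int) -> "IndexParams":
        """Fill in table size and modulus for an index over ``n_kmers``."""
        table = self.table_size
        if table is None:
            # strictly above the hash base so hash values stay injective
            # on single characters even for tiny references
            table = int(nextprime(max(4 * n_kmers, self.hash_base)))
        modulus = self.hash_modulus if self.hash_modulus is not None else table
        return replace(self, table_size=table, hash_modulus=modulus)


def direct_hash(kmer: str, params: IndexParams) -> int:
    """Horner-rule polynomial hash of a single k-mer."""
    if params.hash_modulus is None:
        raise UsageError("params must be resolved before hashing")
    h = 0
    base, mod = params.hash_base, params.hash_modulus
    for ch in kmer:
        h = (h * base + ord(ch)) % mod
    return h


def rolling_hashes(seq, params: IndexParams) -> List[int]:
    """Hash every k-mer window of ``seq`` in one pass.

    Each slide reuses the previous window's hash: subtract the outgoing
    character's contribution, shift, add the incoming character.  Output
    values equal :func:`direct_hash` of each window.
    """
    s = seq.residues if isinstance(seq, Sequence) else seq
    k = params.k
    n = len(s) - k + 1
    if n < 1:
        raise DegenerateInputError(
            f"sequence of length {len(s)} is shorter than k={k}"
        )
    if params.hash_modulus is None:
        params = params.resolved(n)
    base, mod = params.hash_base, params.hash_modulus
    codes = [ord(c) for c in s]
    h = 0
    for c in codes[:k]:
        h = (h * base + c) % mod
    out = [h]
    top = pow(base, k - 1, mod)
    for i in range(1, n):
        h = ((h - codes[i - 1] * top) * base + codes[i + k - 1]) % mod
        out.append(h)
    return out


@dataclass
class KmerIndex:
    """Chained hash index over the k-mers of one reference window.

    ``pool_pos[i]`` is the (global) reference position of entry ``i``;
    ``pool_next[i]`` chains entries sharing a bucket (-1 terminates).
    Positions are inserted in ascending order at chain heads, so chains
    run from the largest position downward.
    """

    params: IndexParams  # resolved: table_size/hash_modulus are concrete
    reference_name: str
    reference: str  # residues, kept for collision verification
    window_start: int  # first indexed k-mer start position
    window_end: int  # last indexed k-mer start position (inclusive)
    buckets: List[int]
    pool_pos: List[int]
    pool_next: List[int]

    @property
    def n_entries(self) -> int:
        return len(self.pool_pos)

    def lookup(
        self, kmer: str, prefer_pos: Optional[int] = None
    ) -> List[int]:
        """All verified occurrence positions of ``kmer``.

        Candidates from the bucket chain are confirmed character-for-
        character against the reference, so hash collisions are excluded.
        With ``prefer_pos`` the result is ordered by distance to that
        position (ties to the smaller position); otherwise ascending.
        """
        k = self.params.k
        if len(kmer) != k:
            raise UsageError(f"lookup kmer has length {len(kmer)}, k={k}")
        h = direct_hash(kmer, self.params)
        ref = self.reference
        positions: List[int] = []
        entry = self.buckets[h]
        pool_pos, pool_next = self.pool_pos, self.pool_next
        while entry != -1:
            p = pool_pos[entry]
            if ref[p : p + k] == kmer:
                positions.append(p)
            entry = pool_next[entry]
        positions.reverse()  # chain runs high-to-low; restore ascending
        if prefer_pos is not None:
            positions.sort(key=lambda p: (abs(p - prefer_pos), p))
        return positions


def _build(
    reference: Sequence, start: int, span: int, params: IndexParams
) -> KmerIndex:
    L = len(reference)
    k = params.k
    stop = min(start + span, L)  # window clipped to reference end
    if stop - start < k:
        raise DegenerateInputError(
            f"index window [{start}, {stop}) shorter than k={k}"
        )
    window = reference.residues[start:stop]
    n = len(window) - k + 1
    params = params.resolved(n)
    hashes = rolling_hashes(window, params)
    buckets = [-1] * params.table_size
    # pool sized exactly to the k-mer count; filled in place, never grown
    pool_pos = [0] * n
    pool_next = [0] * n
    for i, h in enumerate(hashes):
        pool_pos[i] = start + i
        pool_next[i] = buckets[h]
        buckets[h] = i
    return KmerIndex(
        params=params,
        reference_name=reference.name,
        reference=reference.residues,
        window_start=start,
        window_end=start + n - 1,
        buckets=buckets,
        pool_pos=pool_pos,
        pool_next=pool_next,
    )


def build_global_index(
    reference: Sequence, params: IndexParams = IndexParams()
) -> KmerIndex:
    """Index every k-mer of the complete reference."""
    global _global_builds
    idx = _build(reference, 0, len(reference), params)
    _global_builds += 1
    return idx


def build_partial_index(
    reference: Sequence, start: int, span: int, params: IndexParams
) -> KmerIndex:
    """Index the k-mers starting in ``[start, min(start + span, L) - k]``.

    Stored positions are global reference coordinates, so lookups against
    a partial index are directly comparable with global ones.
    """
    if start < 0:
        raise UsageError(f"negative window start {start}")
    return _build(reference, start, span, params)
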