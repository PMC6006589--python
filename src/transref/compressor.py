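"""Greedy referential compression against an indexed reference.

The factorization is the classic longest-match scheme used by hash-table
referential compressors: at each target position look up the k-mer in the
reference index, extend every candidate hit by direct character
comparison, and keep the longest extension.  A match at least
``min_match_len`` long is emitted as a match token and both cursors jump
past it; otherwise the current character is emitted as a literal and the
cursor advances by one.  When several candidates extend equally far, the
one nearest the current reference pointer wins (relative positions are
cheap to encode and intra-species similarity makes the corresponding
position the likeliest home), with the smaller position as the final tie
break.

The same factorization drives both target-vs-reference compression
(:func:`compress_sequence`) and reference-vs-reference alignment
(:func:`align_references`), which re-expresses the token list as a tiling
block distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .encoding import (
    CompressedRecord,
    DegenerateInputError,
    DistBlock,
    LiteralToken,
    MatchToken,
    RefDistribution,
    Sequence,
    Token,
    UsageError,
    decode_record,
    make_record,
)
from .kmer_index import IndexParams, KmerIndex


@dataclass(frozen=True)
class CompressParams:
    """Compression settings.

    ``min_match_len`` must be at least k: shorter matches cannot be found
    through the index and cost about as much to encode as the literals
    they would replace.  ``max_candidates`` caps how many index hits are
    extended per lookup; hits are taken in preference order, so the cap
    only prunes far-away candidates in highly repetitive references.
    """

    index: IndexParams = field(default_factory=IndexParams)
    min_match_len: int = 16
    tie_break: str = "nearest"  # "nearest" to RP, or "leftmost"
    max_candidates: int = 32

    def __post_init__(self) -> None:
        if self.min_match_len < self.index.k:
            raise UsageError(
                f"min_match_len {self.min_match_len} < k {self.index.k}"
            )
        if self.tie_break not in ("nearest", "leftmost"):
            raise UsageError(f"unknown tie_break {self.tie_break!r}")


def longest_common_extension(a: str, i: int, b: str, j: int) -> int:
    """Length of the longest common prefix of ``a[i:]`` and ``b[j:]``.

    Compares in doubling chunks so the inner loop runs at C speed.
    """
    limit = min(len(a) - i, len(b) - j)
    if limit <= 0:
        return 0
    n = 0
    chunk = 32
    while n < limit:
        step = min(chunk, limit - n)
        if a[i + n : i + n + step] == b[j + n : j + n + step]:
            n += step
            chunk *= 2
        else:
            break
    # resolve the final unequal chunk character by character
    while n < limit and a[i + n] == b[j + n]:
        n += 1
    return n


def greedy_factorize(
    target: str,
    index: KmerIndex,
    min_match_len: int,
    tie_break: str = "nearest",
    max_candidates: int = 32,
    start_anchor: int = 0,
) -> List[Token]:
    """Factorize ``target`` into match/literal tokens against ``index``.

    ``start_anchor`` seeds the reference pointer used for nearest-position
    candidate preference (useful when re-encoding a fragment expected to
    land near a known reference position).
    """
    k = index.params.k
    ref = index.reference
    n = len(target)
    tokens: List[Token] = []
    lit: List[str] = []
    cp = 0
    rp = start_anchor
    while cp <= n - k:
        kmer = target[cp : cp + k]
        if tie_break == "nearest":
            cands = index.lookup(kmer, prefer_pos=rp)
        else:
            cands = index.lookup(kmer)
        best_len = 0
        best_pos = -1
        for p in cands[:max_candidates]:
            ext = k + longest_common_extension(target, cp + k, ref, p + k)
            if ext > best_len:  # ties keep the earlier, preferred candidate
                best_len, best_pos = ext, p
        if best_len >= min_match_len:
            if lit:
                tokens.append(LiteralToken("".join(lit)))
                lit.clear()
            tokens.append(MatchToken(best_pos, best_pos + best_len - 1))
            cp += best_len
            rp = best_pos + best_len
        else:
            lit.append(target[cp])
            cp += 1
            rp += 1
    lit.append(target[cp:])
    if lit and any(lit):
        tokens.append(LiteralToken("".join(lit)))
    return tokens


def compress_sequence(
    target: Sequence,
    reference: Sequence,
    index: KmerIndex,
    params: CompressParams,
) -> CompressedRecord:
    """Compress ``target`` against ``reference`` using its k-mer index."""
    if len(target) == 0:
        raise DegenerateInputError("empty target")
    if index.reference_name != reference.name:
        raise UsageError(
            f"index was built on {index.reference_name!r}, reference is "
            f"{reference.name!r}"
        )
    tokens = greedy_factorize(
        target.residues,
        index,
        params.min_match_len,
        tie_break=params.tie_break,
        max_candidates=params.max_candidates,
    )
    return make_record(target.name, reference.name, tokens)


def tokens_to_distribution(
    tokens: List[Token], encoded_name: str, base_name: str, base_length: int
) -> RefDistribution:
    """Re-express a token list as a tiling block distribution.

    Match tokens keep both coordinate ranges.  A literal run becomes a
    mismatch block anchored on the base side at one past the previous
    match's end; its anchor end is the position before the next match
    resumes when that interval is nonempty (a substitution-like gap), else
    it spans the literal's own length (an insertion), clamped to base
    bounds.  Anchors orient small-range realignment later; reconstruction
    uses only the characters.
    """
    blocks: List[DistBlock] = []
    b = 0
    prev_a_end = -1
    for i, tok in enumerate(tokens):
        if isinstance(tok, MatchToken):
            blocks.append(
                DistBlock(b, b + len(tok) - 1, tok.r_start, tok.r_end)
            )
            prev_a_end = tok.r_end
        else:
            a_start = prev_a_end + 1
            nxt = next(
                (t for t in tokens[i + 1 :] if isinstance(t, MatchToken)),
                None,
            )
            if nxt is not None and nxt.r_start - 1 >= a_start:
                a_end = nxt.r_start - 1
            else:
                a_end = a_start + len(tok) - 1
            a_start = min(a_start, base_length - 1)
            a_end = max(0, min(a_end, base_length - 1))
            blocks.append(
                DistBlock(b, b + len(tok) - 1, a_start, a_end, tok.chars)
            )
        b += len(tok)
    return RefDistribution(
        encoded_name=encoded_name,
        base_name=base_name,
        blocks=blocks,
        encoded_length=b,
    )


def align_references(
    encoded: Sequence,
    base: Sequence,
    index: KmerIndex,
    params: CompressParams,
) -> RefDistribution:
    """Compress one reference with another, yielding its distribution."""
    if len(encoded) == 0:
        raise DegenerateInputError("empty encoded sequence")
    if index.reference_name != base.name:
        raise UsageError(
            f"index was built on {index.reference_name!r}, base is "
            f"{base.name!r}"
        )
    tokens = greedy_factorize(
        encoded.residues,
        index,
        params.min_match_len,
        tie_break=params.tie_break,
        max_candidates=params.max_candidates,
    )
    tokens = [t for t in tokens]  # already merged by construction order
    return tokens_to_distribution(tokens, encoded.name, base.name, len(base))


def recompress_baseline(
    record: CompressedRecord,
    ref1: Sequence,
    ref2: Sequence,
    index2: KmerIndex,
    params: CompressParams,
) -> CompressedRecord:
    """Decompress-and-recompress: the traditional re-referencing workflow.

    Serves as the correctness and size oracle for the transform
    algorithms, which must decode to the same target.
    """
    target = decode_record(record, ref1)
    return compress_sequence(target, ref2, index2, params)
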