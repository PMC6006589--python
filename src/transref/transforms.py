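"""Re-referencing transforms: TDM, TPI and TGI.

A record compressed against Ref1 is converted into a record compressed
against Ref2 without decompress-and-recompress, by composing it with the
*distribution* of Ref1 on Ref2 (Ref1 compressed against Ref2).  Both
encodings tile Ref1's coordinate space, so a lockstep sweep splits the
target's tokens at every block boundary and classifies each overlap:

====  =============  =================  =============================
case  T vs Ref1      Ref1 vs Ref2       consequence
====  =============  =================  =============================
A     match          match              T matches Ref2: remap coords
B     literal        match              T differs from Ref2: literal
C     match          mismatch           partially decompress from Ref1
D     literal        mismatch           relationship unknown: literal
====  =============  =================  =============================

* **TDM** (transform by direct match) applies exactly that table: case A
  becomes a match token with offset-shifted Ref2 coordinates, everything
  else becomes literal characters.  Fast, no index, but every divergence
  between the references is paid for in literals.
* **TPI** (transform by partial index) repairs TDM's literalization: runs
  of characters are first used to extend the previous match by direct
  comparison, then re-encoded against a small windowed index of Ref2
  built around the expected position — exploiting that genomes are most
  similar at corresponding positions ("good matches" are nearby ones).
  Case-A matches shorter than ``min_encode_match`` are folded into the
  surrounding character run and realigned with their neighbors.
* **TGI** (transform through global index) serves batch workloads: one
  global Ref2 index is built for the whole batch (and reused to compute
  the distribution), long character runs are realigned against it, short
  ones are stored verbatim, and case-A matches are kept only when long
  enough and not *misplaced* (mapped further than ``misplace_threshold``
  from the running anchor — far-away matches are penalized because
  relative positions are cheap to encode only when small).

Every transform is lossless: its output decodes against Ref2 to exactly
the sequence the input decodes to against Ref1.
"""

from __future__ import annotations

import enum
import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple, Union

from .compressor import greedy_factorize, longest_common_extension
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
    make_record,
)
from .kmer_index import (
    IndexParams,
    KmerIndex,
    build_global_index,
    build_partial_index,
)

logger = logging.getLogger(__name__)


class CaseLabel(enum.Enum):
    """Relationship of an overlap interval to both encodings."""

    A = "A"  # T matches Ref1, Ref1 matches Ref2
    B = "B"  # T differs from Ref1, Ref1 matches Ref2
    C = "C"  # T matches Ref1, Ref1 differs from Ref2
    D = "D"  # T differs from Ref1, Ref1 differs from Ref2


@dataclass(frozen=True)
class TransformParams:
    """Tunable thresholds of the transform algorithms (all in bases).

    ``k_partial``        k-mer length of windowed realignment indexes; small
                         (default 8) so short re-anchoring matches are found.
    ``delta``            backward reach of the realignment window before the
                         expected position (default 100).
    ``Delta``            forward span of the realignment window (default
                         4096, comfortably above typical indel displacement
                         at percent-scale divergence).
    ``min_encode_match`` matches shorter than this are literalized
                         (default 16; shorter matches cost roughly as much
                         as the literals they replace).
    ``misplace_threshold`` case-A matches mapped further than this from the
                         running anchor are decompressed and realigned
                         (default 1000).
    ``min_realign_len``  TGI stores character runs shorter than this
                         verbatim instead of realigning them (default 32).
    """

    k_partial: int = 8
    delta: int = 100
    Delta: int = 4096
    min_encode_match: int = 16
    misplace_threshold: int = 1000
    min_realign_len: int = 32

    def __post_init__(self) -> None:
        for name in (
            "k_partial",
            "delta",
            "Delta",
            "min_encode_match",
            "misplace_threshold",
            "min_realign_len",
        ):
            if getattr(self, name) < 1:
                raise UsageError(f"{name} must be >= 1")
        if self.k_partial > self.min_encode_match:
            raise UsageError("k_partial must not exceed min_encode_match")


def classify_case(
    overlap: Tuple[int, int], token: Token, block: DistBlock
) -> CaseLabel:
    """Classify a nonempty overlap of a record token and a dist block."""
    lo, hi = overlap
    if hi < lo:
        raise UsageError(f"empty overlap ({lo}, {hi})")
    if isinstance(token, MatchToken):
        return CaseLabel.A if block.is_match else CaseLabel.C
    return CaseLabel.B if block.is_match else CaseLabel.D


# ---------------------------------------------------------------------------
# lockstep sweep

Segment = Tuple[Token, DistBlock, Optional[int], Optional[int], int]
# (token, block, f_lo, f_hi, seg_len); f_* are Ref1 coordinates for match
# tokens, None for literal tokens (which have no Ref1 extent).


def _sweep(record: CompressedRecord, distr: RefDistribution) -> Iterator[Segment]:
    """Split record tokens at distribution block boundaries.

    Match tokens are cut wherever their Ref1 interval crosses a block
    edge.  A literal token has no Ref1 extent; it is classified against
    the block containing its anchor (one past the previous match's end,
    clamped to Ref1 bounds) and yielded whole.
    """
    blocks = distr.blocks
    b_starts = [blk.b_start for blk in blocks]
    prev_end = -1
    for tok in record.tokens:
        if isinstance(tok, MatchToken):
            f = tok.r_start
            while f <= tok.r_end:
                bi = bisect_right(b_starts, f) - 1
                blk = blocks[bi]
                f_hi = min(tok.r_end, blk.b_end)
                yield tok, blk, f, f_hi, f_hi - f + 1
                f = f_hi + 1
            prev_end = tok.r_end
        else:
            anchor = min(prev_end + 1, distr.encoded_length - 1)
            bi = bisect_right(b_starts, anchor) - 1
            yield tok, blocks[bi], None, None, len(tok)


def _map_to_base(blk: DistBlock, f_lo: int, f_hi: int) -> Tuple[int, int]:
    """Ref2 coordinates of a Ref1 interval inside a match block."""
    off = blk.a_start - blk.b_start
    return f_lo + off, f_hi + off


def _tally(tally: Optional[Dict[str, int]], label: CaseLabel, n: int) -> None:
    if tally is not None:
        tally[label.value] = tally.get(label.value, 0) + n


# ---------------------------------------------------------------------------
# TDM


def transform_tdm(
    record: CompressedRecord,
    distr: RefDistribution,
    ref1: Sequence,
    params: TransformParams,
    tally: Optional[Dict[str, int]] = None,
) -> CompressedRecord:
    """Direct-match transform: remap case A, literalize everything else.

    Case C reads its characters straight from Ref1 (partial
    decompression of the match token); cases B and D copy the literal
    characters through unchanged.
    """
    _check_inputs(record, distr, ref1)
    out: List[Token] = []
    for tok, blk, f_lo, f_hi, seg_len in _sweep(record, distr):
        if isinstance(tok, MatchToken):
            label = classify_case((f_lo, f_hi), tok, blk)
            if label is CaseLabel.A:
                a_lo, a_hi = _map_to_base(blk, f_lo, f_hi)
                out.append(MatchToken(a_lo, a_hi))
            else:  # case C: partial decompression from Ref1
                out.append(LiteralToken(ref1.residues[f_lo : f_hi + 1]))
        else:
            label = CaseLabel.B if blk.is_match else CaseLabel.D
            out.append(LiteralToken(tok.chars))
        _tally(tally, label, seg_len)
    return make_record(record.target_name, distr.base_name, out)


def _check_inputs(
    record: CompressedRecord, distr: RefDistribution, ref1: Sequence
) -> None:
    if record.reference_name != distr.encoded_name:
        raise UsageError(
            f"record is on {record.reference_name!r} but distribution "
            f"encodes {distr.encoded_name!r}"
        )
    if ref1.name != distr.encoded_name:
        raise UsageError(
            f"ref1 is {ref1.name!r}, distribution encodes "
            f"{distr.encoded_name!r}"
        )
    if len(ref1) != distr.encoded_length:
        raise UsageError(
            f"ref1 length {len(ref1)} != distribution encoded length "
            f"{distr.encoded_length}"
        )


# ---------------------------------------------------------------------------
# character-run re-encoding shared by TPI and TGI


def _token_cost(tokens: List[Token]) -> int:
    """Approximate serialized byte cost of a token list.

    Matches cost their two printed coordinates; literals cost their
    characters plus a fixed coordinate overhead.  Used only to decide
    whether a realignment actually pays for itself.
    """
    cost = 0
    for tok in tokens:
        if isinstance(tok, MatchToken):
            cost += 3 + len(str(tok.r_start)) + len(str(tok.r_end))
        else:
            cost += 4 + 12 + len(tok.chars)
    return cost


def partial_index_compress(
    chars: str,
    ref2: Sequence,
    anchor: int,
    prev_token: Optional[MatchToken],
    params: TransformParams,
) -> List[Token]:
    """Re-encode a character run against a window of Ref2 around ``anchor``.

    First the previous match (if given) is extended by direct comparison
    of ``chars`` against Ref2 past its end; when extension consumes
    characters, the returned list *starts with the extended replacement*
    of ``prev_token`` and the caller must substitute it.  Remaining
    characters are greedily re-encoded against a partial index of Ref2
    over ``[anchor - delta, anchor + Delta]`` with k = ``k_partial``,
    preferring candidates nearest the anchor; matches shorter than
    ``min_encode_match`` stay literal.  If the window collapses below
    ``k_partial`` the run is returned as one literal.
    """
    if not chars:
        raise UsageError("empty character run")
    if not 0 <= anchor < len(ref2):
        anchor = max(0, min(anchor, len(ref2) - 1))
    out: List[Token] = []
    ext = 0
    if prev_token is not None:
        ext = longest_common_extension(
            chars, 0, ref2.residues, prev_token.r_end + 1
        )
        if ext:
            out.append(MatchToken(prev_token.r_start, prev_token.r_end + ext))
    rest = chars[ext:]
    if not rest:
        return out
    rest_anchor = anchor + ext
    lo = max(0, rest_anchor - params.delta)
    hi = min(len(ref2), rest_anchor + params.Delta)
    if hi - lo < params.k_partial or len(rest) < params.k_partial:
        out.append(LiteralToken(rest))
        return out
    idx = build_partial_index(
        ref2, lo, hi - lo, IndexParams(k=params.k_partial)
    )
    toks = greedy_factorize(
        rest,
        idx,
        params.min_encode_match,
        tie_break="nearest",
        start_anchor=rest_anchor,
    )
    if _token_cost(toks) >= _token_cost([LiteralToken(rest)]):
        toks = [LiteralToken(rest)]
    out.extend(toks)
    return out


def _flush_chars(
    out: List[Token],
    chars: str,
    anchor: int,
    ref2: Sequence,
    params: TransformParams,
    global_index: Optional[KmerIndex],
    mode: str,
) -> None:
    """Append a pending character run to ``out``, re-encoding when it pays.

    TPI routes the run through :func:`partial_index_compress`; TGI
    realigns runs of at least ``min_realign_len`` against the global
    index (after match extension) and stores shorter runs verbatim.
    """
    if not chars:
        return
    prev = out[-1] if out and isinstance(out[-1], MatchToken) else None
    if mode == "tpi":
        toks = partial_index_compress(chars, ref2, anchor, prev, params)
        if prev is not None and toks and isinstance(toks[0], MatchToken) and (
            toks[0].r_start == prev.r_start and toks[0].r_end > prev.r_end
        ):
            out[-1] = toks.pop(0)
        _extend_merged(out, toks)
        return
    # TGI: extension first (case-D rule), then global realignment
    ext = 0
    if prev is not None:
        ext = longest_common_extension(
            chars, 0, ref2.residues, prev.r_end + 1
        )
        if ext:
            out[-1] = MatchToken(prev.r_start, prev.r_end + ext)
    rest = chars[ext:]
    if not rest:
        return
    if len(rest) < params.min_realign_len:
        _extend_merged(out, [LiteralToken(rest)])
        return
    toks = greedy_factorize(
        rest,
        global_index,
        params.min_encode_match,
        tie_break="nearest",
        start_anchor=anchor + ext,
    )
    if _token_cost(toks) >= _token_cost([LiteralToken(rest)]):
        toks = [LiteralToken(rest)]
    _extend_merged(out, toks)


def _extend_merged(out: List[Token], toks: List[Token]) -> None:
    """Append tokens, merging adjacent literals and contiguous matches."""
    for tok in toks:
        if out:
            last = out[-1]
            if isinstance(tok, LiteralToken) and isinstance(last, LiteralToken):
                out[-1] = LiteralToken(last.chars + tok.chars)
                continue
            if (
                isinstance(tok, MatchToken)
                and isinstance(last, MatchToken)
                and tok.r_start == last.r_end + 1
            ):
                out[-1] = MatchToken(last.r_start, tok.r_end)
                continue
        out.append(tok)


# ---------------------------------------------------------------------------
# TPI


def transform_tpi(
    record: CompressedRecord,
    distr: RefDistribution,
    ref1: Sequence,
    ref2: Sequence,
    params: TransformParams,
    tally: Optional[Dict[str, int]] = None,
) -> CompressedRecord:
    """Partial-index transform: TDM plus windowed realignment of literals."""
    _check_inputs(record, distr, ref1)
    if ref2.name != distr.base_name:
        raise UsageError(
            f"ref2 is {ref2.name!r}, distribution base is "
            f"{distr.base_name!r}"
        )
    out: List[Token] = []
    pending: List[str] = []
    pending_anchor = 0
    anchor = 0  # expected Ref2 position of the next output character
    for tok, blk, f_lo, f_hi, seg_len in _sweep(record, distr):
        if isinstance(tok, MatchToken):
            label = classify_case((f_lo, f_hi), tok, blk)
            if label is CaseLabel.A:
                a_lo, a_hi = _map_to_base(blk, f_lo, f_hi)
                if seg_len >= params.min_encode_match:
                    _flush_chars(
                        out, "".join(pending), pending_anchor, ref2,
                        params, None, "tpi",
                    )
                    pending.clear()
                    _extend_merged(out, [MatchToken(a_lo, a_hi)])
                    anchor = a_hi + 1
                    _tally(tally, label, seg_len)
                    continue
                chars = ref1.residues[f_lo : f_hi + 1]  # short A: literalize
            else:  # case C
                chars = ref1.residues[f_lo : f_hi + 1]
        else:
            label = CaseLabel.B if blk.is_match else CaseLabel.D
            chars = tok.chars
        if not pending:
            pending_anchor = anchor
        pending.append(chars)
        anchor += seg_len
        _tally(tally, label, seg_len)
    _flush_chars(
        out, "".join(pending), pending_anchor, ref2, params, None, "tpi"
    )
    return make_record(record.target_name, distr.base_name, out)


# ---------------------------------------------------------------------------
# TGI


def transform_tgi(
    records: List[CompressedRecord],
    ref1: Sequence,
    ref2: Sequence,
    params: TransformParams,
    index_params: Optional[IndexParams] = None,
    tally: Optional[Dict[str, int]] = None,
) -> List[CompressedRecord]:
    """Global-index transform of a batch of records from Ref1 to Ref2.

    One global Ref2 index is built for the whole batch and reused both to
    compute the Ref1-on-Ref2 distribution and to realign character runs.
    A failing record is logged and skipped; it does not abort the batch.
    """
    if not records:
        return []
    if index_params is None:
        index_params = IndexParams()
    from .compressor import CompressParams, align_references

    index2 = build_global_index(ref2, index_params)  # built exactly once
    cparams = CompressParams(
        index=index_params,
        min_match_len=max(index_params.k, params.min_encode_match),
    )
    distr = align_references(ref1, ref2, index2, cparams)
    out: List[CompressedRecord] = []
    for rec in records:
        try:
            out.append(
                _tgi_one(rec, distr, ref1, ref2, index2, params, tally)
            )
        except Exception:
            logger.exception(
                "TGI failed for record %r; skipping", rec.target_name
            )
    return out


def _tgi_one(
    record: CompressedRecord,
    distr: RefDistribution,
    ref1: Sequence,
    ref2: Sequence,
    index2: KmerIndex,
    params: TransformParams,
    tally: Optional[Dict[str, int]] = None,
) -> CompressedRecord:
    _check_inputs(record, distr, ref1)
    out: List[Token] = []
    pending: List[str] = []
    pending_anchor = 0
    anchor = 0
    seen_match = False
    for tok, blk, f_lo, f_hi, seg_len in _sweep(record, distr):
        if isinstance(tok, MatchToken):
            label = classify_case((f_lo, f_hi), tok, blk)
            if label is CaseLabel.A:
                a_lo, a_hi = _map_to_base(blk, f_lo, f_hi)
                misplaced = (
                    seen_match
                    and abs(a_lo - anchor) > params.misplace_threshold
                )
                if seg_len >= params.min_realign_len and not misplaced:
                    _flush_chars(
                        out, "".join(pending), pending_anchor, ref2,
                        params, index2, "tgi",
                    )
                    pending.clear()
                    _extend_merged(out, [MatchToken(a_lo, a_hi)])
                    anchor = a_hi + 1
                    seen_match = True
                    _tally(tally, label, seg_len)
                    continue
                chars = ref1.residues[f_lo : f_hi + 1]  # short or misplaced
            else:  # case C: partial decompression
                chars = ref1.residues[f_lo : f_hi + 1]
        else:
            label = CaseLabel.B if blk.is_match else CaseLabel.D
            chars = tok.chars
        if not pending:
            pending_anchor = anchor
        pending.append(chars)
        anchor += seg_len
        _tally(tally, label, seg_len)
    _flush_chars(
        out, "".join(pending), pending_anchor, ref2, params, index2, "tgi"
    )
    return make_record(record.target_name, distr.base_name, out)


# ---------------------------------------------------------------------------
# relative coordinates


@dataclass(frozen=True)
class RelativeMatch:
    """A match stored as (offset from previous match's end, length).

    The first match of a record is flagged ``absolute`` and stores its
    absolute start instead of an offset.
    """

    offset: int
    length: int
    absolute: bool = False


RelItem = Union[RelativeMatch, LiteralToken]


@dataclass
class RelativeRecord:
    """A compressed record with relative match coordinates."""

    target_name: str
    reference_name: str
    items: List[RelItem]
    original_length: int


def emit_relative(record: CompressedRecord) -> RelativeRecord:
    """Rewrite match coordinates relative to the previous match's end.

    Nearby matches then need only small integers, which general-purpose
    entropy coding exploits downstream.
    """
    items: List[RelItem] = []
    prev_end: Optional[int] = None
    for tok in record.tokens:
        if isinstance(tok, MatchToken):
            if prev_end is None:
                items.append(
                    RelativeMatch(tok.r_start, len(tok), absolute=True)
                )
            else:
                items.append(RelativeMatch(tok.r_start - prev_end, len(tok)))
            prev_end = tok.r_end
        else:
            items.append(tok)
    return RelativeRecord(
        record.target_name,
        record.reference_name,
        items,
        record.original_length,
    )


def absolutize(rel: RelativeRecord) -> CompressedRecord:
    """Invert :func:`emit_relative`."""
    tokens: List[Token] = []
    prev_end: Optional[int] = None
    for item in rel.items:
        if isinstance(item, RelativeMatch):
            if item.absolute or prev_end is None:
                start = item.offset
            else:
                start = prev_end + item.offset
            tokens.append(MatchToken(start, start + item.length - 1))
            prev_end = start + item.length - 1
        else:
            tokens.append(item)
    return CompressedRecord(
        rel.target_name, rel.reference_name, tokens, rel.original_length
    )
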