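"""Token and block data model for reference-based sequence compression.

A *compressed record* expresses a target sequence against a reference as an
ordered list of match tokens (intervals copied verbatim from the reference)
and literal tokens (characters stored as-is, the "misstr" of the on-disk
triples).  A *reference distribution* expresses one reference against
another as an ordered list of blocks that tile the encoded sequence: match
blocks carry coordinate ranges on both sequences, mismatch blocks carry the
literal characters plus an anchor range on the base reference.

Both structures are lossless: decoding a record against its reference, or
applying a distribution to its base, reproduces the original sequence
exactly.  The canonical on-disk form is textual (``.rgc`` for records,
``.dst`` for distributions); files may additionally be gzip-wrapped and are
unwrapped transparently on read.

Coordinates are 0-based and inclusive on both ends throughout.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence as PySequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: DNA alphabet: the four bases, U, and the IUPAC ambiguity codes
#: (N, R, Y, S, W, K, M, B, D, H, V).  Ambiguity codes are ordinary
#: symbols here: they may appear in references and literals alike.
ALPHABET = frozenset("ACGTURYSWKMBDHVN")


class TransrefError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TransrefError):
    """Malformed serialized record/distribution text."""


class BoundsError(TransrefError):
    """A token or block points outside its reference."""


class ReferenceMismatchError(TransrefError):
    """An operation was given a reference with the wrong name."""


class DegenerateInputError(TransrefError):
    """Input too short/empty for the requested operation."""


class UsageError(TransrefError):
    """An argument violates an operation's contract."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the IUPAC-extended alphabet.

    Residues are folded to uppercase on construction; any character outside
    :data:`ALPHABET` is an ingest error.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise DegenerateInputError(f"sequence {self.name!r} is empty")
        folded = self.residues.upper()
        if folded is not self.residues:
            object.__setattr__(self, "residues", folded)
        bad = set(folded) - ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains characters outside the "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]


@dataclass(frozen=True)
class MatchToken:
    """An interval ``[r_start, r_end]`` copied verbatim from the reference."""

    r_start: int
    r_end: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_start <= self.r_end:
            raise UsageError(
                f"invalid match interval ({self.r_start}, {self.r_end})"
            )

    def __len__(self) -> int:
        return self.r_end - self.r_start + 1


@dataclass(frozen=True)
class LiteralToken:
    """A nonempty run of characters stored verbatim."""

    chars: str

    def __post_init__(self) -> None:
        if not self.chars:
            raise UsageError("empty literal token")

    def __len__(self) -> int:
        return len(self.chars)


Token = Union[MatchToken, LiteralToken]


def merge_tokens(tokens: Iterable[Token]) -> List[Token]:
    """Canonicalize a token stream: concatenate adjacent literal tokens."""
    out: List[Token] = []
    for tok in tokens:
        if (
            isinstance(tok, LiteralToken)
            and out
            and isinstance(out[-1], LiteralToken)
        ):
            out[-1] = LiteralToken(out[-1].chars + tok.chars)
        else:
            out.append(tok)
    return out


@dataclass
class CompressedRecord:
    """An ordered token list encoding one target against one reference.

    Invariants checked on construction: token lengths sum to
    ``original_length`` and no two literal tokens are adjacent (use
    :func:`make_record` to canonicalize an arbitrary stream).
    """

    target_name: str
    reference_name: str
    tokens: List[Token]
    original_length: int

    def __post_init__(self) -> None:
        total = sum(len(t) for t in self.tokens)
        if total != self.original_length:
            raise FormatError(
                f"token lengths sum to {total}, expected {self.original_length}"
            )
        for i in range(1, len(self.tokens)):
            if isinstance(self.tokens[i], LiteralToken) and isinstance(
                self.tokens[i - 1], LiteralToken
            ):
                raise FormatError(f"adjacent literal tokens at index {i}")

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


def make_record(
    target_name: str, reference_name: str, tokens: Iterable[Token]
) -> CompressedRecord:
    """Build a canonical record, merging adjacent literals."""
    merged = merge_tokens(tokens)
    return CompressedRecord(
        target_name=target_name,
        reference_name=reference_name,
        tokens=merged,
        original_length=sum(len(t) for t in merged),
    )


@dataclass(frozen=True)
class DistBlock:
    """One block of a reference distribution.

    ``b_start``/``b_end`` index the encoded sequence; ``a_start``/``a_end``
    index the base reference.  An empty ``misstr`` marks a match block
    (equal-length intervals copied from the base); a nonempty ``misstr``
    marks a mismatch block whose characters are stored verbatim and whose
    base-side range is only an anchor.
    """

    b_start: int
    b_end: int
    a_start: int
    a_end: int
    misstr: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.b_start <= self.b_end:
            raise FormatError(
                f"invalid encoded interval ({self.b_start}, {self.b_end})"
            )
        if self.misstr:
            if len(self.misstr) != self.b_end - self.b_start + 1:
                raise FormatError(
                    "mismatch block length "
                    f"{self.b_end - self.b_start + 1} != misstr length "
                    f"{len(self.misstr)}"
                )
        else:
            if self.b_end - self.b_start != self.a_end - self.a_start:
                raise FormatError(
                    f"match block ({self.b_start},{self.b_end}) has unequal "
                    f"base interval ({self.a_start},{self.a_end})"
                )
            if self.a_start < 0:
                raise FormatError("match block base interval is negative")

    @property
    def is_match(self) -> bool:
        return not self.misstr

    def __len__(self) -> int:
        return self.b_end - self.b_start + 1


@dataclass
class RefDistribution:
    """Ordered blocks encoding one reference (``encoded``) on another (``base``).

    Blocks must tile the encoded sequence exactly: the first starts at 0,
    each next starts one past the previous end, and the last ends at
    ``encoded_length - 1``.
    """

    encoded_name: str
    base_name: str
    blocks: List[DistBlock]
    encoded_length: int

    def __post_init__(self) -> None:
        expect = 0
        for i, blk in enumerate(self.blocks):
            if blk.b_start != expect:
                raise FormatError(
                    f"block {i} starts at {blk.b_start}, expected {expect}"
                )
            expect = blk.b_end + 1
        if expect != self.encoded_length:
            raise FormatError(
                f"blocks end at {expect - 1}, expected {self.encoded_length - 1}"
            )


# ---------------------------------------------------------------------------
# decoding


def decode_record(record: CompressedRecord, reference: Sequence) -> Sequence:
    """Decode a compressed record back to the original target sequence.

    Match tokens copy ``reference[r_start..r_end]``; literal tokens emit
    their characters; parts are concatenated in token order.
    """
    if reference.name != record.reference_name:
        raise ReferenceMismatchError(
            f"record references {record.reference_name!r}, got "
            f"{reference.name!r}"
        )
    parts: List[str] = []
    for i, tok in enumerate(record.tokens):
        if isinstance(tok, MatchToken):
            if tok.r_end >= len(reference):
                raise BoundsError(
                    f"token {i}: match ({tok.r_start},{tok.r_end}) exceeds "
                    f"reference length {len(reference)}"
                )
            parts.append(reference.residues[tok.r_start : tok.r_end + 1])
        else:
            parts.append(tok.chars)
    return Sequence(record.target_name, "".join(parts))


def apply_distribution(distr: RefDistribution, base: Sequence) -> Sequence:
    """Reconstruct the encoded reference from its distribution on ``base``."""
    if base.name != distr.base_name:
        raise ReferenceMismatchError(
            f"distribution is based on {distr.base_name!r}, got {base.name!r}"
        )
    parts: List[str] = []
    for i, blk in enumerate(distr.blocks):
        if blk.is_match:
            if blk.a_end >= len(base):
                raise BoundsError(
                    f"block {i}: base interval ({blk.a_start},{blk.a_end}) "
                    f"exceeds base length {len(base)}"
                )
            parts.append(base.residues[blk.a_start : blk.a_end + 1])
        else:
            parts.append(blk.misstr)
    return Sequence(distr.encoded_name, "".join(parts))


# ---------------------------------------------------------------------------
# serialization

_TUPLE_RE = re.compile(r"\(([^()]*)\)")
_RGC_HEADER_RE = re.compile(
    r"^#rgc v1 target=(?P<target>\S+) ref=(?P<ref>\S+) len=(?P<len>\d+)$"
)
_DST_HEADER_RE = re.compile(
    r"^#dst v1 encoded=(?P<enc>\S+) base=(?P<base>\S+) len=(?P<len>\d+)$"
)


def serialize_record(record: CompressedRecord) -> str:
    """Render a record in the canonical textual dialect.

    Matches are 2-tuples of reference coordinates; literals are 3-tuples
    carrying the target coordinates of the run (redundant, kept for
    readability) plus the characters.
    """
    parts = [
        f"#rgc v1 target={record.target_name} ref={record.reference_name} "
        f"len={record.original_length}\n"
    ]
    t = 0
    for tok in record.tokens:
        if isinstance(tok, MatchToken):
            parts.append(f"({tok.r_start},{tok.r_end})")
        else:
            parts.append(f"({t},{t + len(tok) - 1},{tok.chars})")
        t += len(tok)
    parts.append("\n")
    return "".join(parts)


def parse_record(text: str) -> CompressedRecord:
    """Parse the canonical textual dialect back into a record."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty record text")
    m = _RGC_HEADER_RE.match(lines[0])
    if m is None:
        raise FormatError(f"line 1: bad record header: {lines[0]!r}")
    body = "".join(lines[1:])
    tokens: List[Token] = []
    pos = 0
    t = 0
    for i, tup in enumerate(_TUPLE_RE.finditer(body)):
        fields = tup.group(1).split(",")
        if len(fields) == 2:
            try:
                a, b = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise FormatError(f"tuple {i}: non-numeric coordinate") from exc
            tokens.append(MatchToken(a, b))
            t += b - a + 1
        elif len(fields) == 3:
            try:
                a, b = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise FormatError(f"tuple {i}: non-numeric coordinate") from exc
            chars = fields[2]
            if not chars:
                raise FormatError(f"tuple {i}: empty literal")
            if b - a + 1 != len(chars):
                raise FormatError(
                    f"tuple {i}: literal coordinates ({a},{b}) disagree with "
                    f"{len(chars)} characters"
                )
            if a != t:
                raise FormatError(
                    f"tuple {i}: literal starts at {a}, expected {t}"
                )
            tokens.append(LiteralToken(chars))
            t += len(chars)
        else:
            raise FormatError(
                f"tuple {i}: expected 2 or 3 fields, got {len(fields)}"
            )
        pos = tup.end()
    if body[pos:].strip():
        raise FormatError("trailing garbage after last tuple")
    if not tokens:
        raise FormatError("record has no tokens")
    rec = CompressedRecord(
        target_name=m.group("target"),
        reference_name=m.group("ref"),
        tokens=tokens,
        original_length=t,
    )
    if rec.original_length != int(m.group("len")):
        raise FormatError(
            f"header declares length {m.group('len')}, tokens sum to {t}"
        )
    return rec


def serialize_distribution(distr: RefDistribution) -> str:
    parts = [
        f"#dst v1 encoded={distr.encoded_name} base={distr.base_name} "
        f"len={distr.encoded_length}\n"
    ]
    for blk in distr.blocks:
        if blk.is_match:
            parts.append(f"({blk.b_start},{blk.b_end},{blk.a_start},{blk.a_end})")
        else:
            parts.append(
                f"({blk.b_start},{blk.b_end},{blk.a_start},{blk.a_end},"
                f"{blk.misstr})"
            )
    parts.append("\n")
    return "".join(parts)


def parse_distribution(text: str) -> RefDistribution:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty distribution text")
    m = _DST_HEADER_RE.match(lines[0])
    if m is None:
        raise FormatError(f"line 1: bad distribution header: {lines[0]!r}")
    body = "".join(lines[1:])
    blocks: List[DistBlock] = []
    for i, tup in enumerate(_TUPLE_RE.finditer(body)):
        fields = tup.group(1).split(",")
        if len(fields) not in (4, 5):
            raise FormatError(
                f"block {i}: expected 4 or 5 fields, got {len(fields)}"
            )
        try:
            coords = [int(f) for f in fields[:4]]
        except ValueError as exc:
            raise FormatError(f"block {i}: non-numeric coordinate") from exc
        misstr = fields[4] if len(fields) == 5 else ""
        try:
            blocks.append(DistBlock(*coords, misstr))
        except FormatError as exc:
            raise FormatError(f"block {i}: {exc}") from exc
    if not blocks:
        raise FormatError("distribution has no blocks")
    distr = RefDistribution(
        encoded_name=m.group("enc"),
        base_name=m.group("base"),
        blocks=blocks,
        encoded_length=blocks[-1].b_end + 1,
    )
    if distr.encoded_length != int(m.group("len")):
        raise FormatError(
            f"header declares length {m.group('len')}, blocks tile "
            f"{distr.encoded_length}"
        )
    return distr


def record_size_bytes(record: CompressedRecord) -> int:
    """Size in bytes of the canonical serialization (UTF-8)."""
    return len(serialize_record(record).encode("utf-8"))


def distribution_size_bytes(distr: RefDistribution) -> int:
    return len(serialize_distribution(distr).encode("utf-8"))


# ---------------------------------------------------------------------------
# file I/O

_GZIP_MAGIC = b"\x1f\x8b"


def _read_text(path) -> str:
    """Read a text file, transparently unwrapping a gzip container."""
    raw = Path(path).read_bytes()
    if raw[:2] == _GZIP_MAGIC:
        raw = gzip.decompress(raw)
    return raw.decode("utf-8")


def _write_text(path, text: str, compress: bool = False) -> None:
    data = text.encode("utf-8")
    if compress:
        data = gzip.compress(data)
    Path(path).write_bytes(data)


def read_record(path) -> CompressedRecord:
    return parse_record(_read_text(path))


def write_record(path, record: CompressedRecord, compress: bool = False) -> None:
    _write_text(path, serialize_record(record), compress=compress)


def read_distribution(path) -> RefDistribution:
    return parse_distribution(_read_text(path))


def write_distribution(
    path, distr: RefDistribution, compress: bool = False
) -> None:
    _write_text(path, serialize_distribution(distr), compress=compress)


def read_fasta(path) -> List[Sequence]:
    """Read a (possibly multi-record) FASTA file."""
    seqs = [
        Sequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(path, seqs: PySequence[Sequence], width: int = 70) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
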