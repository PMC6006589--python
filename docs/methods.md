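# Methods

## Data model

A compressed record is an ordered list of tokens: match tokens
`(r_start, r_end)` naming an interval of the reference (0-based,
inclusive on both ends) and literal tokens carrying characters verbatim.
Token lengths sum to the target length, adjacent literals are merged on
construction, and decoding is concatenation of reference slices and
literal runs. A reference distribution is the same idea for a
reference-vs-reference encoding, normalized into blocks that *tile* the
encoded sequence: the first block starts at 0, each next starts one past
the previous end. Match blocks carry equal-length coordinate ranges on
both sequences; mismatch blocks carry the characters plus a base-side
anchor range. The anchor of a mismatch block is set to one past the
previous match's base end; its end is the position before the next match
resumes when that gap is nonempty (substitution-like), otherwise it
spans the literal's own length (insertion-like), clamped to base bounds.
Anchors orient windowed realignment; reconstruction never reads them.

The canonical serialization is textual and self-describing (header line
with names and length, then the tuple stream). `record_size_bytes` is
the byte length of that canonical form; all size comparisons in tests
and reports use it. Bit-packed or entropy-coded output is deliberately
out of scope — any general-purpose stream compressor can wrap the
container, and readers unwrap gzip transparently.

The alphabet is the IUPAC-extended DNA set (A/C/G/T/U plus
R,Y,S,W,K,M,B,D,H,V,N). Ambiguity codes are ordinary symbols: they are
indexed, matched and literalized exactly like bases, and a mismatching
code simply fails match verification.

## Index

The k-mer index is a chained hash table in two fixed-size arrays: a
bucket array indexed directly by hash value, and a memory pool with one
entry per k-mer occurrence (`position`, `next`). The pool is sized
exactly to the number of k-mers in the indexed window — memory is a
linear function of reference length and is never reallocated during the
build, since dynamic reallocation dominates naive builds at genome
scale. Hashing is a polynomial rolling hash (Rabin–Karp) over raw
character codes with base 131; the modulus equals the table size, a
prime of roughly four times the k-mer count (load factor ~0.25), so hash
values index buckets directly. Every lookup verifies candidates by
direct character comparison against the reference, so collisions can
slow a lookup but never corrupt it; a deliberately tiny modulus is part
of the test suite. With `prefer_pos`, results are ordered by distance to
the preferred position with ties to the smaller coordinate — a total
order, so candidate choice is deterministic.

Defaults: k = 16 for global indexes; k = 8 for the small windowed
indexes used in realignment, where short re-anchoring matches matter
more than selectivity. Both are configurable.

## Compression

Greedy longest-match factorization: at each target position, look up
the k-mer, extend every candidate by direct comparison (in doubling
chunks, so the inner loop is C-speed slice comparison), keep the
longest, and emit it if at least `min_match_len` (default k = 16 —
shorter matches are undiscoverable through the index and cost about as
much as the literals they replace). Otherwise one literal character is
emitted and the cursor advances by one; trailing sub-k bases are
literals. Equally long candidates resolve to the one nearest the
running reference pointer, then the smaller position. At most
`max_candidates` (32) hits are extended per lookup, taken in preference
order; this only prunes far-away candidates in highly repetitive
references and keeps worst-case cost bounded. The same routine, with a
start anchor, re-encodes fragments during transformation, which keeps
one compressor as the single oracle for everything.

## Transforms

Both encodings tile Ref1's coordinates, so a lockstep sweep splits the
record's match tokens at every distribution block edge. A literal token
of T has no Ref1 extent; it is classified against the block containing
the position one past the previous match's end (clamped), and passes
through whole. The sweep partitions the target exactly once — asserted
in tests by summing overlap lengths.

* **TDM**: case A (match over match block) remaps by the block's
  constant offset; case C (match over mismatch block) partially
  decompresses from Ref1, which is held in memory; cases B/D copy the
  literal characters.
* **TPI**: tracks the *expected* Ref2 position of the next output
  character (last emitted match end + 1, advanced by run lengths).
  Case-A overlaps shorter than `min_encode_match` (16) are folded into
  the surrounding character run. Pending runs are flushed by (1)
  extending the previous match by direct comparison, then (2) greedy
  re-encoding against a partial Ref2 index over
  `[anchor − delta, anchor + Delta]` (defaults 100 and 4096: the window
  comfortably covers indel displacement at percent-scale divergence
  while staying cheap to build). If the re-encoding would serialize
  larger than the plain literal, the literal wins — realignment never
  degrades size.
* **TGI**: one global Ref2 index per batch, reused for the distribution
  and for realignment. Case-A matches are kept only when at least
  `min_realign_len` (32) long and not *misplaced* (mapped further than
  `misplace_threshold` = 1000 from the running anchor); otherwise they
  are decompressed into the character stream. Runs shorter than
  `min_realign_len` are stored verbatim (a global lookup per tiny run
  costs more than it saves); longer runs are extended then realigned
  globally with nearest-to-anchor preference and the same cost guard.
  Failures are isolated per record: a bad record is logged and skipped,
  never aborting the batch. `emit_relative`/`absolutize` convert match
  starts to offsets from the previous match's end (first match absolute,
  flagged), an invertible preparation for downstream delta/entropy
  coding.

None of `delta`, `Delta`, `min_realign_len` or `misplace_threshold` has
a canonical published value; the defaults above were fixed once from the
divergence regime the generator emulates and are all configurable.

## Synthetic data

`generate_reference` draws i.i.d. bases; `mutate` applies per-base SNPs
(1%), insertion/deletion starts (0.1% each, geometric lengths with mean
3) and ambiguity-code injection (0.01%), echoing ~99.5% intra-species
similarity. Every mutate call returns a replayable edit script, and an
independent replay function reproduces the output in tests. Fixtures
chain Ref2 → Ref1 → targets and pre-compress each target on Ref1,
verifying decode equality before returning. All randomness flows from
explicit seeds through `numpy` generators; derived seeds are spawned
from a `SeedSequence` and kept below 2³¹.

What the generator does *not* emulate: structural variants,
recombination, repeat families (beyond chance repeats), chromosome-scale
lengths, and GC/content biases. Passing tests therefore demonstrate
correctness of the algorithms and the expected size orderings under
percent-scale point divergence — not compression ratios on real human
genomes, where repeat structure makes candidate lists longer and match
placement harder.

## Numerical and procedural choices

* Coordinates 0-based inclusive everywhere; serialization round-trips
  byte-identically on canonical text.
* Greedy compression is fully deterministic: identical inputs and
  parameters give byte-identical output.
* Degenerate inputs: targets shorter than k compress to a single
  literal; realignment windows that collapse below `k_partial` return
  the run as one literal rather than erroring; empty TGI batches return
  empty lists.
* Benchmark reports verify decode equality for every output before
  reporting any number, and never assert timings (host-dependent);
  index-build time is reported separately from transform time.
* Test problem sizes: the standard suite is 20 triplets of 10 kb at the
  default rates; losslessness is additionally checked on 200+ pairs of
  1–50 kb across SNP rates 0–5%, and index completeness against naive
  enumeration on sequences up to 60 kb for k ∈ {4, 8, 16}.

## Known limitations

* Greedy parsing is not optimal; no affine-gap model.
* Transform chains across more than two references are out of scope, as
  are thread/process pools and disk-serialized indexes.
* TPI rebuilds a small window index per flushed run; for very fragmented
  records TGI's single global index is the better tool — consistent with
  the small-scale vs large-scale division of labor between the methods.
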