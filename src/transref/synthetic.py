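"""Seeded generators of reference triplets and compressed-record banks.

Intra-species genomes are overwhelmingly similar (on the order of 99.5%
identity for humans), which is exactly the regime referential compression
and re-referencing target.  The generators emulate that regime: a base
reference Ref2 is drawn i.i.d. over the DNA alphabet, Ref1 is a mutated
copy of Ref2, and each target is a mutated copy of Ref1.  Mutations are
per-base substitutions (SNPs), geometric-length insertions and deletions,
and a trickle of IUPAC ambiguity codes (N, U, R, S, K) so the special-
character path is exercised.  Every mutate call returns a replayable edit
script, and everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence as PySequence, Tuple

import numpy as np

from .compressor import CompressParams, compress_sequence
from .encoding import (
    CompressedRecord,
    Sequence,
    UsageError,
    decode_record,
)
from .kmer_index import build_global_index

BASES = "ACGT"
AMBIGUITY_CODES = "NURSK"

#: One edit event: (kind, src_pos, out_pos, payload).  ``src_pos`` indexes
#: the input sequence, ``out_pos`` the output; payload is the substituted
#: character, inserted string, or deletion length.
Event = Tuple[str, int, int, object]


@dataclass(frozen=True)
class MutationSpec:
    """Per-base mutation rates and the seed driving them.

    Defaults echo percent-scale intra-species divergence: 1% SNPs, 0.1%
    insertion starts, 0.1% deletion starts, geometric indel lengths with
    mean 3, and 0.01% ambiguity-code injection.
    """

    snp_rate: float = 0.01
    ins_rate: float = 0.001
    del_rate: float = 0.001
    indel_len_mean: float = 3.0
    ambig_rate: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "ins_rate", "del_rate", "ambig_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise UsageError(f"{name} must be in [0, 1), got {r}")
        if self.snp_rate + self.ins_rate + self.del_rate + self.ambig_rate >= 1.0:
            raise UsageError("mutation rates must sum to less than 1")
        if self.indel_len_mean < 1.0:
            raise UsageError("indel_len_mean must be >= 1")


def generate_reference(
    length: int,
    seed: int,
    alphabet_weights: Optional[PySequence[float]] = None,
    name: str = "ref",
) -> Sequence:
    """Draw a reference i.i.d. over A/C/G/T (optionally weighted)."""
    if length < 1:
        raise UsageError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    if alphabet_weights is None:
        p = None
    else:
        w = np.asarray(alphabet_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or w.sum() <= 0:
            raise UsageError("alphabet_weights must be 4 nonnegative values")
        p = w / w.sum()
    codes = rng.choice(np.frombuffer(BASES.encode(), dtype=np.uint8),
                       size=length, p=p)
    return Sequence(name, codes.tobytes().decode())


def mutate(
    seq: Sequence, spec: MutationSpec, name: Optional[str] = None
) -> Tuple[Sequence, List[Event]]:
    """Apply seeded point mutations and indels; return output plus log.

    The log is a replayable edit script: :func:`replay` applied to the
    input reproduces the output exactly.
    """
    rng = np.random.default_rng(spec.seed)
    s = seq.residues
    n = len(s)
    out: List[str] = []
    log: List[Event] = []
    t_del = spec.del_rate
    t_ins = t_del + spec.ins_rate
    t_snp = t_ins + spec.snp_rate
    t_amb = t_snp + spec.ambig_rate
    i = 0
    while i < n:
        r = rng.random()
        if r < t_del:
            glen = min(int(rng.geometric(1.0 / spec.indel_len_mean)), n - i)
            log.append(("del", i, len(out), glen))
            i += glen
            continue
        if r < t_ins:
            glen = int(rng.geometric(1.0 / spec.indel_len_mean))
            ins = "".join(BASES[j] for j in rng.integers(0, 4, size=glen))
            log.append(("ins", i, len(out), ins))
            out.append(ins)
            out.append(s[i])
        elif r < t_snp:
            alts = [b for b in BASES if b != s[i]]
            ch = alts[int(rng.integers(0, len(alts)))]
            log.append(("snp", i, len(out), ch))
            out.append(ch)
        elif r < t_amb:
            ch = AMBIGUITY_CODES[int(rng.integers(0, len(AMBIGUITY_CODES)))]
            log.append(("amb", i, len(out), ch))
            out.append(ch)
        else:
            out.append(s[i])
        i += 1
    residues = "".join(out)
    return Sequence(name or f"{seq.name}_mut", residues), log


def replay(seq: Sequence, log: List[Event], name: str = "replayed") -> Sequence:
    """Independently re-apply an edit script to the original sequence."""
    events: Dict[int, Event] = {ev[1]: ev for ev in log}
    s = seq.residues
    out: List[str] = []
    i = 0
    n = len(s)
    while i < n:
        ev = events.get(i)
        if ev is None:
            out.append(s[i])
            i += 1
            continue
        kind, _, _, payload = ev
        if kind == "del":
            i += int(payload)
        elif kind == "ins":
            out.append(str(payload))
            out.append(s[i])
            i += 1
        else:  # snp / amb
            out.append(str(payload))
            i += 1
    return Sequence(name, "".join(out))


@dataclass
class BankFixture:
    """A synthetic gene-bank: Ref2 → Ref1 → targets, pre-compressed on Ref1."""

    ref1: Sequence
    ref2: Sequence
    targets: List[Sequence]
    records_on_ref1: List[CompressedRecord]
    truth: List[List[Event]]  # per-target edit scripts (Ref1 → target)


def make_bank_fixture(
    n_targets: int,
    length: int,
    spec_ref1_from_ref2: MutationSpec,
    spec_target_from_ref1: MutationSpec,
    seed: int,
    compress_params: Optional[CompressParams] = None,
) -> BankFixture:
    """Generate Ref2, derive Ref1 and targets, compress targets on Ref1.

    Per-step seeds are spawned deterministically from ``seed``; the rates
    in the two mutation specs control Ref2→Ref1 and Ref1→target
    divergence respectively.  Every record is verified to decode back to
    its target before the fixture is returned.
    """
    if n_targets < 1:
        raise UsageError("n_targets must be >= 1")
    if compress_params is None:
        compress_params = CompressParams()
    child = np.random.SeedSequence(seed).generate_state(n_targets + 2)
    # keep derived seeds below 2**31 for portability of downstream seeding
    child = [int(c) % (2**31) for c in child]
    ref2 = generate_reference(length, child[0], name="ref2")
    ref1, _ = mutate(
        ref2, replace(spec_ref1_from_ref2, seed=child[1]), name="ref1"
    )
    index1 = build_global_index(ref1, compress_params.index)
    targets: List[Sequence] = []
    records: List[CompressedRecord] = []
    truth: List[List[Event]] = []
    for t in range(n_targets):
        tgt, log = mutate(
            ref1,
            replace(spec_target_from_ref1, seed=child[2 + t]),
            name=f"target_{t}",
        )
        rec = compress_sequence(tgt, ref1, index1, compress_params)
        if decode_record(rec, ref1).residues != tgt.residues:
            raise AssertionError(
                f"fixture self-check failed for target {t}"
            )  # pragma: no cover - compressor is lossless by construction
        targets.append(tgt)
        records.append(rec)
        truth.append(log)
    return BankFixture(
        ref1=ref1, ref2=ref2, targets=targets,
        records_on_ref1=records, truth=truth,
    )
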