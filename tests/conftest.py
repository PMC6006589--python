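"""Shared fixtures: small sequences and the standard synthetic suite."""

from __future__ import annotations

import random

import pytest

import transref as tr

STANDARD_SEEDS = tuple(range(1, 21))
STANDARD_LENGTH = 10_000


def random_dna(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_random_record(seed: int) -> tr.CompressedRecord:
    """A random valid record: alternating match/literal tokens."""
    rng = random.Random(seed)
    tokens = []
    want_match = rng.random() < 0.5
    for _ in range(rng.randint(1, 12)):
        if want_match:
            start = rng.randint(0, 5000)
            tokens.append(tr.MatchToken(start, start + rng.randint(0, 400)))
        else:
            tokens.append(
                tr.LiteralToken(random_dna(rng.randint(1, 30), rng.random()))
            )
        want_match = not want_match
    return tr.make_record(f"t{seed}", "ref", tokens)


@pytest.fixture(scope="session")
def standard_suite():
    """20 triplets (seeds 1-20, 10 kb, 1% SNP / 0.1% indel per step),
    with all four methods' outputs and sizes precomputed once."""
    cparams = tr.CompressParams()
    tparams = tr.TransformParams()
    suite = []
    for seed in STANDARD_SEEDS:
        fx = tr.make_bank_fixture(
            n_targets=1,
            length=STANDARD_LENGTH,
            spec_ref1_from_ref2=tr.MutationSpec(),
            spec_target_from_ref1=tr.MutationSpec(),
            seed=seed,
            compress_params=cparams,
        )
        index2 = tr.build_global_index(fx.ref2, cparams.index)
        distr = tr.align_references(fx.ref1, fx.ref2, index2, cparams)
        rec = fx.records_on_ref1[0]
        outputs = {
            "baseline": tr.recompress_baseline(
                rec, fx.ref1, fx.ref2, index2, cparams
            ),
            "tdm": tr.transform_tdm(rec, distr, fx.ref1, tparams),
            "tpi": tr.transform_tpi(rec, distr, fx.ref1, fx.ref2, tparams),
            "tgi": tr.transform_tgi(
                [rec], fx.ref1, fx.ref2, tparams,
                index_params=cparams.index,
            )[0],
        }
        sizes = {m: tr.record_size_bytes(r) for m, r in outputs.items()}
        suite.append(
            {
                "seed": seed,
                "fixture": fx,
                "distr": distr,
                "record": rec,
                "outputs": outputs,
                "sizes": sizes,
            }
        )
    return suite
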