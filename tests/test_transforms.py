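"""TDM / TPI / TGI re-referencing: case logic, losslessness, sizes."""

import random

import pytest

import transref as tr
from transref import kmer_index
from transref.transforms import CaseLabel, RelativeMatch, _sweep

from conftest import random_dna, make_random_record


def identity_distribution(ref: tr.Sequence) -> tr.RefDistribution:
    return tr.RefDistribution(
        ref.name, "ref2", [tr.DistBlock(0, len(ref) - 1, 0, len(ref) - 1)],
        len(ref),
    )


def make_triplet(seed, length=4000, snp=0.01, indel=0.001):
    fx = tr.make_bank_fixture(
        n_targets=1, length=length,
        spec_ref1_from_ref2=tr.MutationSpec(
            snp_rate=snp, ins_rate=indel, del_rate=indel
        ),
        spec_target_from_ref1=tr.MutationSpec(
            snp_rate=snp, ins_rate=indel, del_rate=indel
        ),
        seed=seed,
    )
    cparams = tr.CompressParams()
    idx2 = tr.build_global_index(fx.ref2, cparams.index)
    distr = tr.align_references(fx.ref1, fx.ref2, idx2, cparams)
    return fx, distr


class TestClassifyCase:
    match_tok = tr.MatchToken(0, 9)
    lit_tok = tr.LiteralToken("ACGT")
    match_blk = tr.DistBlock(0, 9, 0, 9)
    mis_blk = tr.DistBlock(0, 3, 0, 3, "ACGT")

    @pytest.mark.parametrize(
        "token,block,expected",
        [
            (match_tok, match_blk, CaseLabel.A),
            (lit_tok, match_blk, CaseLabel.B),
            (match_tok, mis_blk, CaseLabel.C),
            (lit_tok, mis_blk, CaseLabel.D),
        ],
        ids=["A", "B", "C", "D"],
    )
    def test_case_table(self, token, block, expected):
        assert tr.classify_case((0, 3), token, block) is expected

    def test_empty_overlap_rejected(self):
        with pytest.raises(tr.UsageError):
            tr.classify_case((5, 4), self.match_tok, self.match_blk)


class TestSweep:
    def test_partition_covers_target_exactly(self):
        fx, distr = make_triplet(seed=5)
        rec = fx.records_on_ref1[0]
        total = sum(seg_len for *_, seg_len in _sweep(rec, distr))
        assert total == rec.original_length


class TestTDM:
    def test_identity_distribution_is_identity(self):
        ref1 = tr.Sequence("ref1", random_dna(500, seed=1))
        rec = tr.make_record(
            "t", "ref1",
            [tr.MatchToken(0, 199), tr.LiteralToken("NN"),
             tr.MatchToken(200, 499)],
        )
        out = tr.transform_tdm(
            rec, identity_distribution(ref1), ref1, tr.TransformParams()
        )
        assert out.tokens == rec.tokens
        assert out.reference_name == "ref2"

    def test_pure_literal_record_passes_through(self):
        ref1 = tr.Sequence("ref1", random_dna(100, seed=2))
        rec = tr.make_record("t", "ref1", [tr.LiteralToken("T" * 40)])
        out = tr.transform_tdm(
            rec, identity_distribution(ref1), ref1, tr.TransformParams()
        )
        assert out.tokens == [tr.LiteralToken("T" * 40)]

    def test_decode_equality_and_case_a_slices(self):
        fx, distr = make_triplet(seed=3, length=10_000)
        rec = fx.records_on_ref1[0]
        tally = {}
        out = tr.transform_tdm(
            rec, distr, fx.ref1, tr.TransformParams(), tally=tally
        )
        target = fx.targets[0].residues
        decoded = tr.decode_record(out, fx.ref2)
        assert decoded.residues == target
        # every emitted match is a verbatim Ref2 slice of the target
        t = 0
        for tok in out.tokens:
            if isinstance(tok, tr.MatchToken):
                assert (
                    fx.ref2.residues[tok.r_start : tok.r_end + 1]
                    == target[t : t + len(tok)]
                )
            t += len(tok)
        assert tally.get("A", 0) > 0
        assert sum(tally.values()) == rec.original_length


class TestPartialIndexCompress:
    def test_window_slice_becomes_single_match(self):
        ref2 = tr.Sequence("ref2", random_dna(3000, seed=7))
        chars = ref2.residues[1000:1100]
        toks = tr.partial_index_compress(
            chars, ref2, 1000, None, tr.TransformParams()
        )
        assert toks == [tr.MatchToken(1000, 1099)]

    def test_pure_extension_of_previous_match(self):
        ref2 = tr.Sequence("ref2", random_dna(3000, seed=7))
        prev = tr.MatchToken(900, 999)
        toks = tr.partial_index_compress(
            ref2.residues[1000:1050], ref2, 1000, prev, tr.TransformParams()
        )
        assert toks == [tr.MatchToken(900, 1049)]

    def test_foreign_chars_stay_literal(self):
        ref2 = tr.Sequence("ref2", random_dna(3000, seed=8))
        toks = tr.partial_index_compress(
            "U" * 30, ref2, 1500, None, tr.TransformParams()
        )
        assert toks == [tr.LiteralToken("U" * 30)]

    def test_scattered_snps_decode_with_bounded_literals(self):
        rng = random.Random(11)
        ref2 = tr.Sequence("ref2", random_dna(6000, seed=11))
        params = tr.TransformParams()
        lo = 2000
        chars = list(ref2.residues[lo : lo + 300])
        for pos in rng.sample(range(20, 280), 3):
            chars[pos] = "A" if chars[pos] != "A" else "C"
        chars = "".join(chars)
        toks = tr.partial_index_compress(chars, ref2, lo, None, params)
        decoded = "".join(
            ref2.residues[t.r_start : t.r_end + 1]
            if isinstance(t, tr.MatchToken) else t.chars
            for t in toks
        )
        assert decoded == chars
        lit_total = sum(
            len(t) for t in toks if isinstance(t, tr.LiteralToken)
        )
        # greedy re-anchoring loses at most k_partial-1 flank per SNP side
        assert lit_total <= 3 + 2 * (params.k_partial - 1) * 3


class TestTPI:
    def test_identity_distribution_matches_tdm(self):
        ref1 = tr.Sequence("ref1", random_dna(2000, seed=21))
        ref2 = tr.Sequence("ref2", ref1.residues)
        rec = tr.make_record("t", "ref1", [tr.MatchToken(0, 1999)])
        distr = identity_distribution(ref1)
        params = tr.TransformParams()
        tdm = tr.transform_tdm(rec, distr, ref1, params)
        tpi = tr.transform_tpi(rec, distr, ref1, ref2, params)
        assert tpi.tokens == tdm.tokens == rec.tokens

    def test_recovers_block_shared_with_ref2_only(self):
        """A region where T is close to Ref2 but foreign to Ref1: TDM must
        literalize it, TPI re-matches it through the windowed index."""
        base = random_dna(3000, seed=23)
        foreign = random_dna(200, seed=24)  # present in ref2 and T only
        ref2 = tr.Sequence("ref2", base[:1500] + foreign + base[1500:])
        ref1 = tr.Sequence("ref1", base)
        target = tr.Sequence("t", ref2.residues)
        cparams = tr.CompressParams()
        idx1 = tr.build_global_index(ref1, cparams.index)
        rec = tr.compress_sequence(target, ref1, idx1, cparams)
        idx2 = tr.build_global_index(ref2, cparams.index)
        distr = tr.align_references(ref1, ref2, idx2, cparams)
        params = tr.TransformParams()
        tdm = tr.transform_tdm(rec, distr, ref1, params)
        tpi = tr.transform_tpi(rec, distr, ref1, ref2, params)
        assert tr.decode_record(tdm, ref2).residues == target.residues
        assert tr.decode_record(tpi, ref2).residues == target.residues
        assert tr.record_size_bytes(tpi) < tr.record_size_bytes(tdm)

    def test_standard_suite_decodes_and_never_larger_than_tdm(
        self, standard_suite
    ):
        tdm_total = sum(e["sizes"]["tdm"] for e in standard_suite)
        tpi_total = sum(e["sizes"]["tpi"] for e in standard_suite)
        assert tpi_total <= tdm_total


class TestTGI:
    def test_same_references_yield_long_matches(self):
        ref = tr.generate_reference(4000, seed=31, name="ref1")
        ref2 = tr.Sequence("ref2", ref.residues)
        tgt, _ = tr.mutate(ref, tr.MutationSpec(seed=32), name="t")
        idx1 = tr.build_global_index(ref, tr.IndexParams())
        rec = tr.compress_sequence(tgt, ref, idx1, tr.CompressParams())
        out = tr.transform_tgi([rec], ref, ref2, tr.TransformParams())[0]
        assert tr.decode_record(out, ref2).residues == tgt.residues
        match_bases = sum(
            len(t) for t in out.tokens if isinstance(t, tr.MatchToken)
        )
        assert match_bases / rec.original_length > 0.9

    def test_literal_run_recovered_through_global_lookup(self):
        base = random_dna(4000, seed=33)
        shared = random_dna(500, seed=34)
        ref1 = tr.Sequence("ref1", base)
        ref2 = tr.Sequence("ref2", base + shared)  # run exists only in ref2
        target = tr.Sequence("t", base[:1000] + shared + base[1000:])
        cparams = tr.CompressParams()
        idx1 = tr.build_global_index(ref1, cparams.index)
        rec = tr.compress_sequence(target, ref1, idx1, cparams)
        k = cparams.index.k
        out = tr.transform_tgi(
            [rec], ref1, ref2, tr.TransformParams(),
            index_params=cparams.index,
        )[0]
        assert tr.decode_record(out, ref2).residues == target.residues
        longest = max(
            (len(t) for t in out.tokens
             if isinstance(t, tr.MatchToken) and t.r_start >= 4000),
            default=0,
        )
        assert longest >= 500 - 2 * (k - 1)

    def test_batch_builds_exactly_one_global_index(self):
        fx = tr.make_bank_fixture(
            n_targets=20, length=3000,
            spec_ref1_from_ref2=tr.MutationSpec(),
            spec_target_from_ref1=tr.MutationSpec(),
            seed=77,
        )
        before = tr.global_build_count()
        outs = tr.transform_tgi(
            fx.records_on_ref1, fx.ref1, fx.ref2, tr.TransformParams()
        )
        assert tr.global_build_count() - before == 1
        assert len(outs) == 20
        for out, tgt in zip(outs, fx.targets):
            assert tr.decode_record(out, fx.ref2).residues == tgt.residues

    def test_empty_batch(self):
        ref = tr.generate_reference(100, seed=1, name="r1")
        assert tr.transform_tgi([], ref, ref, tr.TransformParams()) == []

    def test_standard_suite_never_larger_than_tdm(self, standard_suite):
        tdm_total = sum(e["sizes"]["tdm"] for e in standard_suite)
        tgi_total = sum(e["sizes"]["tgi"] for e in standard_suite)
        assert tgi_total <= tdm_total


class TestDegenerateInputs:
    def test_target_shorter_than_k_transforms_losslessly(self):
        fx, distr = make_triplet(seed=41, length=1000)
        short = tr.Sequence("s", "ACGTACG")  # shorter than k=16
        idx1 = tr.build_global_index(fx.ref1, tr.IndexParams())
        rec = tr.compress_sequence(short, fx.ref1, idx1, tr.CompressParams())
        params = tr.TransformParams()
        for out in (
            tr.transform_tdm(rec, distr, fx.ref1, params),
            tr.transform_tpi(rec, distr, fx.ref1, fx.ref2, params),
            tr.transform_tgi([rec], fx.ref1, fx.ref2, params)[0],
        ):
            assert tr.decode_record(out, fx.ref2).residues == "ACGTACG"

    def test_record_ending_in_literal(self):
        fx, distr = make_triplet(seed=43, length=2000)
        tail = tr.Sequence("s", fx.ref1.residues[:500] + "NNNNNNN")
        idx1 = tr.build_global_index(fx.ref1, tr.IndexParams())
        rec = tr.compress_sequence(tail, fx.ref1, idx1, tr.CompressParams())
        assert isinstance(rec.tokens[-1], tr.LiteralToken)
        params = tr.TransformParams()
        out = tr.transform_tpi(rec, distr, fx.ref1, fx.ref2, params)
        assert tr.decode_record(out, fx.ref2).residues == tail.residues


class TestRelativeCoordinates:
    def test_single_match_first_form(self):
        rec = tr.make_record("t", "r", [tr.MatchToken(0, 99)])
        rel = tr.emit_relative(rec)
        assert rel.items == [RelativeMatch(0, 100, absolute=True)]

    def test_adjacent_matches_offset_one(self):
        rec = tr.CompressedRecord(
            "t", "r", [tr.MatchToken(0, 9), tr.MatchToken(10, 19)], 20
        )
        rel = tr.emit_relative(rec)
        assert rel.items[1] == RelativeMatch(1, 10)

    @pytest.mark.parametrize("seed", range(100))
    def test_roundtrip_identity(self, seed):
        rec = make_random_record(1000 + seed)
        assert tr.absolutize(tr.emit_relative(rec)) == rec
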