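"""Benchmark harness: run all re-referencing methods on one fixture.

Reports, per method, wall time (index build separated from transform),
output sizes in canonical bytes, compression ratios (original bytes over
compressed bytes) and case tallies.  Every output is verified to decode
to its target before any number is reported; timing is informational
only — it depends on the host and is never asserted by tests.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .compressor import (
    CompressParams,
    align_references,
    recompress_baseline,
)
from .encoding import (
    CompressedRecord,
    TransrefError,
    decode_record,
    record_size_bytes,
)
from .kmer_index import build_global_index
from .synthetic import BankFixture
from .transforms import (
    TransformParams,
    transform_tdm,
    transform_tgi,
    transform_tpi,
)

METHODS = ("baseline", "tdm", "tpi", "tgi")


class CorrectnessError(TransrefError):
    """A method produced output that does not decode to its target."""


@dataclass
class BenchReport:
    """Aggregate measurements for one fixture run."""

    n_records: int
    original_bytes: int
    transform_seconds: Dict[str, float] = field(default_factory=dict)
    index_seconds: Dict[str, float] = field(default_factory=dict)
    output_bytes: Dict[str, int] = field(default_factory=dict)
    ratios: Dict[str, float] = field(default_factory=dict)
    case_tallies: Dict[str, Dict[str, int]] = field(default_factory=dict)
    peak_index_entries: int = 0

    def to_tsv(self) -> str:
        lines = ["method\ttransform_s\tindex_s\tbytes\tratio"]
        for m in METHODS:
            lines.append(
                f"{m}\t{self.transform_seconds.get(m, 0.0):.4f}"
                f"\t{self.index_seconds.get(m, 0.0):.4f}"
                f"\t{self.output_bytes.get(m, 0)}"
                f"\t{self.ratios.get(m, 0.0):.4f}"
            )
        return "\n".join(lines) + "\n"


def _verify(
    outputs: List[CompressedRecord], fixture: BankFixture, method: str
) -> None:
    for rec, tgt in zip(outputs, fixture.targets):
        got = decode_record(rec, fixture.ref2).residues
        if got != tgt.residues:
            raise CorrectnessError(
                f"{method}: record {rec.target_name!r} does not decode to "
                "its target"
            )


def run_benchmark(
    fixture: BankFixture,
    compress_params: Optional[CompressParams] = None,
    transform_params: Optional[TransformParams] = None,
) -> BenchReport:
    """Run baseline, TDM, TPI and TGI on identical inputs and measure."""
    if compress_params is None:
        compress_params = CompressParams()
    if transform_params is None:
        transform_params = TransformParams()
    ref1, ref2 = fixture.ref1, fixture.ref2
    records = fixture.records_on_ref1
    report = BenchReport(
        n_records=len(records),
        original_bytes=sum(len(t) for t in fixture.targets),
    )

    t0 = time.perf_counter()
    index2 = build_global_index(ref2, compress_params.index)
    shared_index_s = time.perf_counter() - t0
    report.peak_index_entries = index2.n_entries

    t0 = time.perf_counter()
    distr = align_references(ref1, ref2, index2, compress_params)
    align_s = time.perf_counter() - t0

    # baseline: decompress-and-recompress (needs the index, not the distr)
    t0 = time.perf_counter()
    base_out = [
        recompress_baseline(rec, ref1, ref2, index2, compress_params)
        for rec in records
    ]
    report.transform_seconds["baseline"] = time.perf_counter() - t0
    report.index_seconds["baseline"] = shared_index_s
    _verify(base_out, fixture, "baseline")

    tally: Dict[str, int] = {}
    t0 = time.perf_counter()
    tdm_out = [
        transform_tdm(rec, distr, ref1, transform_params, tally=tally)
        for rec in records
    ]
    report.transform_seconds["tdm"] = time.perf_counter() - t0
    report.index_seconds["tdm"] = shared_index_s + align_s
    report.case_tallies["tdm"] = dict(tally)
    _verify(tdm_out, fixture, "tdm")

    tally = {}
    t0 = time.perf_counter()
    tpi_out = [
        transform_tpi(rec, distr, ref1, ref2, transform_params, tally=tally)
        for rec in records
    ]
    report.transform_seconds["tpi"] = time.perf_counter() - t0
    report.index_seconds["tpi"] = shared_index_s + align_s
    report.case_tallies["tpi"] = dict(tally)
    _verify(tpi_out, fixture, "tpi")

    tally = {}
    t0 = time.perf_counter()
    tgi_out = transform_tgi(
        records, ref1, ref2, transform_params,
        index_params=compress_params.index, tally=tally,
    )
    report.transform_seconds["tgi"] = time.perf_counter() - t0
    report.index_seconds["tgi"] = 0.0  # TGI builds its own (timed inside)
    report.case_tallies["tgi"] = dict(tally)
    if len(tgi_out) != len(records):
        raise CorrectnessError("tgi: batch dropped records")
    _verify(tgi_out, fixture, "tgi")

    for method, outs in (
        ("baseline", base_out),
        ("tdm", tdm_out),
        ("tpi", tpi_out),
        ("tgi", tgi_out),
    ):
        total = sum(record_size_bytes(r) for r in outs)
        report.output_bytes[method] = total
        report.ratios[method] = report.original_bytes / total
    return report
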