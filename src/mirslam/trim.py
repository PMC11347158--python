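"""Raw-read cleanup: 3' adapter removal, randomized-base clipping, length filter.

NEXTflex-style libraries place 4 randomized nucleotides on each side of the
insert.  The processing order mirrors the tool chain this reproduces: the
adapter is removed first, then 4 bases are clipped from the 3' end, the
``> max_length`` filter is applied, 4 bases are clipped from the 5' end, and
finally too-short inserts are dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .config import TrimParams

DISCARD_REASONS = ("none", "no_adapter", "too_long", "too_short")


@dataclass
class TrimmedRead:
    read_id: str
    insert_seq: str          # empty when discarded
    discard_reason: str      # one of DISCARD_REASONS

    @property
    def kept(self) -> bool:
        return self.discard_reason == "none"


def find_adapter_start(seq: str, params: TrimParams) -> int:
    """Start of the longest read suffix matching a prefix of the adapter.

    A suffix starting at ``i`` matches when, over the overlap ``w``
    (read length − i, capped at the adapter length), the number of
    mismatches is at most ``floor(adapter_mismatch_rate * w)`` and
    ``w >= min_overlap``.  Returns -1 when no suffix qualifies.
    """
    adapter = params.adapter_seq
    n = len(seq)
    last = n - params.min_overlap
    # fast path: an exact full-adapter hit; only earlier starts then need the scan
    exact = seq.find(adapter)
    limit = exact if exact != -1 else last + 1
    for i in range(min(limit, last + 1)):
        w = min(n - i, len(adapter))
        budget = int(params.adapter_mismatch_rate * w)
        mm = 0
        for j in range(w):
            if seq[i + j] != adapter[j]:
                mm += 1
                if mm > budget:
                    break
        else:
            return i
    return exact


def remove_adapter(seq: str, params: TrimParams) -> tuple[str, bool]:
    """Remove the 3' adapter; returns ``(trimmed, found)``.

    When no adapter is detected the sequence passes through unchanged with
    ``found=False`` so the caller's no-adapter policy can decide its fate.
    """
    i = find_adapter_start(seq, params)
    if i < 0:
        return seq, False
    return seq[:i], True


def clip_and_filter(read_id: str, seq: str, params: TrimParams,
                    adapter_found: bool = True) -> TrimmedRead:
    """Apply randomized-base clipping and length filters to an
    adapter-trimmed sequence.

    Order: discard no-adapter reads (unless kept by policy); clip ``clip3``
    bases from the 3' end; discard if still longer than ``max_length``; clip
    ``clip5`` bases from the 5' end; discard if shorter than ``min_length``.
    """
    if not adapter_found and not params.keep_no_adapter:
        return TrimmedRead(read_id, "", "no_adapter")
    seq = seq[:len(seq) - params.clip3] if params.clip3 else seq
    if len(seq) > params.max_length:
        return TrimmedRead(read_id, "", "too_long")
    seq = seq[params.clip5:]
    if len(seq) < params.min_length:
        return TrimmedRead(read_id, "", "too_short")
    return TrimmedRead(read_id, seq, "none")


def trim_read(read_id: str, seq: str, params: TrimParams) -> TrimmedRead:
    trimmed, found = remove_adapter(seq, params)
    return clip_and_filter(read_id, trimmed, params, adapter_found=found)


def trim_reads(reads: Iterable[tuple[str, str]], params: TrimParams
               ) -> Iterator[TrimmedRead]:
    """Trim a stream of ``(read_id, sequence)`` pairs."""
    params.validate()
    for read_id, seq in reads:
        yield trim_read(read_id, seq, params)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a (optionally gzipped) FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title, seq


def trim_fastq(in_path: str | Path, out_path: str | Path, params: TrimParams,
               report_path: str | Path | None = None) -> dict[str, int]:
    """Trim a FASTQ file to a FASTQ of clean inserts; returns and optionally
    writes the per-discard-reason counts (conservation: they sum to the
    input read count)."""
    from .simulate import write_fastq

    counts = {r: 0 for r in DISCARD_REASONS}

    def _kept() -> Iterator[tuple[str, str, str]]:
        for tr in trim_reads(read_fastq(in_path), params):
            counts[tr.discard_reason] += 1
            if tr.kept:
                yield tr.read_id, tr.insert_seq, "I" * len(tr.insert_seq)

    write_fastq(_kept(), out_path)
    report = {"kept": counts.pop("none"), **counts}
    if report_path is not None:
        pd.DataFrame([report]).to_csv(report_path, sep="\t", index=False)
    return report
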