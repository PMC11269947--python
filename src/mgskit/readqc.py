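"""High-quality non-host (HQNH) read-pair filtering.

A read pair is HQNH if (1) neither mate maps to the host genome, (2) after
adapter removal and quality end-trimming both mates are at least
``min_len`` bases long. Host mapping itself is upstream of this package;
its outcome is consumed as a per-read flag (written into the FASTQ
description by the simulator as ``host=0/1``).

Trimming dialect: exact adapter prefix/suffix stripping, then 3' and then
5' end-trimming while the terminal base quality is below the Phred floor.
Internal bases below the floor inside a high-quality stretch are retained;
this mirrors the end-trimming behaviour of common adapter/quality trimmers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InputError

DEFAULT_PHRED_FLOOR = 30
DEFAULT_MIN_LEN = 100


@dataclass(frozen=True)
class Read:
    seq: str
    quals: tuple[int, ...]
    host: bool | None = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise InputError("sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    r1: Read
    r2: Read


def remove_host_pairs(pairs: Iterable[ReadPair]) -> list[ReadPair]:
    """Keep a pair iff neither mate carries the host flag."""
    out = []
    for p in pairs:
        if p.r1.host is None or p.r2.host is None:
            raise InputError("host flags missing; host screening contract not met")
        if not (p.r1.host or p.r2.host):
            out.append(p)
    return out


def trim_read(
    seq: str,
    quals: Sequence[int],
    phred_floor: int = DEFAULT_PHRED_FLOOR,
    adapters: Sequence[str] = (),
) -> tuple[str, tuple[int, ...]]:
    """Adapter strip then quality end-trim one read.

    Adapters are removed by exact prefix/suffix match; quality trimming
    removes bases from the 3' end, then the 5' end, while the terminal base
    is below ``phred_floor``.
    """
    if len(seq) != len(quals):
        raise InputError("sequence and quality lengths differ")
    quals = list(quals)
    for ad in adapters:
        if ad and seq.endswith(ad):
            seq, quals = seq[: -len(ad)], quals[: -len(ad)]
        if ad and seq.startswith(ad):
            seq, quals = seq[len(ad):], quals[len(ad):]
    end = len(seq)
    while end > 0 and quals[end - 1] < phred_floor:
        end -= 1
    start = 0
    while start < end and quals[start] < phred_floor:
        start += 1
    return seq[start:end], tuple(quals[start:end])


def trim_pair(pair: ReadPair, phred_floor: int = DEFAULT_PHRED_FLOOR, adapters: Sequence[str] = ()) -> ReadPair:
    reads = []
    for r in (pair.r1, pair.r2):
        seq, quals = trim_read(r.seq, r.quals, phred_floor, adapters)
        reads.append(Read(seq, quals, r.host))
    return ReadPair(*reads)


def hqnh_filter(pairs: Iterable[ReadPair], min_len: int = DEFAULT_MIN_LEN) -> list[ReadPair]:
    """Keep pairs in which both mates are at least ``min_len`` bases."""
    return [p for p in pairs if len(p.r1) >= min_len and len(p.r2) >= min_len]


def qc_pipeline(
    pairs: Sequence[ReadPair],
    phred_floor: int = DEFAULT_PHRED_FLOOR,
    min_len: int = DEFAULT_MIN_LEN,
    adapters: Sequence[str] = (),
) -> tuple[list[ReadPair], dict[str, int]]:
    """Host removal -> trimming -> length filter, with a stage summary."""
    n_in = len(pairs)
    non_host = remove_host_pairs(pairs)
    trimmed = [trim_pair(p, phred_floor, adapters) for p in non_host]
    kept = hqnh_filter(trimmed, min_len)
    summary = {
        "pairs_in": n_in,
        "host_removed": n_in - len(non_host),
        "trimmed_pairs": len(trimmed),
        "hqnh_pairs": len(kept),
    }
    return kept, summary


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def _to_record(read: Read, read_id: str) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read_id, description=f"host={int(bool(read.host))}")
    rec.letter_annotations["phred_quality"] = list(read.quals)
    return rec


def write_fastq_pair(pairs: Sequence[ReadPair], r1_path, r2_path, id_prefix: str = "read") -> None:
    recs1 = [_to_record(p.r1, f"{id_prefix}{i}/1") for i, p in enumerate(pairs)]
    recs2 = [_to_record(p.r2, f"{id_prefix}{i}/2") for i, p in enumerate(pairs)]
    SeqIO.write(recs1, str(r1_path), "fastq")
    SeqIO.write(recs2, str(r2_path), "fastq")


def _from_record(rec: SeqRecord) -> Read:
    host = None
    for token in rec.description.split():
        if token.startswith("host="):
            host = bool(int(token[5:]))
    return Read(str(rec.seq), tuple(rec.letter_annotations["phred_quality"]), host)


def read_fastq_pair(r1_path, r2_path) -> list[ReadPair]:
    recs1 = list(SeqIO.parse(str(r1_path), "fastq"))
    recs2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(recs1) != len(recs2):
        raise InputError("R1/R2 FASTQ files have different read counts")
    return [ReadPair(_from_record(a), _from_record(b)) for a, b in zip(recs1, recs2)]
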