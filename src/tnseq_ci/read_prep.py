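"""Read preparation: fuzzy transposon detection and genomic-tag extraction.

Each sequencing read is expected to begin with (or contain) the 32-nt
transposon end sequence, followed by a short genomic tag that localizes the
insertion.  The transposon is found by scanning every offset of the read
for the minimum Hamming distance to the expected sequence, accepting a
match when that minimum is at most ``max_mismatches`` (default 3).  The
``tag_length`` bases immediately after the match are the genomic tag.

Every read lands in exactly one accounting bucket — no transposon, too
short to yield a full tag, or used — so that
``total = no_tn + too_short + used`` holds exactly.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import revcomp

__all__ = [
    "DEFAULT_TN_SEQUENCE",
    "ReadPrepParams",
    "PrepAccounting",
    "hamming",
    "find_transposon",
    "extract_tag",
    "process_fastq",
]

#: Transposon end sequence expected at the junction (32 nt).
DEFAULT_TN_SEQUENCE = "CGATCTAGACCGGGGACTTATCATCCAACCTG"


@dataclass(frozen=True)
class ReadPrepParams:
    """Parameters controlling transposon detection and tag extraction.

    tag_length defaults to 17 nt; the construct's MmeI digestion yields
    16-18 genomic bases so the length is configurable per run.
    """

    tn_sequence: str = DEFAULT_TN_SEQUENCE
    max_mismatches: int = 3
    tag_length: int = 17
    revcomp_input: bool = False
    anchor0: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        if set(self.tn_sequence) - set("ACGT"):
            raise ValueError("tn_sequence must be over {A,C,G,T}")


@dataclass
class PrepAccounting:
    """Read accounting; the buckets partition the input exactly."""

    total_reads: int = 0
    reads_no_tn: int = 0
    reads_too_short: int = 0
    reads_used: int = 0

    @property
    def pct_no_tn(self) -> float:
        return 100.0 * self.reads_no_tn / self.total_reads if self.total_reads else 0.0

    def __add__(self, other: "PrepAccounting") -> "PrepAccounting":
        return PrepAccounting(
            self.total_reads + other.total_reads,
            self.reads_no_tn + other.reads_no_tn,
            self.reads_too_short + other.reads_too_short,
            self.reads_used + other.reads_used,
        )


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length DNA strings; N matches nothing."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def find_transposon(read: str, params: ReadPrepParams) -> int | None:
    """Locate the transposon end sequence in a read.

    Scans all offsets and returns the leftmost offset achieving the minimum
    Hamming distance, provided that minimum is within ``max_mismatches``;
    returns None otherwise (including reads shorter than the transposon).
    With ``anchor0`` only offset 0 is considered.
    """
    if params.revcomp_input:
        read = revcomp(read)
    tn = params.tn_sequence
    n_offsets = len(read) - len(tn) + 1
    if n_offsets < 1:
        return None
    if params.anchor0:
        n_offsets = 1
    best_offset = None
    best_dist = params.max_mismatches + 1
    for offset in range(n_offsets):
        d = hamming(read[offset : offset + len(tn)], tn)
        if d < best_dist:
            best_dist = d
            best_offset = offset
            if d == 0:
                break
    return best_offset


def extract_tag(read: str, offset: int, params: ReadPrepParams) -> str | None:
    """The tag_length bases after the transposon match, or None if too short."""
    if params.revcomp_input:
        read = revcomp(read)
    start = offset + len(params.tn_sequence)
    end = start + params.tag_length
    if end > len(read):
        return None
    return read[start:end]


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (upper-cased) from a FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq.upper()


def _scan_batch(
    seqs: list[str], params: ReadPrepParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized minimal-Hamming transposon scan over a batch of reads.

    Returns (offsets, distances) per read; offset -1 where no valid offset
    exists (read shorter than the transposon).  Semantics match
    find_transposon (leftmost minimal offset).
    """
    tn = np.frombuffer(params.tn_sequence.encode(), dtype=np.uint8)
    tlen = tn.size
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    maxlen = int(lengths.max()) if seqs else 0
    if maxlen < tlen:
        return np.full(len(seqs), -1, dtype=np.int64), np.zeros(len(seqs), np.int64)
    # Pad with a byte outside the DNA alphabet so pads always mismatch.
    buf = np.full((len(seqs), maxlen), ord("#"), dtype=np.uint8)
    for i, s in enumerate(seqs):
        buf[i, : lengths[i]] = np.frombuffer(s.encode(), dtype=np.uint8)
    n_offsets = 1 if params.anchor0 else maxlen - tlen + 1
    dist = np.empty((len(seqs), n_offsets), dtype=np.int16)
    for o in range(n_offsets):
        dist[:, o] = (buf[:, o : o + tlen] != tn).sum(axis=1)
    # Invalidate offsets that run past each read's true end.
    big = np.int16(tlen + 1)
    offs = np.arange(n_offsets)
    invalid = offs[None, :] > (lengths - tlen)[:, None]
    dist[invalid] = big
    best = dist.argmin(axis=1)  # argmin takes the leftmost minimum
    best_d = dist[np.arange(len(seqs)), best]
    offsets = np.where(best_d <= params.max_mismatches, best, -1)
    offsets[lengths < tlen] = -1
    return offsets.astype(np.int64), best_d.astype(np.int64)


def process_fastq(
    path: str | Path,
    params: ReadPrepParams | None = None,
    batch_size: int = 200_000,
) -> tuple[Counter, PrepAccounting]:
    """Extract genomic tags from a FASTQ file with full read accounting.

    Returns the multiset of tags (a Counter) and a PrepAccounting whose
    buckets sum exactly to the number of input reads.  Quality strings are
    parsed but unused — no quality filtering is applied.
    """
    if params is None:
        params = ReadPrepParams()
    tags: Counter = Counter()
    acct = PrepAccounting()
    tlen = len(params.tn_sequence)
    do_revcomp = params.revcomp_input
    # revcomp is applied to whole batches below; the scan itself must not
    # re-apply it.
    scan_params = ReadPrepParams(
        params.tn_sequence, params.max_mismatches, params.tag_length,
        False, params.anchor0,
    )
    batch: list[str] = []

    def flush(batch: list[str]) -> None:
        if not batch:
            return
        if do_revcomp:
            batch = [revcomp(s) for s in batch]
        offsets, _ = _scan_batch(batch, scan_params)
        for seq, off in zip(batch, offsets):
            acct.total_reads += 1
            if off < 0:
                acct.reads_no_tn += 1
                continue
            start = off + tlen
            if start + scan_params.tag_length > len(seq):
                acct.reads_too_short += 1
                continue
            acct.reads_used += 1
            tags[seq[start : start + scan_params.tag_length]] += 1

    for seq in _iter_fastq(path):
        batch.append(seq)
        if len(batch) >= batch_size:
            flush(batch)
            batch = []
    flush(batch)
    return tags, acct
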