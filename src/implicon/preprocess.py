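"""UMI extraction and read trimming.

The library design places an 8-nt random UMI at the start of Read 2.  The
first ``umi_length`` bases of Read 2 are removed and appended to both read
identifiers behind a reserved ``:UMI:`` token so any downstream parser that
splits on whitespace keeps it.  Trimming removes a 3' adapter occurrence and
then low-quality 3' tails by the running-sum rule; if either mate of a pair
ends up shorter than the minimum length, the whole pair is dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import AnalysisConfig

UMI_DELIM = ":UMI:"


@dataclass
class RawRead:
    id: str
    seq: str
    qual: str


@dataclass
class TaggedReadPair:
    """A read pair after UMI relocation and trimming."""

    id: str          # shared identifier carrying the UMI token
    umi: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq_pairs(r1_path: str | Path,
                     r2_path: str | Path) -> Iterator[Tuple[RawRead, RawRead]]:
    """Stream synchronised read pairs from two (optionally gzipped) FASTQ files."""
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2):
            yield RawRead(id1.split()[0], s1, q1), RawRead(id2.split()[0], s2, q2)


def extract_umi(pair: Tuple[RawRead, RawRead],
                config: AnalysisConfig) -> Optional[TaggedReadPair]:
    """Move the first ``umi_length`` bases of Read 2 into both read ids.

    Returns ``None`` when Read 2 is not strictly longer than the UMI (the
    pair carries no usable genomic sequence and is rejected).
    """
    r1, r2 = pair
    n = config.umi_length
    if len(r2.seq) <= n:
        return None
    umi = r2.seq[:n]
    base_id = r1.id.split("/")[0]
    return TaggedReadPair(
        id=f"{base_id}{UMI_DELIM}{umi}",
        umi=umi,
        seq1=r1.seq,
        qual1=r1.qual,
        seq2=r2.seq[n:],
        qual2=r2.qual[n:],
    )


def _find_adapter(seq: str, adapter: str, min_overlap: int = 3,
                  max_mismatch_frac: float = 0.1) -> int:
    """Leftmost position where a 3' adapter prefix starts, or ``len(seq)``.

    The adapter may run off the read end, so at position ``i`` we compare the
    adapter prefix of length ``min(len(adapter), len(seq) - i)`` and accept
    overlaps of at least ``min_overlap`` bases with at most 10% mismatches.
    Candidate positions are anchored on an exact match of the adapter's first
    ``min_overlap`` bases, which keeps the scan cheap on adapter-free reads.
    """
    n = len(seq)
    anchor = adapter[:min_overlap]
    i = seq.find(anchor)
    while 0 <= i <= n - min_overlap:
        k = min(len(adapter), n - i)
        mism = sum(1 for a, b in zip(seq[i:i + k], adapter[:k]) if a != b)
        if mism <= int(max_mismatch_frac * k):
            return i
        i = seq.find(anchor, i + 1)
    return n


def quality_trim(seq: str, qual: str, q_cutoff: int = 20,
                 adapter: str | None = "AGATCGGAAGAGC") -> Tuple[str, str]:
    """Remove a 3' adapter hit, then low-quality 3' tail (running-sum rule).

    The quality rule removes the suffix whose cumulative ``q_cutoff - q`` is
    maximal (BWA-style): scanning from the 3' end, the cut point is placed
    where the running badness peaks; if no suffix is net-bad the read is
    unchanged.  Idempotent by construction.
    """
    if adapter:
        cut = _find_adapter(seq, adapter)
        seq, qual = seq[:cut], qual[:cut]
    if not qual or min(qual) >= chr(q_cutoff + 33):
        return seq, qual  # no base below the cutoff: nothing to trim
    best_sum = 0
    running = 0
    cut = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        running += q_cutoff - (ord(qual[i]) - 33)
        if running > best_sum:
            best_sum = running
            cut = i
    return seq[:cut], qual[:cut]


def trim_pair(pair: TaggedReadPair,
              config: AnalysisConfig) -> Optional[TaggedReadPair]:
    """Trim both mates; drop the pair if either mate becomes too short."""
    s1, q1 = quality_trim(pair.seq1, pair.qual1, config.quality_trim_cutoff,
                          config.adapter)
    s2, q2 = quality_trim(pair.seq2, pair.qual2, config.quality_trim_cutoff,
                          config.adapter)
    if len(s1) < config.min_length_after_trim or len(s2) < config.min_length_after_trim:
        return None
    return TaggedReadPair(pair.id, pair.umi, s1, q1, s2, q2)


def preprocess_pairs(
    raw_pairs: Iterable[Tuple[RawRead, RawRead]],
    config: AnalysisConfig,
    counters: Optional[dict] = None,
) -> Iterator[TaggedReadPair]:
    """extract_umi + trim over a stream of raw pairs, counting rejections."""
    c = counters if counters is not None else {}
    c.setdefault("pairs_in", 0)
    c.setdefault("umi_rejected", 0)
    c.setdefault("trim_dropped", 0)
    for raw in raw_pairs:
        c["pairs_in"] += 1
        tagged = extract_umi(raw, config)
        if tagged is None:
            c["umi_rejected"] += 1
            continue
        trimmed = trim_pair(tagged, config)
        if trimmed is None:
            c["trim_dropped"] += 1
            continue
        yield trimmed
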