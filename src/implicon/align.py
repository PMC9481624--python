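"""Bisulfite-space placement of read pairs onto panel amplicons.

Alignment happens in the collapsed three-letter alphabet: the read and the
reference are both C-to-T collapsed (or, for the opposite orientation,
G-to-A via reverse complement), so a read's CpG methylation pattern can never
influence where it is placed.  SNP positions are wildcard-masked so both
parental alleles score identically.

Placement is ungapped: targeted amplicons are short and the simulator makes
no indels (a declared limitation for real data).  Candidate offsets come from
an exact seed k-mer index; reads with no seed hit fall back to exhaustive
scoring at every offset of every reference.  A placement is accepted when its
identity strictly exceeds ``min_identity`` and beats the best other region by
at least ``ambiguity_margin``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .panel import AmpliconRegion, revcomp
from .preprocess import TaggedReadPair

_CT = bytes.maketrans(b"C", b"T")
_GA = bytes.maketrans(b"G", b"A")


@dataclass
class ReferenceSet:
    """Collapsed references + seed index for one panel."""

    regions: List[AmpliconRegion]
    fwd: List[np.ndarray]        # C->T collapsed design strand
    rev: List[np.ndarray]        # G->A collapsed reverse complement
    mask_fwd: List[np.ndarray]   # SNP wildcard positions (bool)
    mask_rev: List[np.ndarray]
    index: Dict[bytes, List[Tuple[int, int]]]  # kmer -> [(region_idx, pos)]
    k: int

    def region_idx(self, name: str) -> int:
        return next(i for i, r in enumerate(self.regions) if r.name == name)


def convert_panel_references(regions: Sequence[AmpliconRegion],
                             k: int = 24) -> ReferenceSet:
    """Build both collapsed references per region plus the seed k-mer index.

    Every CpG cytosine is collapsed onto T in the forward reference (and its
    G onto A in the reverse-complement reference), making the reference
    methylation-ambiguous by construction; SNP offsets are masked as
    always-match so reads from either allele place identically.
    """
    fwd, rev, mfwd, mrev = [], [], [], []
    index: Dict[bytes, List[Tuple[int, int]]] = {}
    for ridx, region in enumerate(regions):
        if region.sequence is None:
            raise ValueError(f"region {region.name} has no reference sequence")
        seq = region.sequence.encode()
        f = np.frombuffer(seq.translate(_CT), np.uint8)
        r = np.frombuffer(revcomp(region.sequence).encode().translate(_GA), np.uint8)
        L = len(seq)
        mf = np.zeros(L, bool)
        mr = np.zeros(L, bool)
        for s in region.snps:
            mf[s.offset] = True
            mr[L - 1 - s.offset] = True
        fwd.append(f)
        rev.append(r)
        mfwd.append(mf)
        mrev.append(mr)
        fb = f.tobytes()
        for pos in range(0, L - k + 1):
            index.setdefault(fb[pos:pos + k], []).append((ridx, pos))
    return ReferenceSet(list(regions), fwd, rev, mfwd, mrev, index, k)


@dataclass
class PlacedRead:
    region_idx: int
    start: int            # forward (design-strand) coordinates
    strand: str           # '+': read is design-strand; '-': reverse complement
    identity: float
    second_identity: float  # best identity in any other region


@dataclass
class AmpliconAlignment:
    """Accepted placement of one read pair onto one amplicon."""

    region: str
    mate1_start: int
    mate1_end: int
    mate1_strand: str
    mate2_start: int
    mate2_end: int
    mate2_strand: str
    identity1: float
    identity2: float

    @property
    def identity(self) -> float:
        return min(self.identity1, self.identity2)


@dataclass
class Unplaced:
    reason: str           # low_identity | ambiguous | mate_conflict


def _identity(q: np.ndarray, ref: np.ndarray, mask: np.ndarray, start: int) -> float:
    n = len(q)
    window = ref[start:start + n]
    return float(np.mean((q == window) | mask[start:start + n]))


def _exhaustive_best(q: np.ndarray, refs: ReferenceSet
                     ) -> List[Tuple[float, int, int]]:
    """Best (identity, start) per region at every offset; ungapped, contained."""
    out = []
    n = len(q)
    for ridx, (ref, mask) in enumerate(zip(refs.fwd, refs.mask_fwd)):
        if n > len(ref):
            continue
        win = np.lib.stride_tricks.sliding_window_view(ref, n)
        mwin = np.lib.stride_tricks.sliding_window_view(mask, n)
        ids = ((win == q) | mwin).mean(axis=1)
        best = int(np.argmax(ids))
        out.append((float(ids[best]), ridx, best))
    return out


def _place_read(seq: str, refs: ReferenceSet,
                config: AnalysisConfig) -> PlacedRead | Unplaced:
    raw = seq.encode()
    variants = ((raw.translate(_CT), "+"),
                (revcomp(seq).encode().translate(_CT), "-"))
    k = refs.k
    # best candidate per (region, strand): {(ridx): (identity, start, strand)}
    best_by_region: Dict[int, Tuple[float, int, str]] = {}
    any_candidate = False
    for q, strand in variants:
        if len(q) < k:
            continue
        qa = np.frombuffer(q, np.uint8)
        seen = set()
        for off in range(0, len(q) - k + 1, k):
            for ridx, pos in refs.index.get(q[off:off + k], ()):
                start = pos - off
                if start < 0 or start + len(q) > len(refs.fwd[ridx]):
                    continue
                key = (ridx, start, strand)
                if key in seen:
                    continue
                seen.add(key)
                any_candidate = True
                ident = _identity(qa, refs.fwd[ridx], refs.mask_fwd[ridx], start)
                cur = best_by_region.get(ridx)
                if cur is None or ident > cur[0]:
                    best_by_region[ridx] = (ident, start, strand)
    if not any_candidate:
        # no exact seed anywhere: score everything (rare, error-dense reads)
        for q, strand in variants:
            qa = np.frombuffer(q, np.uint8)
            for ident, ridx, start in _exhaustive_best(qa, refs):
                cur = best_by_region.get(ridx)
                if cur is None or ident > cur[0]:
                    best_by_region[ridx] = (ident, start, strand)
    if not best_by_region:
        return Unplaced("low_identity")

    ranked = sorted(
        ((v[0], ridx, v[1], v[2]) for ridx, v in best_by_region.items()),
        reverse=True,
    )
    ident, ridx, start, strand = ranked[0]
    second = ranked[1][0] if len(ranked) > 1 else 0.0
    if ident <= config.min_identity:
        return Unplaced("low_identity")
    if ident - second < config.ambiguity_margin:
        return Unplaced("ambiguous")
    return PlacedRead(ridx, start, strand, ident, second)


def place_pair(pair: TaggedReadPair, refs: ReferenceSet,
               config: AnalysisConfig) -> AmpliconAlignment | Unplaced:
    """Place both mates; both must land on the same amplicon.

    Mates are aligned independently; a disagreement between them on the
    region is reported as ``mate_conflict``.
    """
    p1 = _place_read(pair.seq1, refs, config)
    p2 = _place_read(pair.seq2, refs, config)
    if isinstance(p1, Unplaced):
        return p1
    if isinstance(p2, Unplaced):
        return p2
    if p1.region_idx != p2.region_idx:
        return Unplaced("mate_conflict")
    region = refs.regions[p1.region_idx]
    return AmpliconAlignment(
        region=region.name,
        mate1_start=p1.start,
        mate1_end=p1.start + len(pair.seq1),
        mate1_strand=p1.strand,
        mate2_start=p2.start,
        mate2_end=p2.start + len(pair.seq2),
        mate2_strand=p2.strand,
        identity1=p1.identity,
        identity2=p2.identity,
    )


def place_pairs(pairs, refs: ReferenceSet, config: AnalysisConfig,
                counters: Optional[dict] = None):
    """Place a stream of pairs; yields ``(pair, alignment)`` for accepted ones."""
    c = counters if counters is not None else {}
    for key in ("placed", "unplaced_low_identity", "unplaced_ambiguous",
                "unplaced_mate_conflict"):
        c.setdefault(key, 0)
    for pair in pairs:
        result = place_pair(pair, refs, config)
        if isinstance(result, Unplaced):
            c[f"unplaced_{result.reason}"] += 1
            continue
        c["placed"] += 1
        yield pair, result


def oriented_mates(pair: TaggedReadPair, aln: AmpliconAlignment
                   ) -> List[Tuple[int, int, str, str]]:
    """Mates in design-strand orientation: ``(start, end, seq, qual)``.

    Mate 1 first (it wins at overlapping positions downstream); '-' strand
    mates are reverse-complemented and their qualities reversed so every
    returned sequence reads along the top strand of the region.
    """
    out = []
    for start, end, strand, seq, qual in (
        (aln.mate1_start, aln.mate1_end, aln.mate1_strand, pair.seq1, pair.qual1),
        (aln.mate2_start, aln.mate2_end, aln.mate2_strand, pair.seq2, pair.qual2),
    ):
        if strand == "-":
            seq = revcomp(seq)
            qual = qual[::-1]
        out.append((start, end, seq, qual))
    return out


def write_sam(placements, refs: ReferenceSet, path) -> None:
    """Minimal SAM emission (one line per placed mate) for external viewing."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for region in refs.regions:
            fh.write(f"@SQ\tSN:{region.name}\tLN:{region.length}\n")
        for pair, aln in placements:
            for mate, (start, end, strand, seq, qual) in enumerate(
                (
                    (aln.mate1_start, aln.mate1_end, aln.mate1_strand,
                     pair.seq1, pair.qual1),
                    (aln.mate2_start, aln.mate2_end, aln.mate2_strand,
                     pair.seq2, pair.qual2),
                ),
                start=1,
            ):
                flag = 0x1 | 0x2 | (0x40 if mate == 1 else 0x80)
                if strand == "-":
                    flag |= 0x10
                    seq = revcomp(seq)
                    qual = qual[::-1]
                fh.write(
                    f"{pair.id}\t{flag}\t{aln.region}\t{start + 1}\t60\t"
                    f"{len(seq)}M\t=\t"
                    f"{(aln.mate2_start if mate == 1 else aln.mate1_start) + 1}\t0\t"
                    f"{seq}\t{qual}\n"
                )
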