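"""Domain model of the targeted hybrid-genome amplicon panel.

An :class:`AmpliconRegion` is one bisulfite-PCR target: its coordinates,
ordered CpG map, strain SNPs (maternal BL6 reference base vs paternal CAST
alternative) and the expected imprint configuration.  The packaged default
panel mirrors the assay design — 13 imprinted control regions (11 methylated
on the maternal allele, 2 on the paternal) plus two unmethylated and one
methylated control region — over synthetic 300-480 bp sequences whose CpG
counts match the published per-locus numbers for the headline loci
(Peg3 24, Dlk1-Dio3 27, Igf2-H19 16, PWS-AS 15).

Coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive intervals.  The maternal allele is always listed first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

REGION_CLASSES = (
    "maternal_methylated_ICR",
    "paternal_methylated_ICR",
    "control_unmethylated",
    "control_methylated",
)

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.encode().translate(_COMP)[::-1].decode()


def complement(base: str) -> str:
    return base.encode().translate(_COMP).decode()


class PanelError(ValueError):
    """Raised for malformed panel/SNP files or inconsistent region definitions."""


def effective_base(base: str, design_strand: str) -> str:
    """Base as it reads after full bisulfite conversion of the design strand.

    On the top strand unmethylated C converts to T; a bottom-strand design
    reads top-strand G positions as converted (G collapses onto A in
    top-strand coordinates).  SNPs located in a CpG context are not modelled
    (the packaged panel keeps SNPs clear of CpGs).
    """
    if design_strand == "top":
        return "T" if base == "C" else base
    if design_strand == "bottom":
        return "A" if base == "G" else base
    raise ValueError(f"unknown design_strand {design_strand!r}")


def snp_usable(maternal_base: str, paternal_base: str, design_strand: str) -> bool:
    """A SNP is usable when conversion does not collapse the two alleles."""
    return effective_base(maternal_base, design_strand) != effective_base(
        paternal_base, design_strand
    )


@dataclass
class SnpSite:
    """One strain-distinguishing SNP inside a region (top-strand bases)."""

    offset: int                       # region-relative, 0-based
    maternal_base: str                # BL6 / reference
    paternal_base: str                # CAST / alternative
    usable_on_design_strand: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.maternal_base == self.paternal_base:
            raise PanelError(
                f"SNP at offset {self.offset}: maternal and paternal base identical"
            )


@dataclass
class AmpliconRegion:
    """One panel target with its CpG map, SNPs and imprint configuration."""

    name: str
    chrom: str
    start: int                        # 0-based
    end: int                          # half-open
    design_strand: str                # "top" or "bottom"
    region_class: str
    cpg_positions: List[int] = field(default_factory=list)
    snps: List[SnpSite] = field(default_factory=list)
    sequence: Optional[str] = None    # top-strand reference sequence

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def methylated_allele(self) -> Optional[str]:
        """Which parental allele carries methylation in the normal state."""
        if self.region_class == "maternal_methylated_ICR":
            return "maternal"
        if self.region_class == "paternal_methylated_ICR":
            return "paternal"
        return None

    @property
    def interval_1based(self) -> str:
        """Printable 1-based inclusive interval, e.g. ``chr7:3000001-3000400``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def usable_snps(self) -> List[SnpSite]:
        return [s for s in self.snps if s.usable_on_design_strand]

    def validate(self) -> None:
        if self.start >= self.end:
            raise PanelError(f"{self.name}: start >= end")
        if self.region_class not in REGION_CLASSES:
            raise PanelError(f"{self.name}: unknown region_class {self.region_class!r}")
        if self.design_strand not in ("top", "bottom"):
            raise PanelError(f"{self.name}: bad design_strand {self.design_strand!r}")
        cp = self.cpg_positions
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise PanelError(f"{self.name}: CpG offsets not strictly increasing")
        if cp and (cp[0] < 0 or cp[-1] >= self.length - 1):
            raise PanelError(f"{self.name}: CpG offset outside region")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise PanelError(f"{self.name}: sequence length != end - start")
            for o in cp:
                if self.sequence[o : o + 2] != "CG":
                    raise PanelError(
                        f"{self.name}: no CpG dinucleotide at offset {o}"
                    )
        for s in self.snps:
            if not 0 <= s.offset < self.length:
                raise PanelError(f"{self.name}: SNP offset {s.offset} outside region")
            if self.sequence is not None and self.sequence[s.offset] != s.maternal_base:
                raise PanelError(
                    f"{self.name}: SNP maternal base disagrees with reference "
                    f"at offset {s.offset}"
                )


def mark_usable_snps(region: AmpliconRegion) -> AmpliconRegion:
    """Set each SNP's usability flag under the region's design strand.

    A C/T SNP read on a C-to-T-converted strand (or its complement on a
    bottom-strand design) is indistinguishable between alleles and is never
    used for allele assignment.  Regions left without any usable SNP are
    flagged with a warning: their reads can never be split by parent.
    """
    snps = [
        replace(s, usable_on_design_strand=snp_usable(
            s.maternal_base, s.paternal_base, region.design_strand))
        for s in region.snps
    ]
    out = replace(region, snps=snps)
    if out.snps and not out.usable_snps():
        log.warning("region %s has no usable SNP on its design strand", out.name)
    return out


# ---------------------------------------------------------------------------
# panel file I/O
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = "chrom start end name design_strand region_class cpg_offsets".split()


def load_panel(
    panel_path: str | Path,
    snp_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> List[AmpliconRegion]:
    """Read a BED-like panel TSV (+ optional SNP TSV and reference FASTA).

    Panel columns: chrom, start, end, name, design_strand, region_class,
    comma-separated CpG offsets.  SNP file columns: chrom, pos (1-based, VCF
    convention), maternal (REF) base, paternal (ALT) base.  A SNP that falls
    outside every region is an error.
    """
    regions: List[AmpliconRegion] = []
    lines = Path(panel_path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(_PANEL_COLUMNS):
            raise PanelError(
                f"{panel_path}: line {i}: expected {len(_PANEL_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        chrom, start, end, name, strand, rclass, offsets = parts
        try:
            region = AmpliconRegion(
                name=name,
                chrom=chrom,
                start=int(start),
                end=int(end),
                design_strand=strand,
                region_class=rclass,
                cpg_positions=[int(x) for x in offsets.split(",") if x != ""],
            )
        except ValueError as exc:
            raise PanelError(f"{panel_path}: line {i}: {exc}") from exc
        regions.append(region)

    if not regions:
        log.warning("panel file %s contains no regions", panel_path)
        return []

    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        for r in regions:
            if r.name in seqs:
                r.sequence = seqs[r.name]

    if snp_path is not None:
        for i, line in enumerate(Path(snp_path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise PanelError(f"{snp_path}: line {i}: expected 4 columns")
            chrom, pos, mat, pat = parts
            pos0 = int(pos) - 1  # VCF 1-based -> internal 0-based
            hit = [
                r for r in regions
                if r.chrom == chrom and r.start <= pos0 < r.end
            ]
            if not hit:
                raise PanelError(
                    f"{snp_path}: line {i}: SNP {chrom}:{pos} outside every region"
                )
            for r in hit:
                r.snps.append(SnpSite(pos0 - r.start, mat.upper(), pat.upper()))

    out = []
    for r in regions:
        r.snps.sort(key=lambda s: s.offset)
        r.validate()
        out.append(mark_usable_snps(r))
    return out


def write_panel(
    regions: List[AmpliconRegion],
    panel_path: str | Path,
    snp_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> None:
    """Write the panel back to TSV/FASTA; inverse of :func:`load_panel`."""
    with open(panel_path, "w") as fh:
        fh.write("#" + "\t".join(_PANEL_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.name,
                        r.design_strand,
                        r.region_class,
                        ",".join(str(o) for o in r.cpg_positions),
                    ]
                )
                + "\n"
            )
    if snp_path is not None:
        with open(snp_path, "w") as fh:
            fh.write("#chrom\tpos\tmaternal\tpaternal\n")
            for r in regions:
                for s in r.snps:
                    fh.write(
                        f"{r.chrom}\t{r.start + s.offset + 1}\t"
                        f"{s.maternal_base}\t{s.paternal_base}\n"
                    )
    if fasta_path is not None:
        recs = [
            SeqRecord(Seq(r.sequence), id=r.name, description=r.interval_1based)
            for r in regions
            if r.sequence is not None
        ]
        SeqIO.write(recs, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# packaged default panel
# ---------------------------------------------------------------------------

# name, chrom, CpG count, region class.  CpG counts for the four headline
# loci follow the published per-locus numbers; the rest are plausible
# amplicon densities.  Chromosome labels follow the mouse loci; coordinates
# and sequences are synthetic (no genome extract is shipped).
_DEFAULT_SPECS = [
    ("Peg3", "chr7", 24, "maternal_methylated_ICR"),
    ("PWS-AS", "chr7", 15, "maternal_methylated_ICR"),
    ("Gnas", "chr2", 21, "maternal_methylated_ICR"),
    ("Commd1-Zrsr1", "chr11", 18, "maternal_methylated_ICR"),
    ("Mcts2-H13", "chr2", 14, "maternal_methylated_ICR"),
    ("Kcnq1-Kcnq1ot1", "chr7", 22, "maternal_methylated_ICR"),
    ("Mest-Peg1", "chr6", 19, "maternal_methylated_ICR"),
    ("Plagl1-Zac1", "chr10", 17, "maternal_methylated_ICR"),
    ("Grb10", "chr11", 25, "maternal_methylated_ICR"),
    ("Igf2r", "chr17", 13, "maternal_methylated_ICR"),
    ("Impact", "chr18", 12, "maternal_methylated_ICR"),
    ("Igf2-H19", "chr7", 16, "paternal_methylated_ICR"),
    ("Dlk1-Dio3", "chr12", 27, "paternal_methylated_ICR"),
    ("ctrl-unmeth-1", "chr3", 11, "control_unmethylated"),
    ("ctrl-unmeth-2", "chr9", 13, "control_unmethylated"),
    ("ctrl-meth-1", "chr4", 12, "control_methylated"),
]

_PANEL_SEED = 910425  # fixed: the packaged panel is part of the package


def _synthetic_region(name, chrom, n_cpg, rclass, start, rng) -> AmpliconRegion:
    length = min(480, max(300, 60 + 14 * n_cpg))
    codes = rng.choice(
        np.frombuffer(b"ACGT", np.uint8), size=length, p=[0.3, 0.2, 0.2, 0.3]
    ).copy()
    C, G, A = ord("C"), ord("G"), ord("A")
    # remove accidental CpGs so the CpG map is exhaustive
    bad = np.where((codes[:-1] == C) & (codes[1:] == G))[0]
    codes[bad + 1] = A
    # place CpGs evenly with jitter, min spacing 4
    base = np.linspace(15, length - 20, n_cpg)
    jitter = rng.integers(-3, 4, size=n_cpg)
    offs = np.sort(base.astype(int) + jitter)
    for i in range(1, n_cpg):
        offs[i] = max(offs[i], offs[i - 1] + 4)
    codes[offs] = C
    codes[offs + 1] = G
    seq = codes.tobytes().decode()

    # three usable SNPs per region, away from CpGs
    snps = []
    cpg_blocked = set()
    for o in offs:
        cpg_blocked.update(range(o - 2, o + 4))
    for frac in (0.2, 0.5, 0.8):
        o = int(length * frac)
        while o in cpg_blocked or seq[o - 1] == "C" or any(s.offset == o for s in snps):
            o += 1
        ref = seq[o]
        alt = "G" if ref != "G" else "A"
        snps.append(SnpSite(o, ref, alt))

    region = AmpliconRegion(
        name=name,
        chrom=chrom,
        start=start,
        end=start + length,
        design_strand="top",
        region_class=rclass,
        cpg_positions=[int(o) for o in offs],
        snps=sorted(snps, key=lambda s: s.offset),
        sequence=seq,
    )
    region.validate()
    return mark_usable_snps(region)


def default_panel() -> List[AmpliconRegion]:
    """The packaged 16-region panel (13 imprinted + 3 controls).

    Deterministic: sequences are generated from a fixed seed, so every
    installation sees byte-identical references.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    regions = []
    for i, (name, chrom, n_cpg, rclass) in enumerate(_DEFAULT_SPECS):
        start = 3_000_000 + i * 50_000
        regions.append(_synthetic_region(name, chrom, n_cpg, rclass, start, rng))
    # one deliberately conversion-confounded SNP on Peg3 (C/T on a top-strand
    # design): exercises the usability rule downstream.
    peg3 = regions[0]
    o = next(
        i for i, b in enumerate(peg3.sequence)
        if b == "T"
        and all(abs(i - c) > 3 for c in peg3.cpg_positions)
        and all(abs(i - s.offset) > 2 for s in peg3.snps)
        and i > 10
    )
    peg3.snps.append(SnpSite(o, "T", "C"))
    peg3.snps.sort(key=lambda s: s.offset)
    regions[0] = mark_usable_snps(peg3)
    return regions
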