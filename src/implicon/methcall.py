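"""Per-CpG methylation calls, allele assignment, UMI deduplication, summaries.

Calling convention (design-strand orientation): at a covered CpG cytosine an
observed C is methylated, an observed T unmethylated; anything else — other
bases, base quality below the floor, or an uncovered position — is missing.
Where the two mates overlap, mate 1 wins.  Missing states never enter a
percentage denominator.

Allele assignment uses the usable strain SNPs: if every covered usable SNP
supports one parent the molecule is assigned to it; mixed support is
``conflicting`` (excluded from allele summaries but counted as a QC
fraction); no informative SNP leaves the molecule ``unassigned``.

PCR duplicates are groups with identical (region, span, UMI); each group
collapses to one molecule by per-CpG majority vote (ties become missing) and
majority allele (ties become conflicting).  The per-allele coverage filter
(strictly more than ``min_reads_per_allele``) applies to deduplicated
molecule counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import AmpliconAlignment, oriented_mates
from .config import AnalysisConfig
from .panel import AmpliconRegion, effective_base
from .preprocess import TaggedReadPair

log = logging.getLogger(__name__)

ALLELES = ("maternal", "paternal")

METH, UNMETH, MISSING = 1, 0, -1


@dataclass
class MoleculeCall:
    """One (possibly still duplicated) DNA molecule observation."""

    region: str
    allele: str                     # maternal | paternal | unassigned | conflicting
    states: np.ndarray              # int8 over the region's CpGs
    umi: str
    span: Tuple[int, int]           # union of mate spans, 0-based half-open


def call_cpgs(alignment: AmpliconAlignment, pair: TaggedReadPair,
              region: AmpliconRegion, min_base_quality: int = 20) -> np.ndarray:
    """Per-CpG states for one pair; mate 1 overrides mate 2 where both cover."""
    if region.design_strand != "top":
        raise NotImplementedError("bottom-strand designs are not supported in calling")
    states = np.full(region.n_cpgs, MISSING, dtype=np.int8)
    mates = oriented_mates(pair, alignment)
    for start, end, seq, qual in reversed(mates):  # mate 2 first, mate 1 wins
        for j, cp in enumerate(region.cpg_positions):
            if start <= cp < start + len(seq):
                b = seq[cp - start]
                q = ord(qual[cp - start]) - 33
                if q < min_base_quality:
                    states[j] = MISSING
                elif b == "C":
                    states[j] = METH
                elif b == "T":
                    states[j] = UNMETH
                else:
                    states[j] = MISSING
    return states


def assign_allele(alignment: AmpliconAlignment, pair: TaggedReadPair,
                  region: AmpliconRegion, min_base_quality: int = 20) -> str:
    """Assign the pair to a parental allele from its covered usable SNPs."""
    mat_votes = pat_votes = 0
    mates = oriented_mates(pair, alignment)
    for snp in region.usable_snps():
        base = qual = None
        for start, end, seq, qual_s in mates:  # mate 1 first: it wins overlap
            if start <= snp.offset < start + len(seq):
                base = seq[snp.offset - start]
                qual = ord(qual_s[snp.offset - start]) - 33
                break
        if base is None or qual < min_base_quality:
            continue
        if base == effective_base(snp.maternal_base, region.design_strand):
            mat_votes += 1
        elif base == effective_base(snp.paternal_base, region.design_strand):
            pat_votes += 1
    if mat_votes and pat_votes:
        return "conflicting"
    if mat_votes:
        return "maternal"
    if pat_votes:
        return "paternal"
    return "unassigned"


def pair_to_molecule_call(alignment: AmpliconAlignment, pair: TaggedReadPair,
                          region: AmpliconRegion,
                          config: AnalysisConfig) -> MoleculeCall:
    span = (
        min(alignment.mate1_start, alignment.mate2_start),
        max(alignment.mate1_end, alignment.mate2_end),
    )
    return MoleculeCall(
        region=region.name,
        allele=assign_allele(alignment, pair, region, config.min_base_quality),
        states=call_cpgs(alignment, pair, region, config.min_base_quality),
        umi=pair.umi,
        span=span,
    )


def deduplicate(calls: Sequence[MoleculeCall]) -> List[MoleculeCall]:
    """Collapse PCR duplicates: identical (region, span, UMI) groups.

    Per CpG the duplicate group votes; a strict majority of methylated vs
    unmethylated wins, ties (including all-missing) are missing.  The allele
    is the modal label, with ties reported as conflicting.
    """
    if not calls:
        return []
    groups: Dict[Tuple[str, int, int, str], List[MoleculeCall]] = {}
    for call in calls:
        key = (call.region, call.span[0], call.span[1], call.umi)
        groups.setdefault(key, []).append(call)

    out: List[MoleculeCall] = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) == 1:
            out.append(members[0])
            continue
        states = np.stack([m.states for m in members])
        n_meth = (states == METH).sum(axis=0)
        n_unmeth = (states == UNMETH).sum(axis=0)
        merged = np.where(n_meth > n_unmeth, METH,
                          np.where(n_unmeth > n_meth, UNMETH, MISSING)
                          ).astype(np.int8)
        counts: Dict[str, int] = {}
        for m in members:
            counts[m.allele] = counts.get(m.allele, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            allele = "conflicting"
        else:
            allele = ranked[0][0]
        out.append(MoleculeCall(members[0].region, allele, merged,
                                members[0].umi, members[0].span))
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class AlleleStats:
    """Per-allele CpG-level counts and percentages for one region x sample."""

    n_molecules: int
    cpg_meth: np.ndarray
    cpg_unmeth: np.ndarray
    cpg_missing: np.ndarray

    @property
    def cpg_pct(self) -> np.ndarray:
        """% methylation per CpG; NaN where no informative call exists."""
        info = self.cpg_meth + self.cpg_unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(info > 0, 100.0 * self.cpg_meth / info, np.nan)

    @property
    def mean_pct(self) -> float:
        """Mean across CpGs with at least one informative call (NaN if none)."""
        pct = self.cpg_pct
        if np.all(np.isnan(pct)):
            return float("nan")
        return float(np.nanmean(pct))


@dataclass
class RegionAlleleSummary:
    """Per region x sample: per-allele methylation, counts, filter status."""

    region: str
    chrom: str
    start: int
    end: int
    sample: str
    sample_group: str
    run_id: str
    maternal: Optional[AlleleStats]
    paternal: Optional[AlleleStats]
    n_unassigned: int
    n_conflicting: int
    pass_coverage: bool
    excluded_reason: Optional[str] = None

    def allele_stats(self, allele: str) -> Optional[AlleleStats]:
        return self.maternal if allele == "maternal" else self.paternal

    @property
    def total_molecules(self) -> int:
        n = self.n_unassigned + self.n_conflicting
        for stats in (self.maternal, self.paternal):
            if stats is not None:
                n += stats.n_molecules
        return n


def summarize_region(unique_calls: Sequence[MoleculeCall],
                     region: AmpliconRegion, sample: str,
                     config: AnalysisConfig, sample_group: str = "default",
                     run_id: str = "run1") -> RegionAlleleSummary:
    """Aggregate deduplicated molecules into the per-allele region summary.

    ``pass_coverage`` requires *strictly more than* ``min_reads_per_allele``
    deduplicated molecules on each parental allele.  Conflicting-allele
    molecules are excluded from the allele statistics but counted; above
    ``conflicting_warn_fraction`` of the region total they trigger a warning.
    """
    per_allele: Dict[str, Optional[AlleleStats]] = {}
    n_by_label = {"maternal": 0, "paternal": 0, "unassigned": 0, "conflicting": 0}
    stacked: Dict[str, List[np.ndarray]] = {a: [] for a in ALLELES}
    for call in unique_calls:
        n_by_label[call.allele] += 1
        if call.allele in stacked:
            stacked[call.allele].append(call.states)

    for allele in ALLELES:
        rows = stacked[allele]
        if not rows:
            per_allele[allele] = None
            continue
        states = np.stack(rows)
        stats = AlleleStats(
            n_molecules=len(rows),
            cpg_meth=(states == METH).sum(axis=0),
            cpg_unmeth=(states == UNMETH).sum(axis=0),
            cpg_missing=(states == MISSING).sum(axis=0),
        )
        if np.all(stats.cpg_meth + stats.cpg_unmeth == 0):
            # zero informative calls at every CpG: allele reported absent
            stats = None
        per_allele[allele] = stats

    pass_cov = all(
        per_allele[a] is not None
        and per_allele[a].n_molecules > config.min_reads_per_allele
        for a in ALLELES
    )
    total = len(unique_calls)
    if total and n_by_label["conflicting"] / total > config.conflicting_warn_fraction:
        log.warning(
            "%s %s: %.1f%% conflicting-allele molecules",
            sample, region.name, 100 * n_by_label["conflicting"] / total,
        )
    return RegionAlleleSummary(
        region=region.name,
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        sample=sample,
        sample_group=sample_group,
        run_id=run_id,
        maternal=per_allele["maternal"],
        paternal=per_allele["paternal"],
        n_unassigned=n_by_label["unassigned"],
        n_conflicting=n_by_label["conflicting"],
        pass_coverage=pass_cov,
    )


def apply_exclusions(
    summaries: Sequence[RegionAlleleSummary],
    exclusions: Sequence[Tuple[str, str, int, int]],
) -> List[RegionAlleleSummary]:
    """Drop summaries whose interval intersects a listed exclusion.

    Exclusion entries are ``(sample_group, chrom, start, end)`` with 0-based
    half-open coordinates; only summaries of the matching sample group are
    affected.  Dropped summaries are kept in the output with
    ``excluded_reason='listed'`` so reports can show what was removed.
    """
    out = []
    for s in summaries:
        hit = any(
            group == s.sample_group and chrom == s.chrom
            and s.start < end and start < s.end
            for group, chrom, start, end in exclusions
        )
        out.append(replace(s, excluded_reason="listed") if hit else s)
    return out


def merge_runs(summaries: Sequence[RegionAlleleSummary]
               ) -> List[RegionAlleleSummary]:
    """For a sample sequenced in several runs keep, per region, the deeper run.

    Depth is the total deduplicated molecule count; an exact tie keeps the
    lexicographically earlier run id and logs a warning.
    """
    by_key: Dict[Tuple[str, str], List[RegionAlleleSummary]] = {}
    for s in summaries:
        by_key.setdefault((s.sample, s.region), []).append(s)
    out = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda s: (-s.total_molecules, s.run_id))
        if len(group) > 1 and group[0].total_molecules == group[1].total_molecules:
            log.warning("%s/%s: run depth tie, keeping run %s",
                        key[0], key[1], group[0].run_id)
        out.append(group[0])
    return out


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def summaries_to_frames(summaries: Sequence[RegionAlleleSummary],
                        regions: Dict[str, AmpliconRegion]
                        ) -> Dict[str, pd.DataFrame]:
    """region_summary and cpg_methylation tables (1-based CpG positions)."""
    region_rows, cpg_rows = [], []
    for s in summaries:
        for allele in ALLELES:  # maternal always listed first
            stats = s.allele_stats(allele)
            region_rows.append(
                {
                    "sample": s.sample,
                    "region": s.region,
                    "interval": f"{s.chrom}:{s.start + 1}-{s.end}",
                    "allele": allele,
                    "n_molecules": 0 if stats is None else stats.n_molecules,
                    "mean_pct_methylation":
                        float("nan") if stats is None else round(stats.mean_pct, 4),
                    "n_unassigned": s.n_unassigned,
                    "n_conflicting": s.n_conflicting,
                    "pass_coverage": s.pass_coverage,
                    "excluded_reason": s.excluded_reason or "",
                    "run_id": s.run_id,
                }
            )
            if stats is None:
                continue
            region = regions[s.region]
            for j, off in enumerate(region.cpg_positions):
                cpg_rows.append(
                    {
                        "sample": s.sample,
                        "region": s.region,
                        "allele": allele,
                        "cpg_position": s.start + off + 1,  # 1-based report
                        "pct_methylation": round(float(stats.cpg_pct[j]), 4),
                        "n_methylated": int(stats.cpg_meth[j]),
                        "n_unmethylated": int(stats.cpg_unmeth[j]),
                        "n_missing": int(stats.cpg_missing[j]),
                    }
                )
    return {
        "region_summary": pd.DataFrame(region_rows),
        "cpg_methylation": pd.DataFrame(cpg_rows),
    }


def molecule_matrix_frame(calls_by_region: Dict[str, List[MoleculeCall]],
                          sample: str) -> pd.DataFrame:
    """One row per deduplicated molecule: allele + CpG state string.

    This is the single-molecule data layer behind read-level methylation
    plots ('1' methylated, '0' unmethylated, '.' missing).
    """
    rows = []
    for region in sorted(calls_by_region):
        for call in calls_by_region[region]:
            rows.append(
                {
                    "sample": sample,
                    "region": region,
                    "allele": call.allele,
                    "umi": call.umi,
                    "span_start": call.span[0],
                    "span_end": call.span[1],
                    "states": "".join(
                        "1" if x == METH else "0" if x == UNMETH else "."
                        for x in call.states
                    ),
                }
            )
    return pd.DataFrame(rows)
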