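"""Allele-specific expression shortlisting, allelic status, and UPD scan.

Works from per-gene SNP read-count tables (no RNA-seq alignment here): each
row is one gene x sample x replicate with maternal/paternal SNP-assignable
read counts plus a Log2 RPKM expression value.  A gene enters the imprinting
analysis when (1) it is monoallelic in the reference tissue (strictly beyond
90:10, in the direction of its expected parent), (2) it is expressed in every
test replicate (Log2 RPKM strictly above 1) and (3) it has sufficient allelic
resolution (cumulative SNP-specific counts strictly above 5 in at least 2 of
3 replicates; with n != 3 replicates the rule generalises to ceil(2n/3)).

Uniparental disomy produces a chromosome-wide allelic skew: the scan flags a
chromosome when the median maternal fraction across its SNP-informative genes
is >= 0.95 (maternal UPD) or <= 0.05 (paternal UPD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig

log = logging.getLogger(__name__)

ASE_COLUMNS = ["gene", "chrom", "expected_parent", "sample", "replicate",
               "maternal_count", "paternal_count", "log2_rpkm"]


def read_ase_tables(counts_path: str | Path,
                    expr_path: str | Path | None = None) -> pd.DataFrame:
    """Load the SNP-count table, merging the expression table when separate."""
    counts = pd.read_csv(counts_path, sep="\t")
    if expr_path is not None:
        expr = pd.read_csv(expr_path, sep="\t")
        counts = counts.merge(expr, on=["gene", "sample", "replicate"],
                              how="left")
    missing = set(ASE_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"ASE table missing columns: {sorted(missing)}")
    return counts


@dataclass
class AseGeneRecord:
    """Per-gene evaluation across test replicates."""

    gene: str
    chrom: str
    expected_parent: str
    reference_maternal_fraction: float
    replicate_maternal_fraction: List[float]
    mean_maternal_fraction: float
    monoallelic_in_reference: bool
    expressed: bool
    resolvable: bool

    @property
    def passes(self) -> bool:
        return self.monoallelic_in_reference and self.expressed and self.resolvable


def _normalised_counts(df: pd.DataFrame, config: AnalysisConfig) -> pd.Series:
    """Cumulative SNP-specific counts per row, optionally CPM-scaled.

    CPM scaling divides by the library's total allele-assigned reads within
    each (sample, replicate); with ``ase_normalise`` off the raw sums are
    used directly (appropriate when the input is already normalised, or for
    small synthetic libraries).
    """
    total = df["maternal_count"] + df["paternal_count"]
    if not config.ase_normalise:
        return total.astype(float)
    lib = total.groupby([df["sample"], df["replicate"]]).transform("sum")
    return 1e6 * total / lib.replace(0, np.nan)


def _required_replicates(n: int, rule: tuple[int, int]) -> int:
    k, of = rule
    if n == of:
        return k
    req = math.ceil(k * n / of)
    log.info("replicate rule %d-of-%d generalised to %d-of-%d", k, of, req, n)
    return req


def build_gene_records(df: pd.DataFrame, config: AnalysisConfig,
                       test_sample: str, reference_sample: str
                       ) -> List[AseGeneRecord]:
    """Evaluate the three shortlisting filters for every gene."""
    df = df.copy()
    df["snp_count"] = _normalised_counts(df, config)
    records = []
    for gene, sub in df.groupby("gene", sort=True):
        ref = sub[sub["sample"] == reference_sample]
        test = sub[sub["sample"] == test_sample]
        if ref.empty or test.empty:
            raise ValueError(f"gene {gene}: missing reference or test rows")
        chrom = sub["chrom"].iloc[0]
        expected = sub["expected_parent"].iloc[0]

        ref_mat = ref["maternal_count"].sum()
        ref_tot = ref_mat + ref["paternal_count"].sum()
        ref_frac = ref_mat / ref_tot if ref_tot > 0 else float("nan")
        if expected == "maternal":
            mono = ref_tot > 0 and ref_frac > config.ase_mono_ratio
        elif expected == "paternal":
            mono = ref_tot > 0 and ref_frac < 1 - config.ase_mono_ratio
        else:  # background gene: not an imprinted candidate
            mono = False

        expressed = bool((test["log2_rpkm"] > config.ase_expr_log2rpkm_min).all())

        n_rep = test["replicate"].nunique()
        need = _required_replicates(n_rep, config.ase_min_replicates)
        resolvable = int((test["snp_count"] > config.ase_snp_count_min).sum()) >= need

        fracs = []
        for _, row in test.sort_values("replicate").iterrows():
            tot = row["maternal_count"] + row["paternal_count"]
            fracs.append(row["maternal_count"] / tot if tot > 0 else float("nan"))
        mean_frac = (float(np.nanmean(fracs))
                     if not all(math.isnan(f) for f in fracs) else float("nan"))
        records.append(
            AseGeneRecord(
                gene=gene,
                chrom=chrom,
                expected_parent=expected,
                reference_maternal_fraction=float(ref_frac),
                replicate_maternal_fraction=fracs,
                mean_maternal_fraction=mean_frac,
                monoallelic_in_reference=bool(mono),
                expressed=expressed,
                resolvable=bool(resolvable),
            )
        )
    return records


def shortlist_genes(df: pd.DataFrame, config: AnalysisConfig,
                    test_sample: str = "iPSC",
                    reference_sample: str = "MEF") -> pd.DataFrame:
    """Apply the three filters; returns one row per gene with flags and pass."""
    records = build_gene_records(df, config, test_sample, reference_sample)
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "chrom": [r.chrom for r in records],
            "expected_parent": [r.expected_parent for r in records],
            "reference_maternal_fraction":
                [round(r.reference_maternal_fraction, 6) for r in records],
            "mean_maternal_fraction":
                [round(r.mean_maternal_fraction, 6) for r in records],
            "monoallelic_in_reference": [r.monoallelic_in_reference for r in records],
            "expressed": [r.expressed for r in records],
            "resolvable": [r.resolvable for r in records],
            "passes": [r.passes for r in records],
        }
    )


def classify_allelic_status(record: AseGeneRecord,
                            config: AnalysisConfig) -> str:
    """Bin the mean expressed-parent fraction of a gene in the test sample.

    ``monoallelic_expected`` keeps the normal imprint; ``monoallelic_switched``
    expresses the normally silenced allele; the middle band is ``biallelic``;
    anything in between is ``biased`` (loss of strict monoallelic expression
    without full biallelism).
    """
    f = record.mean_maternal_fraction
    if math.isnan(f):
        return "not_evaluable"
    f_e = f if record.expected_parent == "maternal" else 1.0 - f
    lo, hi = config.ase_status_biallelic
    if f_e >= config.ase_status_mono:
        return "monoallelic_expected"
    if f_e <= 1 - config.ase_status_mono:
        return "monoallelic_switched"
    if lo <= f_e <= hi:
        return "biallelic"
    return "biased_toward_expected" if f_e > hi else "biased_toward_silenced"


def ase_status_frame(df: pd.DataFrame, config: AnalysisConfig,
                     test_sample: str = "iPSC",
                     reference_sample: str = "MEF") -> pd.DataFrame:
    records = build_gene_records(df, config, test_sample, reference_sample)
    short = shortlist_genes(df, config, test_sample, reference_sample)
    short["status"] = [
        classify_allelic_status(r, config) if r.passes else "filtered"
        for r in records
    ]
    expected = np.where(short["expected_parent"] == "maternal",
                        short["mean_maternal_fraction"],
                        1.0 - short["mean_maternal_fraction"])
    short["mean_expressed_parent_fraction"] = np.round(expected.astype(float), 6)
    return short


def detect_upd(df: pd.DataFrame, config: AnalysisConfig,
               test_sample: str = "iPSC") -> pd.DataFrame:
    """Chromosome-level uniparental disomy scan on one sample.

    Per chromosome with at least ``upd_min_genes`` SNP-informative genes
    (genes with any allele-assigned reads in the test sample), the median of
    the per-gene pooled maternal fraction is compared against the UPD
    thresholds.  Medians are robust to the handful of legitimately
    monoallelic imprinted genes on a normal chromosome.
    """
    test = df[df["sample"] == test_sample]
    rows = []
    for chrom, sub in test.groupby("chrom", sort=True):
        per_gene = []
        for gene, g in sub.groupby("gene"):
            tot = (g["maternal_count"] + g["paternal_count"]).sum()
            if tot == 0:
                continue
            per_gene.append(g["maternal_count"].sum() / tot)
        if len(per_gene) < config.upd_min_genes:
            rows.append({"chrom": chrom, "n_genes": len(per_gene),
                         "median_maternal_fraction": float("nan"),
                         "upd": "not_evaluated"})
            continue
        med = float(np.median(per_gene))
        if med >= config.upd_median_threshold:
            call = "maternal_upd"
        elif med <= 1 - config.upd_median_threshold:
            call = "paternal_upd"
        else:
            call = "none"
        rows.append({"chrom": chrom, "n_genes": len(per_gene),
                     "median_maternal_fraction": round(med, 6), "upd": call})
    return pd.DataFrame(rows)


def ase_heatmap_matrix(df: pd.DataFrame, config: AnalysisConfig,
                       samples: Sequence[str],
                       reference_sample: str = "MEF") -> pd.DataFrame:
    """genes x samples mean expressed-parent fraction (heatmap data layer)."""
    frames = {}
    for sample in samples:
        status = ase_status_frame(df, config, test_sample=sample,
                                  reference_sample=reference_sample)
        frames[sample] = status.set_index("gene")["mean_expressed_parent_fraction"]
    return pd.DataFrame(frames)
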