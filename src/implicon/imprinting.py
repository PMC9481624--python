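"""Region-level imprinting classification and epiallele heterogeneity.

Classification applies the published status rule to the per-allele mean
methylation of a covered region: a normal imprint has strictly more than 75%
methylation on the expected-methylated allele (M) and strictly less than 25%
on the other (U).  Failing the M rule is a hypomethylation defect, graded
complete (M < 10), partial (30 <= M <= 70) or mild (the in-between bands
10-30 and 70-75); failing the U rule (U >= 25) is a hypermethylation defect.
Both defects are assessed independently so a region can carry both.
Unmethylated controls are aberrant when either allele reaches 25%;
methylated controls when either allele drops to 75% or below.

The epiallele layer looks at single molecules: a molecule whose methylated
fraction over its informative CpGs is >= 0.9 is fully methylated, <= 0.1
fully unmethylated, anything else mosaic.  A cell population that has lost
imprinting in some cells but not others shows up as a mixture of the two
extreme epialleles; uniform partial methylation shows up as mosaic molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .config import AnalysisConfig
from .methcall import METH, MoleculeCall, RegionAlleleSummary
from .panel import AmpliconRegion

LABELS = ("normal", "hypomethylated", "hypermethylated", "both_defects",
          "control_ok", "control_aberrant", "not_evaluable")


@dataclass
class EpialleleFractions:
    """Per-allele composition of single-molecule methylation patterns."""

    fully_methylated: float
    fully_unmethylated: float
    mosaic: float
    n_molecules: int
    sufficient: bool

    def as_tuple(self):
        return (self.fully_methylated, self.fully_unmethylated, self.mosaic)


@dataclass
class ImprintCall:
    """Classification of one region x sample."""

    region: str
    sample: str
    label: str
    severity: str                     # complete | partial | mild | none
    loss_magnitude: float             # percentage points below full methylation (M allele)
    gain_magnitude: float             # percentage points gained on the U allele
    meth_allele_pct: float            # M
    unmeth_allele_pct: float          # U
    epiallele: Optional[Dict[str, EpialleleFractions]] = None
    heterogeneity: str = "insufficient"
    retained_fraction: float = float("nan")


def _hypo_severity(m: float, config: AnalysisConfig) -> str:
    if m < config.complete_loss_max:
        return "complete"
    lo, hi = config.partial_band
    if lo <= m <= hi:
        return "partial"
    return "mild"


def classify_imprint(summary: RegionAlleleSummary, region: AmpliconRegion,
                     config: AnalysisConfig) -> ImprintCall:
    """Apply the imprint status rule to one covered region summary.

    Regions that failed the coverage filter or sit on the exclusion list are
    ``not_evaluable``.  All comparisons are strict: a methylated-allele mean
    of exactly 75% is already a (mild) hypomethylation defect, and an
    unmethylated-allele mean of exactly 25% is already hypermethylation.
    """
    if not summary.pass_coverage or summary.excluded_reason is not None:
        return ImprintCall(region.name, summary.sample, "not_evaluable", "none",
                           float("nan"), float("nan"), float("nan"), float("nan"))

    mat = summary.maternal.mean_pct
    pat = summary.paternal.mean_pct

    if region.methylated_allele is None:  # control region
        if region.region_class == "control_unmethylated":
            aberrant = (mat >= config.normal_unmeth_max
                        or pat >= config.normal_unmeth_max)
        else:
            aberrant = (mat <= config.normal_meth_min
                        or pat <= config.normal_meth_min)
        label = "control_aberrant" if aberrant else "control_ok"
        return ImprintCall(region.name, summary.sample, label, "none",
                           float("nan"), float("nan"), mat, pat)

    m = mat if region.methylated_allele == "maternal" else pat
    u = pat if region.methylated_allele == "maternal" else mat
    hypo = not (m > config.normal_meth_min)
    hyper = u >= config.normal_unmeth_max
    if hypo and hyper:
        label = "both_defects"
    elif hypo:
        label = "hypomethylated"
    elif hyper:
        label = "hypermethylated"
    else:
        label = "normal"
    severity = _hypo_severity(m, config) if hypo else "none"
    return ImprintCall(region.name, summary.sample, label, severity,
                       loss_magnitude=100.0 - m, gain_magnitude=u,
                       meth_allele_pct=m, unmeth_allele_pct=u)


def epiallele_partition(unique_calls: Sequence[MoleculeCall],
                        region: AmpliconRegion,
                        config: AnalysisConfig) -> Dict[str, EpialleleFractions]:
    """Per-allele fractions of fully methylated / fully unmethylated / mosaic
    molecules.

    A molecule qualifies when at least ``epiallele_min_informative`` of the
    region's CpGs carry an informative call; alleles with fewer than
    ``epiallele_min_molecules`` qualifying molecules are marked insufficient.
    """
    need = config.epiallele_min_informative * region.n_cpgs
    out: Dict[str, EpialleleFractions] = {}
    for allele in ("maternal", "paternal"):
        n_full = n_empty = n_mosaic = 0
        for call in unique_calls:
            if call.allele != allele:
                continue
            informative = call.states != -1
            n_info = int(informative.sum())
            if n_info < need:
                continue
            f = float((call.states[informative] == METH).mean())
            if f >= config.epiallele_high:
                n_full += 1
            elif f <= config.epiallele_low:
                n_empty += 1
            else:
                n_mosaic += 1
        n = n_full + n_empty + n_mosaic
        if n < config.epiallele_min_molecules:
            out[allele] = EpialleleFractions(float("nan"), float("nan"),
                                             float("nan"), n, sufficient=False)
        else:
            out[allele] = EpialleleFractions(n_full / n, n_empty / n,
                                             n_mosaic / n, n, sufficient=True)
    return out


def infer_heterogeneity(fractions: Dict[str, EpialleleFractions],
                        region: AmpliconRegion,
                        config: AnalysisConfig) -> tuple[str, float]:
    """Label the cell-population structure on the normally methylated allele.

    mixture: both extreme epialleles present at >= ``mixture_floor`` —
    some cells retained the imprint, others erased it.  uniform_partial:
    mosaic molecules dominate — all cells partially methylated.  homogeneous
    otherwise.  Returns ``(label, retained_fraction)`` where the retained
    fraction is the fully-methylated share.
    """
    allele = region.methylated_allele or "maternal"
    fr = fractions.get(allele)
    if fr is None or not fr.sufficient:
        return "insufficient", float("nan")
    if (fr.fully_methylated >= config.mixture_floor
            and fr.fully_unmethylated >= config.mixture_floor):
        return "mixture", fr.fully_methylated
    if fr.mosaic > config.mosaic_majority:
        return "uniform_partial", fr.fully_methylated
    return "homogeneous", fr.fully_methylated


def analyse_regions(
    summaries: Sequence[RegionAlleleSummary],
    calls_by_region: Dict[str, List[MoleculeCall]],
    regions: Dict[str, AmpliconRegion],
    config: AnalysisConfig,
) -> List[ImprintCall]:
    """classify + epiallele partition + heterogeneity for every summary."""
    out = []
    for s in summaries:
        region = regions[s.region]
        call = classify_imprint(s, region, config)
        fractions = epiallele_partition(calls_by_region.get(s.region, []),
                                        region, config)
        call.epiallele = fractions
        call.heterogeneity, call.retained_fraction = infer_heterogeneity(
            fractions, region, config)
        out.append(call)
    return out


def imprint_calls_frame(calls: Sequence[ImprintCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "sample": c.sample,
            "region": c.region,
            "label": c.label,
            "severity": c.severity,
            "meth_allele_pct": round(c.meth_allele_pct, 4),
            "unmeth_allele_pct": round(c.unmeth_allele_pct, 4),
            "loss_magnitude": round(c.loss_magnitude, 4),
            "gain_magnitude": round(c.gain_magnitude, 4),
            "heterogeneity": c.heterogeneity,
            "retained_fraction": round(c.retained_fraction, 4)
            if not math.isnan(c.retained_fraction) else float("nan"),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def epiallele_frame(calls: Sequence[ImprintCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        if not c.epiallele:
            continue
        for allele in ("maternal", "paternal"):
            fr = c.epiallele[allele]
            rows.append(
                {
                    "sample": c.sample,
                    "region": c.region,
                    "allele": allele,
                    "fully_methylated": round(fr.fully_methylated, 6),
                    "fully_unmethylated": round(fr.fully_unmethylated, 6),
                    "mosaic": round(fr.mosaic, 6),
                    "n_molecules": fr.n_molecules,
                    "sufficient": fr.sufficient,
                }
            )
    return pd.DataFrame(rows)


def heatmap_matrix(summaries: Sequence[RegionAlleleSummary]) -> pd.DataFrame:
    """samples x (region, allele) mean % methylation — the heatmap data layer."""
    rows = []
    for s in summaries:
        for allele in ("maternal", "paternal"):
            stats = s.allele_stats(allele)
            rows.append(
                {
                    "sample": s.sample,
                    "column": f"{s.region}|{allele}",
                    "pct": float("nan") if stats is None
                    else round(stats.mean_pct, 4),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.pivot(index="sample", columns="column", values="pct")


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Optional PNG rendering of the heatmap matrix (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * matrix.shape[1]),
                                    max(2, 0.4 * matrix.shape[0])))
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=100, cmap="coolwarm",
                   aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, label="% methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
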