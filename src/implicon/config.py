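"""Analysis configuration: every published threshold in one place.

All thresholds printed with a strict inequality in the source assay
description (">40 reads", ">75 % / <25 %", "<10 %", "90:10", "Log2 RPKM > 1",
"counts > 5") are applied strictly: boundary values fail the check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    Defaults encode the assay's published values; everything can be
    overridden from YAML (see :func:`AnalysisConfig.from_yaml`).
    """

    # --- library structure ---------------------------------------------
    umi_length: int = 8              # in-line UMI at the start of Read 2 (bases)
    read_length: int = 250           # paired-end read length (bases)

    # --- preprocessing --------------------------------------------------
    quality_trim_cutoff: int = 20    # Phred cutoff for 3' running-sum trimming
    min_length_after_trim: int = 20  # pairs with a shorter mate are dropped
    adapter: str = "AGATCGGAAGAGC"   # Illumina adapter prefix searched at 3' end

    # --- alignment -------------------------------------------------------
    min_identity: float = 0.9        # accept placements with identity strictly above
    ambiguity_margin: float = 0.05   # best region must beat second best by this much
    seed_kmer: int = 24              # seed k-mer length for candidate lookup

    # --- methylation calling / coverage ---------------------------------
    min_base_quality: int = 20       # Phred floor for CpG and SNP base calls
    min_reads_per_allele: int = 40   # strict '>' on deduplicated molecules per allele
    conflicting_warn_fraction: float = 0.05

    # --- imprint classification (percent methylation) --------------------
    normal_meth_min: float = 75.0    # methylated allele must exceed this
    normal_unmeth_max: float = 25.0  # unmethylated allele must stay below this
    complete_loss_max: float = 10.0  # below: complete loss of methylation
    partial_band: Tuple[float, float] = (30.0, 70.0)  # partial-loss band

    # --- epiallele / heterogeneity ---------------------------------------
    epiallele_high: float = 0.9      # per-molecule methylated fraction >= : fully methylated
    epiallele_low: float = 0.1       # <= : fully unmethylated
    epiallele_min_informative: float = 0.5  # fraction of CpGs a molecule must cover
    epiallele_min_molecules: int = 20
    mixture_floor: float = 0.2       # both extreme fractions >= : mixed cell population
    mosaic_majority: float = 0.5     # mosaic fraction > : uniform partial methylation

    # --- allele-specific expression --------------------------------------
    ase_mono_ratio: float = 0.9      # 90:10 monoallelic filter in reference tissue
    ase_expr_log2rpkm_min: float = 1.0
    ase_snp_count_min: float = 5.0
    ase_min_replicates: Tuple[int, int] = (2, 3)  # "2 of 3" rule; generalises to ceil(2n/3)
    ase_normalise: bool = False      # CPM-scale SNP counts before the >5 filter
    ase_status_mono: float = 0.9     # bins for allelic-status classification
    ase_status_biallelic: Tuple[float, float] = (1 / 3, 2 / 3)
    upd_min_genes: int = 5
    upd_median_threshold: float = 0.95

    # --- randomness -------------------------------------------------------
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("normal_meth_min", "normal_unmeth_max", "complete_loss_max"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        lo, hi = self.partial_band
        if not (0 <= lo <= hi <= 100):
            raise ValueError(f"partial_band={self.partial_band} invalid")
        if self.normal_unmeth_max >= self.normal_meth_min:
            raise ValueError("normal_unmeth_max must be < normal_meth_min")
        if self.epiallele_low >= self.epiallele_high:
            raise ValueError("epiallele_low must be < epiallele_high")
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")

    # --- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["partial_band"] = list(self.partial_band)
        d["ase_min_replicates"] = list(self.ase_min_replicates)
        d["ase_status_biallelic"] = list(self.ase_status_biallelic)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("partial_band", "ase_min_replicates", "ase_status_biallelic"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
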