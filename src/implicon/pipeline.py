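"""Pipeline orchestration, run reports and end-to-end check scenarios.

Stage order mirrors the assay's processing: UMI relocation and trimming,
bisulfite-space placement, CpG calling, UMI deduplication, allele splitting,
per-region summaries with coverage/exclusion/run-merge filters, then the
imprinting analysis.  Every run emits a JSON report whose stage counters
reconcile exactly (pairs in = placed + unplaced-by-reason + rejected) and a
manifest with a checksum for every file written; identical seed and config
give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import ase as ase_mod
from . import simulate as sim
from .align import convert_panel_references, place_pairs
from .config import AnalysisConfig
from .imprinting import (analyse_regions, epiallele_frame, heatmap_matrix,
                         imprint_calls_frame)
from .methcall import (MoleculeCall, apply_exclusions, deduplicate, merge_runs,
                       molecule_matrix_frame, pair_to_molecule_call,
                       summaries_to_frames, summarize_region)
from .panel import AmpliconRegion, default_panel, load_panel
from .preprocess import preprocess_pairs, read_fastq_pairs

log = logging.getLogger(__name__)

UNPLACED_KEYS = ("unplaced_low_identity", "unplaced_ambiguous",
                 "unplaced_mate_conflict")


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    seed: int
    counters: Dict[str, int] = field(default_factory=dict)
    manifest: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: List[str] = field(default_factory=list)

    def reconciles(self) -> bool:
        c = self.counters
        accounted = (
            c.get("umi_rejected", 0)
            + c.get("trim_dropped", 0)
            + c.get("placed", 0)
            + sum(c.get(k, 0) for k in UNPLACED_KEYS)
        )
        return c.get("pairs_in", 0) == accounted

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "counters": dict(sorted(self.counters.items())),
            "manifest": dict(sorted(self.manifest.items())),
            "stages": self.stages,
            "reconciles": self.reconciles(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def run_reads_pipeline(
    raw_pairs: Iterable,
    regions: Sequence[AmpliconRegion],
    config: AnalysisConfig,
    sample: str = "sample",
    sample_group: str = "default",
    run_id: str = "run1",
    counters: Optional[dict] = None,
):
    """preprocess -> place -> call -> dedup -> summarize over in-memory pairs.

    Returns ``(summaries, calls_by_region, counters)``.  This is the
    computational core shared by :func:`run_pipeline` (which feeds it from
    FASTQ files) and by simulation-based checks that skip the file system.
    """
    c = counters if counters is not None else {}
    refs = convert_panel_references(regions, k=config.seed_kmer)
    region_by_name = {r.name: r for r in regions}
    calls_raw: Dict[str, List[MoleculeCall]] = {r.name: [] for r in regions}

    tagged = preprocess_pairs(raw_pairs, config, counters=c)
    for pair, aln in place_pairs(tagged, refs, config, counters=c):
        region = region_by_name[aln.region]
        calls_raw[aln.region].append(
            pair_to_molecule_call(aln, pair, region, config))

    c["molecules_pre_dedup"] = sum(len(v) for v in calls_raw.values())
    calls_dedup = {name: deduplicate(v) for name, v in calls_raw.items()}
    c["molecules_post_dedup"] = sum(len(v) for v in calls_dedup.values())

    summaries = [
        summarize_region(calls_dedup[r.name], r, sample, config,
                         sample_group=sample_group, run_id=run_id)
        for r in regions
    ]
    c["regions_pass_coverage"] = sum(s.pass_coverage for s in summaries)
    c["regions_fail_coverage"] = sum(not s.pass_coverage for s in summaries)
    total = c["molecules_post_dedup"]
    conflicting = sum(s.n_conflicting for s in summaries)
    c["conflicting_fraction_pct"] = round(100 * conflicting / total, 3) if total else 0
    return summaries, calls_dedup, c


def _pairs_from_batch(batch: sim.ReadBatch):
    """Adapt an in-memory simulated batch to the raw-pair stream interface."""
    from .preprocess import RawRead

    for rid, s1, q1, s2, q2 in zip(batch.ids, batch.r1_seq, batch.r1_qual,
                                   batch.r2_seq, batch.r2_qual):
        yield RawRead(rid, s1, q1), RawRead(rid, s2, q2)


def run_pipeline(config_path: str | Path) -> RunReport:
    """Execute the full pipeline from a YAML run configuration.

    Expected keys::

        sample: {id: ..., group: ..., }
        inputs:                       # one entry per sequencing run
          - {run_id: run1, r1: path, r2: path}
        panel: {panel: path, snps: path, fasta: path}   # omit for the packaged panel
        output_dir: path
        analysis: {<AnalysisConfig overrides>}
        exclusions: [{group: ..., chrom: ..., start: ..., end: ...}]
    """
    cfg_path = Path(config_path)
    raw_cfg = yaml.safe_load(cfg_path.read_text())
    config = AnalysisConfig.from_dict(raw_cfg.get("analysis", {}) or {})
    report = RunReport(config=raw_cfg, seed=config.rng_seed)

    stage = "panel_core"
    try:
        panel_cfg = raw_cfg.get("panel") or {}
        if panel_cfg:
            for key in ("panel", "snps", "fasta"):
                p = panel_cfg.get(key)
                if p is not None and not Path(p).exists():
                    raise PipelineError(stage, f"missing {key} file: {p}")
            regions = load_panel(panel_cfg["panel"], panel_cfg.get("snps"),
                                 panel_cfg.get("fasta"))
        else:
            regions = default_panel()
        if not regions:
            raise PipelineError(stage, "panel is empty")
        report.stages.append(stage)

        sample = raw_cfg.get("sample", {}).get("id", "sample")
        group = raw_cfg.get("sample", {}).get("group", "default")
        outdir = Path(raw_cfg["output_dir"])
        outdir.mkdir(parents=True, exist_ok=True)

        stage = "reads"
        all_summaries = []
        calls_by_region: Dict[str, List[MoleculeCall]] = {}
        for entry in raw_cfg["inputs"]:
            run_id = entry.get("run_id", "run1")
            for key in ("r1", "r2"):
                if not Path(entry[key]).exists():
                    raise PipelineError(stage, f"missing FASTQ: {entry[key]}")
            summaries, calls, _ = run_reads_pipeline(
                read_fastq_pairs(entry["r1"], entry["r2"]),
                regions, config, sample=sample, sample_group=group,
                run_id=run_id, counters=report.counters,
            )
            all_summaries.extend(summaries)
            # molecule matrix reflects the runs kept after merging; for the
            # common single-run case this is simply the run's calls
            for name, v in calls.items():
                calls_by_region.setdefault(name, []).extend(v)
        report.stages.extend(["preprocess", "bsalign", "methcall"])

        stage = "filters"
        merged = merge_runs(all_summaries)
        exclusions = [
            (e["group"], e["chrom"], int(e["start"]), int(e["end"]))
            for e in raw_cfg.get("exclusions", []) or []
        ]
        filtered = apply_exclusions(merged, exclusions)
        report.counters["regions_excluded"] = sum(
            1 for s in filtered if s.excluded_reason)
        report.stages.append(stage)

        stage = "imprint_analysis"
        region_map = {r.name: r for r in regions}
        imprint_calls = analyse_regions(filtered, calls_by_region, region_map,
                                        config)
        report.stages.append(stage)

        stage = "outputs"
        frames = summaries_to_frames(filtered, region_map)
        outputs = {
            "region_summary.tsv": frames["region_summary"],
            "cpg_methylation.tsv": frames["cpg_methylation"],
            "molecule_matrix.tsv": molecule_matrix_frame(calls_by_region, sample),
            "imprint_calls.tsv": imprint_calls_frame(imprint_calls),
            "epiallele_fractions.tsv": epiallele_frame(imprint_calls),
        }
        hm = heatmap_matrix(filtered)
        outputs["heatmap_matrix.tsv"] = hm.reset_index()
        for name, df in outputs.items():
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            report.manifest[name] = _sha256(path)
        report.stages.append(stage)
    except PipelineError:
        (Path(raw_cfg.get("output_dir", ".")) / "run_report.json").parent.mkdir(
            parents=True, exist_ok=True)
        report.to_json(Path(raw_cfg.get("output_dir", ".")) / "run_report.json")
        raise
    report_path = outdir / "run_report.json"
    report.to_json(report_path)
    return report


# ---------------------------------------------------------------------------
# named end-to-end scenarios
# ---------------------------------------------------------------------------

def _scenario_profiles(name: str, regions: Sequence[AmpliconRegion]
                       ) -> Dict[str, sim.EpialleleProfile]:
    profiles = {r.name: sim.canonical_profile(r) for r in regions}
    if name == "canonical_panel":
        pass
    elif name == "female_hypomethylation":
        for r in regions:
            if r.methylated_allele is not None:
                profiles[r.name] = sim.flat_profile(
                    r,
                    p_maternal=0.05 if r.methylated_allele == "maternal" else 0.03,
                    p_paternal=0.05 if r.methylated_allele == "paternal" else 0.03,
                )
    elif name == "male_dlk1_gain":
        r = next(x for x in regions if x.name == "Dlk1-Dio3")
        profiles[r.name] = sim.flat_profile(r, p_maternal=0.85, p_paternal=0.97)
    elif name == "mixture_60_40":
        r = next(x for x in regions if x.name == "Gnas")
        profiles[r.name] = sim.mixture_profile(r, intact_weight=0.6,
                                               allele="maternal")
    else:
        raise ValueError(
            f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}")
    return profiles


def _check_labels(imprint_calls, expectation) -> Tuple[bool, dict]:
    details = {}
    ok = True
    for call in imprint_calls:
        expected = expectation(call)
        got = call.label
        details[call.region] = {"expected": expected, "observed": got}
        ok = ok and (got == expected)
    return ok, details


def end_to_end_check(scenario: str, seed: int, n_per_region: int = 200,
                     workdir: Optional[Path] = None) -> dict:
    """Run a named scenario and assert its expected labels.

    Scenarios: ``canonical_panel`` (all normal / control_ok),
    ``female_hypomethylation`` (complete loss on every ICR's methylated
    allele), ``male_dlk1_gain`` (hypermethylation of the normally
    unmethylated maternal allele at Dlk1-Dio3 only), ``mixture_60_40``
    (60:40 intact:erased maternal mixture at Gnas -> mixture heterogeneity),
    ``upd_chr6`` (ASE scan flags maternal UPD on chr6 only).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {sorted(SCENARIOS)}")
    config = AnalysisConfig(rng_seed=seed)
    t0 = time.time()

    if scenario == "upd_chr6":
        tables = sim.simulate_ase_table(80, config, seed, upd_chrom="chr6")
        merged = tables["counts"].merge(tables["expr"],
                                        on=["gene", "sample", "replicate"])
        upd = ase_mod.detect_upd(merged, config)
        flagged = upd[upd["upd"] == "maternal_upd"]["chrom"].tolist()
        others = upd[(upd["upd"] != "maternal_upd")
                     & (upd["upd"] != "not_evaluated")]["chrom"].tolist()
        passed = flagged == ["chr6"]
        return {"scenario": scenario, "passed": bool(passed),
                "details": {"maternal_upd": flagged, "unflagged": others},
                "elapsed_s": round(time.time() - t0, 2)}

    regions = default_panel()
    profiles = _scenario_profiles(scenario, regions)
    batch = sim.simulate_dataset(regions, profiles, n_per_region, seed)
    summaries, calls, counters = run_reads_pipeline(
        _pairs_from_batch(batch), regions, config)
    region_map = {r.name: r for r in regions}
    imprint_calls = analyse_regions(summaries, calls, region_map, config)

    def canonical_expect(call):
        cls = region_map[call.region].region_class
        return "control_ok" if cls.startswith("control") else "normal"

    if scenario == "canonical_panel":
        ok, details = _check_labels(imprint_calls, canonical_expect)
    elif scenario == "female_hypomethylation":
        def expect(call):
            cls = region_map[call.region].region_class
            return "control_ok" if cls.startswith("control") else "hypomethylated"
        ok, details = _check_labels(imprint_calls, expect)
        severities = {c.region: c.severity for c in imprint_calls
                      if c.label == "hypomethylated"}
        ok = ok and all(v == "complete" for v in severities.values())
        details["severities"] = severities
    elif scenario == "male_dlk1_gain":
        def expect(call):
            if call.region == "Dlk1-Dio3":
                return "hypermethylated"
            return canonical_expect(call)
        ok, details = _check_labels(imprint_calls, expect)
    elif scenario == "mixture_60_40":
        gnas = next(c for c in imprint_calls if c.region == "Gnas")
        ok = gnas.heterogeneity == "mixture"
        details = {"Gnas": {"heterogeneity": gnas.heterogeneity,
                            "retained_fraction": gnas.retained_fraction}}
        others_ok, other_details = _check_labels(
            [c for c in imprint_calls if c.region != "Gnas"], canonical_expect)
        ok = ok and others_ok
        details.update(other_details)
    return {"scenario": scenario, "passed": bool(ok), "details": details,
            "counters": counters, "elapsed_s": round(time.time() - t0, 2)}


SCENARIOS = ("canonical_panel", "female_hypomethylation", "male_dlk1_gain",
             "mixture_60_40", "upd_chr6")
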