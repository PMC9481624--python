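"""Imprint classification rules and epiallele heterogeneity inference."""

import numpy as np
import pytest

from implicon.imprinting import (EpialleleFractions, classify_imprint,
                                 epiallele_partition, infer_heterogeneity)
from implicon.methcall import AlleleStats, MoleculeCall, RegionAlleleSummary
from implicon.panel import AmpliconRegion


def _region(region_class, n_cpg=10):
    return AmpliconRegion("R", "chr1", 0, 400, "top", region_class,
                          cpg_positions=list(range(10, 10 + 4 * n_cpg, 4)))


def _summary(mat_pct, pat_pct, n=100, pass_coverage=True, excluded=None):
    def stats(pct):
        meth = np.full(5, round(n * pct / 100))
        unmeth = np.full(5, n) - meth
        return AlleleStats(n, meth, unmeth, np.zeros(5, int))

    return RegionAlleleSummary("R", "chr1", 0, 400, "s", "g", "run1",
                               stats(mat_pct), stats(pat_pct), 0, 0,
                               pass_coverage, excluded)


def independent_rule(region_class, m_allele_pct, u_allele_pct, cfg):
    """Brute-force re-statement of the classification rules, coded separately."""
    if region_class == "control_unmethylated":
        if m_allele_pct >= 25 or u_allele_pct >= 25:
            return "control_aberrant"
        return "control_ok"
    if region_class == "control_methylated":
        if m_allele_pct <= 75 or u_allele_pct <= 75:
            return "control_aberrant"
        return "control_ok"
    hypo = m_allele_pct <= 75
    hyper = u_allele_pct >= 25
    if hypo and hyper:
        return "both_defects"
    if hypo:
        return "hypomethylated"
    if hyper:
        return "hypermethylated"
    return "normal"


class TestClassifyImprint:
    @pytest.mark.parametrize("m,u,label,severity", [
        (90, 5, "normal", "none"),
        (8, 4, "hypomethylated", "complete"),
        (50, 5, "hypomethylated", "partial"),
        (72, 5, "hypomethylated", "mild"),   # 70-75 gap maps to mild
        (20, 5, "hypomethylated", "mild"),   # 10-30 gap maps to mild
        (75, 5, "hypomethylated", "mild"),   # boundary: strictly > 75 required
        (90, 25, "hypermethylated", "none"),  # boundary: strictly < 25 required
        (60, 40, "both_defects", "partial"),
    ])
    def test_rule_table_maternal_icr(self, config, m, u, label, severity):
        region = _region("maternal_methylated_ICR")
        call = classify_imprint(_summary(m, u), region, config)
        assert (call.label, call.severity) == (label, severity)

    def test_paternal_icr_maps_alleles(self, config):
        region = _region("paternal_methylated_ICR")
        # maternal allele (normally unmethylated) at 85% -> hypermethylated
        call = classify_imprint(_summary(85, 90), region, config)
        assert call.label == "hypermethylated"
        assert call.gain_magnitude == pytest.approx(85, abs=1)

    def test_failed_coverage_not_evaluable(self, config):
        region = _region("maternal_methylated_ICR")
        call = classify_imprint(_summary(90, 5, pass_coverage=False), region,
                                config)
        assert call.label == "not_evaluable"
        call = classify_imprint(_summary(90, 5, excluded="listed"), region,
                                config)
        assert call.label == "not_evaluable"

    @pytest.mark.parametrize("region_class", [
        "maternal_methylated_ICR", "paternal_methylated_ICR",
        "control_unmethylated", "control_methylated",
    ])
    def test_oracle_grid(self, config, region_class):
        """Exhaustive agreement with an independently coded rule set."""
        region = _region(region_class)
        for m in range(0, 101, 5):
            for u in range(0, 101, 5):
                call = classify_imprint(_summary(m, u), region, config)
                if region_class == "paternal_methylated_ICR":
                    expected = independent_rule(region_class, u, m, config)
                else:
                    expected = independent_rule(region_class, m, u, config)
                assert call.label == expected, (region_class, m, u)


def _molecules(region, n_full, n_empty, n_mosaic, allele="maternal"):
    calls = []
    C = region.n_cpgs
    for kind, n in (("full", n_full), ("empty", n_empty), ("mosaic", n_mosaic)):
        for i in range(n):
            if kind == "full":
                states = np.ones(C, np.int8)
            elif kind == "empty":
                states = np.zeros(C, np.int8)
            else:
                states = np.array([i % 2 for i in range(C)], np.int8)
            calls.append(MoleculeCall(region.name, allele, states, f"{kind}{i}",
                                      (0, region.length)))
    return calls


class TestEpialleles:
    def test_direct_count_partition(self, config):
        region = _region("maternal_methylated_ICR")
        fr = epiallele_partition(_molecules(region, 60, 40, 0), region, config)
        assert fr["maternal"].as_tuple() == (0.6, 0.4, 0.0)
        assert not fr["paternal"].sufficient

    def test_all_mosaic(self, config):
        region = _region("maternal_methylated_ICR")
        fr = epiallele_partition(_molecules(region, 0, 0, 40), region, config)
        assert fr["maternal"].as_tuple() == (0.0, 0.0, 1.0)

    def test_insufficient_below_twenty(self, config):
        region = _region("maternal_methylated_ICR")
        fr = epiallele_partition(_molecules(region, 6, 4, 0), region, config)
        assert not fr["maternal"].sufficient

    def test_uninformative_molecules_skipped(self, config):
        region = _region("maternal_methylated_ICR")
        calls = _molecules(region, 25, 0, 0)
        for c in calls[:5]:
            c.states[:] = -1  # fewer than half informative CpGs
        fr = epiallele_partition(calls, region, config)
        assert fr["maternal"].n_molecules == 20

    @pytest.mark.parametrize("fractions,expected,retained", [
        ((0.6, 0.4, 0.0), "mixture", 0.6),
        ((0.05, 0.05, 0.9), "uniform_partial", 0.05),
        ((1.0, 0.0, 0.0), "homogeneous", 1.0),
        ((0.85, 0.1, 0.05), "homogeneous", 0.85),
    ])
    def test_heterogeneity_rules(self, config, fractions, expected, retained):
        region = _region("maternal_methylated_ICR")
        fr = {"maternal": EpialleleFractions(*fractions, 100, True),
              "paternal": EpialleleFractions(0, 1, 0, 100, True)}
        label, ret = infer_heterogeneity(fr, region, config)
        assert label == expected
        assert ret == pytest.approx(retained)

    def test_insufficient_propagates(self, config):
        region = _region("maternal_methylated_ICR")
        fr = {"maternal": EpialleleFractions(float("nan"), float("nan"),
                                             float("nan"), 3, False),
              "paternal": EpialleleFractions(0, 1, 0, 100, True)}
        label, ret = infer_heterogeneity(fr, region, config)
        assert label == "insufficient"
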