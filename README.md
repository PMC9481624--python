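# implicon

Allele-specific analysis of genomic imprinting from targeted amplicon
bisulfite sequencing — from raw paired FASTQ reads with in-line UMIs to
per-allele per-CpG methylation, imprinting-defect classification, read-level
epiallele heterogeneity, and SNP-based allelic-expression / uniparental-disomy
analysis.

## Who this is for

Labs profiling imprinting control regions (ICRs) in F1-hybrid mouse material
(C57BL/6 dam × CAST sire), where dense strain SNPs let every sequencing read
be assigned to its parental chromosome. Typical uses: checking imprint
fidelity in iPSC reprogramming experiments, screening clones for loss or gain
of ICR methylation, and resolving whether a partial methylation defect is a
uniform per-cell change or a mixed cell population.

The package ships a 16-region default panel (13 imprinted ICRs — 11
maternally and 2 paternally methylated — plus two unmethylated and one
methylated control region) over synthetic reference sequences, and a
ground-truthed read simulator, so the entire pipeline runs and is testable
without any sequencing data or genome download.

## The method

Each library places an 8-nt random UMI at the start of Read 2. The pipeline:

1. **UMI extraction** — the first 8 bp of Read 2 move into the read IDs of
   both mates; adapter and 3′-quality trimming (running-sum rule, Q20).
2. **Bisulfite-space placement** — reads and references are compared in the
   C→T-collapsed (three-letter) alphabet, with SNP positions wildcarded, so
   placement is provably independent of methylation state and parental
   allele. Ungapped, seed-k-mer accelerated, identity > 0.9 required.
3. **CpG calling** — at each covered CpG cytosine (design-strand
   orientation): C ⇒ methylated, T ⇒ unmethylated, anything else or
   base quality < Q20 ⇒ missing; mate 1 wins where mates overlap.
4. **UMI deduplication** — PCR duplicates (identical region, span and UMI)
   collapse to one molecule by per-CpG majority vote.
5. **Allele split** — usable strain SNPs (those not destroyed by bisulfite
   conversion, e.g. C/T SNPs on a converted strand) vote maternal/paternal;
   mixed support ⇒ conflicting (counted, excluded).
6. **Summaries and classification** — per region × allele:
   %meth = meth/(meth+unmeth) per CpG, mean across CpGs; regions need
   strictly >40 deduplicated molecules per allele. A normal imprint has
   >75% methylation on the expected allele (M) and <25% on the other (U);
   M ≤ 75 is hypomethylation (complete < 10, partial 30–70, mild otherwise),
   U ≥ 25 is hypermethylation — assessed independently, so dual defects are
   reportable.
7. **Epialleles** — per deduplicated molecule, the methylated fraction f over
   its informative CpGs bins it as fully methylated (f ≥ 0.9), fully
   unmethylated (f ≤ 0.1) or mosaic; a mixture of the two extremes on the
   normally methylated allele indicates a mixed cell population.
8. **ASE / UPD** — from per-gene SNP count tables: genes are shortlisted when
   monoallelic in the reference tissue (strictly beyond 90:10), expressed in
   all test replicates (Log2 RPKM > 1) and resolvable (SNP counts > 5 in
   ≥ 2 of 3 replicates); chromosome-level uniparental disomy is flagged when
   the median maternal fraction over ≥5 informative genes is ≥ 0.95 (or
   ≤ 0.05).

## Worked example

Simulate a canonical (imprint-intact) library over the default panel and run
the pipeline:

```bash
implicon simulate --n 150 --seed 4 --out sim
cat > run.yaml <<'YAML'
sample: {id: demo, group: demo}
inputs:
  - {run_id: run1, r1: sim_R1.fastq.gz, r2: sim_R2.fastq.gz}
output_dir: out
analysis: {rng_seed: 4}
YAML
implicon run --config run.yaml
```

`out/imprint_calls.tsv` then contains one row per region, e.g.:

```
sample  region        label   severity  meth_allele_pct  unmeth_allele_pct  heterogeneity
demo    Commd1-Zrsr1  normal  none      95.6699          3.8202             homogeneous
demo    Dlk1-Dio3     normal  none      96.8383          3.4009             homogeneous
demo    Gnas          normal  none      96.3964          3.9301             homogeneous
```

Every region of the intact library is `normal` (controls `control_ok`): the
expected-methylated allele sits near the simulated 97% (the shortfall from
100% is bisulfite conversion error and sampling), the other allele near 3%,
and the single-molecule layer is `homogeneous` — no sign of a mixed cell
population. `out/region_summary.tsv` holds the per-allele molecule counts and
means (maternal listed first), `out/molecule_matrix.tsv` the per-molecule
CpG state strings behind the read-level plots, and `out/run_report.json` the
stage counters (which always reconcile: pairs in = placed + unplaced +
rejected) plus a checksum manifest.

Allelic expression analysis runs from count tables:

```bash
implicon ase --counts ase_counts.tsv --expr ase_expr.tsv --out ase_out
```

## Scope and limitations

Alignment is ungapped and panel-restricted (no genome-wide mapping, no
indels); only CpG methylation is called (no CHH/CHG); the packaged panel uses
synthetic sequences, not genome extracts; RNA-seq alignment and differential
expression are out of scope (ASE starts from count tables). See
`docs/methods.md` for the model, parameter defaults and design rationale.
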