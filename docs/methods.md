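# Methods

## Problem and model

Genomic imprinting restricts expression of ~150 mammalian genes to one
parental allele, controlled by imprinting control regions (ICRs) that are
methylated on exactly one parental chromosome. In an F1 hybrid of two
divergent inbred strains (C57BL/6 dam × CAST sire) the strains' SNPs make
each sequencing read attributable to its parental chromosome, so targeted
amplicon bisulfite sequencing can measure methylation separately per allele,
and per single DNA molecule.

The package models one amplicon library as a set of target regions, each an
`AmpliconRegion` with a CpG map, strain SNPs, and an expected imprint
configuration (`maternal_methylated_ICR`, `paternal_methylated_ICR`, or an
unmethylated/methylated control). Internally coordinates are 0-based
half-open; reports print 1-based inclusive intervals. The maternal allele is
listed first in every output.

## Synthetic data generator

The generator is first-class, tested code: it produces the statistical
structure the analysis assumes, with full ground truth.

* **Molecules.** Each molecule draws its parental allele 50:50, then a cell
  state from the allele's mixture (weights summing to 1), then each CpG
  independently from the state's per-CpG methylation probability. SNP
  positions carry the drawn allele's base. The canonical germline
  configuration uses 0.97 / 0.03 per-CpG methylation on the
  methylated / unmethylated allele — near-saturation with a realistic
  shortfall; a `noise_free_profile` (1.0 / 0.0, all error rates zero) exists
  for exactness checks.
* **Bisulfite conversion** happens once per molecule (conversion precedes
  PCR): non-CpG cytosines convert to T with probability 0.995
  (`conversion_rate`); methylated CpG cytosines convert with probability
  0.005 (`inappropriate_conversion`). These defaults match routinely reported
  conversion efficiencies of commercial kits.
* **Amplification and sequencing.** Each molecule receives a random N8 UMI
  (uniform over 4^8; collisions are allowed and quantifiable from the truth
  table, with an opt-in `unique_umis` mode for exactness tests) and is
  duplicated 1 + Poisson(mean−1) times (mean 3), guaranteeing every molecule
  is sequenced at least once. Read 1 is the first 250 bases of the converted
  molecule; Read 2 is the UMI plus the reverse complement of the 3′ end.
  Substitution errors at 0.001/base (UMI included); qualities are constant
  Q37 except Q20 at injected errors, which exercises the quality-aware
  calling path without a full error model. Region lengths (300–480 bp) keep
  every pair covering its whole amplicon, so the deduplication span is the
  full region.
* **What is not emulated:** indels, adapter read-through, PhiX spike-in,
  M-bias, strand-asymmetric chemistry, real mm10 sequence context. Passing
  tests therefore demonstrate correctness of the algorithms under the stated
  generative model, not robustness to artefacts absent from it (e.g. indel
  misalignment on real data).
* **ASE tables.** Per gene × replicate, maternal counts are beta-binomial
  (concentration 60) around the true allelic fraction at Poisson depth
  (mean 30 SNP reads/gene). 25% of genes are imprinted (monoallelic at
  0.97/0.03 in the reference tissue, ~70% of them paternally expressed,
  mirroring imprinted-gene catalogues); the rest are biallelic background
  genes — the population a chromosome-wide UPD scan needs. A maternal-UPD
  chromosome forces maternal fraction 1.0 (paternal counts exactly 0). 15%
  of genes are low-expressed so the expression filter has work to do.

## Numerical and design choices

* **Alignment** is ungapped in the C→T-collapsed alphabet, both orientations
  tried (mate 2 is reverse-complement normalised), SNP offsets wildcarded.
  Candidates come from exact 24-mer seeds over the collapsed references;
  reads with no seed hit anywhere are scored exhaustively at every offset of
  every reference. Acceptance requires identity strictly > 0.9 and a margin
  ≥ 0.05 over the best other region; mates disagreeing on the region are
  `mate_conflict`. Collapsed-space scoring makes placement provably
  independent of methylation state (tested property). Identity of random
  sequence against a three-letter reference is ~0.5–0.6, far below the floor.
* **Trimming.** 3′ adapter search anchored on an exact 3-base prefix match
  (≤10% mismatches over the overlap), then BWA-style running-sum quality
  trimming at Q20; pairs are dropped pairwise below 20 nt. Exact parity with
  any external trimmer is a non-goal. The minimum-length and quality cutoffs
  are declared choices, not published values.
* **Strictness.** Every published threshold is applied strictly
  (>40 molecules per allele; >75/<25; <10; >90:10; Log2 RPKM > 1;
  counts > 5): boundary values fail.
* **Severity bands.** Hypomethylation severity is complete (M < 10), partial
  (30 ≤ M ≤ 70) or mild; the bands 10–30 and 70–75, which the published
  wording leaves unnamed, map to "mild" deliberately rather than silently.
* **Coverage filter** counts deduplicated molecules (deduplication precedes
  quantification in the processing order), an explicit resolution of an
  ambiguity in the published wording ("reads").
* **Dedup ties.** Per-CpG majority with ties → missing; allele by modal
  label with ties → conflicting. Conflicting molecules are excluded from
  summaries but reported; above 5% of a region they trigger a warning
  (contamination/chimera proxy).
* **Epiallele cutoffs** (fully methylated f ≥ 0.9, fully unmethylated
  f ≤ 0.1, molecule qualifies with ≥50% informative CpGs, ≥20 molecules per
  allele, mixture floor 0.2, mosaic majority 0.5) are package choices —
  the source material describes these patterns qualitatively — and all sit
  in `AnalysisConfig`.
* **"Normalised cumulative SNP-specific read counts"** is implemented as
  CPM scaling of the per-gene allele-assignable read sum, switchable to raw
  sums (`ase_normalise`); raw is the default because the synthetic libraries
  are orders of magnitude smaller than real ones, making CPM values
  meaningless there.
* **Allelic-status bins** (0.9 / 2⁄3 / 1⁄3 / 0.1 on the expressed-parent
  fraction) interpolate qualitative categories; UPD uses medians so single
  legitimately monoallelic imprinted genes cannot flag a chromosome.
* **Design strand.** The packaged panel targets the top strand throughout
  (the per-region strand is not published); the SNP-usability rule handles
  both strands, calling supports top-strand designs.
* **Determinism.** One master seed spawns per-stage streams
  (`numpy.random.SeedSequence`); identical seed + config give byte-identical
  FASTQ and TSV outputs (tested). Run reports include a counter
  reconciliation identity and a sha256 manifest.

## Problem sizes used in the checks

The packaged checks run at desk scale, chosen to keep the whole suite fast
while leaving comfortable statistical margins: parameter recovery uses 500
molecules/region × 16 regions × 20 seeds with the five truth levels
{0, 0.1, 0.5, 0.9, 1.0} rotating across regions and alleles (the 2-pp
tolerance is ~2.2σ at the worst point, p = 0.5); dedup exactness uses 100
unique-UMI molecules; the mixture check uses ~300 molecules on the mixture
allele; UPD scans 80 genes over 8 chromosomes × 20 seeds.

## Known limitations

Ungapped panel-restricted alignment (indels or off-panel reads on real data
would be lost or rejected, not recovered); no CHH/CHG calling; no M-bias
trimming; no statistical testing between sample groups; bottom-strand
amplicon designs are modelled in the panel but not supported by the calling
path. The mixture-recovery check inherits the irreducible binomial noise of
the generator's state draw: at 300 molecules the recovered fraction carries
σ ≈ 0.029 around the nominal weight even when the pipeline's estimate
matches the realized simulated truth to ±0.01, so a ±0.05 per-seed bound on
the nominal weight holds in only ~92% of seeds.
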