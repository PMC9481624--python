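"""Ground-truthed synthetic hybrid bisulfite amplicon data.

Generates the statistical structure the downstream analysis assumes: F1-hybrid
(BL6 x CAST) molecules drawn 50:50 from the two parental alleles, per-allele
cell-state mixtures with per-CpG methylation probabilities, stochastic
bisulfite conversion, PCR duplication tagged with random N8 UMIs, and paired
250-bp reads (Read 2 starts with the UMI).  Every simulated molecule is
recorded in a truth table so recovery can be checked exactly.

The generator makes no indels and no adapter read-through (amplicons are
longer than the read length); qualities are constant Q37 except at injected
substitution errors, which are written at Q20.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .panel import AmpliconRegion

_ACGT = np.frombuffer(b"ACGT", np.uint8)
_CODE = np.full(256, 255, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b

Q_GOOD = chr(37 + 33)   # Phred 37
Q_ERR = chr(20 + 33)    # Phred 20 at injected-error positions


@dataclass
class CellState:
    """One cell population: mixture weight + per-CpG methylation probabilities."""

    weight: float
    meth_probs: np.ndarray

    def __post_init__(self) -> None:
        self.meth_probs = np.asarray(self.meth_probs, float)
        if not 0 <= self.weight <= 1:
            raise ValueError("state weight outside [0, 1]")
        if np.any((self.meth_probs < 0) | (self.meth_probs > 1)):
            raise ValueError("methylation probabilities outside [0, 1]")


@dataclass
class EpialleleProfile:
    """Per-allele cell-state mixtures plus the error model of one library."""

    maternal_states: List[CellState]
    paternal_states: List[CellState]
    conversion_rate: float = 0.995          # P(unmethylated C read as T)
    inappropriate_conversion: float = 0.005  # P(methylated C read as T)
    seq_error_rate: float = 0.001           # per-base substitution probability
    duplication_mean: float = 3.0           # mean PCR copies per molecule

    def __post_init__(self) -> None:
        for states in (self.maternal_states, self.paternal_states):
            w = sum(s.weight for s in states)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"state weights sum to {w}, expected 1")
        for p in (self.conversion_rate, self.inappropriate_conversion,
                  self.seq_error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probability outside [0, 1]")

    def states(self, allele: str) -> List[CellState]:
        return self.maternal_states if allele == "maternal" else self.paternal_states


def _flat(p: float, n_cpg: int) -> np.ndarray:
    return np.full(n_cpg, float(p))


def flat_profile(region: AmpliconRegion, p_maternal: float, p_paternal: float,
                 **rates) -> EpialleleProfile:
    """Single cell state per allele with a flat per-CpG methylation probability."""
    n = region.n_cpgs
    return EpialleleProfile(
        maternal_states=[CellState(1.0, _flat(p_maternal, n))],
        paternal_states=[CellState(1.0, _flat(p_paternal, n))],
        **rates,
    )


def canonical_profile(region: AmpliconRegion, high: float = 0.97,
                      low: float = 0.03, **rates) -> EpialleleProfile:
    """The region's normal germline configuration.

    Maternal-methylated ICRs carry ~full methylation on the maternal allele
    and ~none on the paternal (and vice versa); unmethylated controls are low
    on both alleles, methylated controls high on both.
    """
    cls = region.region_class
    if cls == "maternal_methylated_ICR":
        pm, pp = high, low
    elif cls == "paternal_methylated_ICR":
        pm, pp = low, high
    elif cls == "control_unmethylated":
        pm = pp = low
    elif cls == "control_methylated":
        pm = pp = high
    else:  # pragma: no cover - validated upstream
        raise ValueError(cls)
    return flat_profile(region, pm, pp, **rates)


def noise_free_profile(region: AmpliconRegion) -> EpialleleProfile:
    """Canonical configuration with all error processes switched off."""
    prof = canonical_profile(region, high=1.0, low=0.0)
    return replace(prof, conversion_rate=1.0, inappropriate_conversion=0.0,
                   seq_error_rate=0.0)


def mixture_profile(region: AmpliconRegion, intact_weight: float,
                    allele: str = "maternal", high: float = 0.97,
                    low: float = 0.03, **rates) -> EpialleleProfile:
    """Canonical profile with one allele split intact:erased at the given weight."""
    prof = canonical_profile(region, high=high, low=low, **rates)
    n = region.n_cpgs
    mix = [CellState(intact_weight, _flat(high, n)),
           CellState(1.0 - intact_weight, _flat(low, n))]
    if allele == "maternal":
        prof.maternal_states = mix
    else:
        prof.paternal_states = mix
    return prof


# ---------------------------------------------------------------------------
# molecule simulation
# ---------------------------------------------------------------------------

@dataclass
class MoleculeSet:
    """Vectorised batch of simulated molecules from one region."""

    region: AmpliconRegion
    seqs: np.ndarray          # (n, L) uint8, unconverted design-strand bases
    alleles: np.ndarray       # (n,) 0 = maternal, 1 = paternal
    state_idx: np.ndarray     # (n,) index into the allele's state list
    cpg_states: np.ndarray    # (n, n_cpg) int8, 1 methylated / 0 unmethylated

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def allele_labels(self) -> np.ndarray:
        return np.where(self.alleles == 0, "maternal", "paternal")

    def to_records(self) -> List[Tuple[str, "TruthRecord"]]:
        out = []
        labels = self.allele_labels()
        for i in range(len(self)):
            rec = TruthRecord(
                molecule_id=i,
                region=self.region.name,
                allele=str(labels[i]),
                state_index=int(self.state_idx[i]),
                cpg_states="".join(map(str, self.cpg_states[i])),
                umi="",
            )
            out.append((self.seqs[i].tobytes().decode(), rec))
        return out


@dataclass
class TruthRecord:
    """One simulated molecule as recorded in the truth table."""

    molecule_id: int
    region: str
    allele: str
    state_index: int
    cpg_states: str
    umi: str


def simulate_molecules(region: AmpliconRegion, profile: EpialleleProfile,
                       n_molecules: int, seed: int) -> MoleculeSet:
    """Draw unconverted molecules: allele 50:50, state by weight, CpGs iid.

    SNP positions carry the parental base of the drawn allele.  Deterministic
    for a fixed seed.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    for states in (profile.maternal_states, profile.paternal_states):
        for s in states:
            if len(s.meth_probs) != region.n_cpgs:
                raise ValueError(
                    f"profile has {len(s.meth_probs)} CpG probabilities but "
                    f"region {region.name} has {region.n_cpgs} CpGs"
                )
    if region.sequence is None:
        raise ValueError(f"region {region.name} has no reference sequence")

    rng = np.random.default_rng(seed)
    ref = np.frombuffer(region.sequence.encode(), np.uint8)
    seqs = np.tile(ref, (n_molecules, 1))
    alleles = rng.integers(0, 2, size=n_molecules)

    # paternal molecules get the CAST base at every SNP (usable or not)
    pat = alleles == 1
    for s in region.snps:
        seqs[pat, s.offset] = ord(s.paternal_base)

    state_idx = np.zeros(n_molecules, dtype=int)
    cpg_states = np.zeros((n_molecules, region.n_cpgs), dtype=np.int8)
    for a, states in ((0, profile.maternal_states), (1, profile.paternal_states)):
        mask = alleles == a
        n_a = int(mask.sum())
        if n_a == 0:
            continue
        weights = np.array([s.weight for s in states])
        idx = rng.choice(len(states), size=n_a, p=weights)
        state_idx[mask] = idx
        probs = np.stack([s.meth_probs for s in states])[idx]  # (n_a, n_cpg)
        cpg_states[mask] = (rng.random(probs.shape) < probs).astype(np.int8)
    return MoleculeSet(region, seqs, alleles, state_idx, cpg_states)


def bisulfite_convert_set(molset: MoleculeSet, profile: EpialleleProfile,
                          rng: np.random.Generator) -> np.ndarray:
    """Apply stochastic bisulfite conversion to a molecule batch.

    Non-CpG cytosines convert to T with probability ``conversion_rate``;
    CpG cytosines convert iff (unmethylated and converted) or (methylated
    and inappropriately converted).  G/A/T are untouched on the design strand.
    """
    C, T = ord("C"), ord("T")
    seqs = molset.seqs.copy()
    cpgs = np.asarray(molset.region.cpg_positions, int)

    is_c = seqs == C
    if cpgs.size:
        is_c[:, cpgs] = False  # CpG columns handled by methylation state
    conv = is_c & (rng.random(seqs.shape) < profile.conversion_rate)
    seqs[conv] = T

    if cpgs.size:
        u = rng.random(molset.cpg_states.shape)
        meth = molset.cpg_states == 1
        to_t = np.where(meth, u < profile.inappropriate_conversion,
                        u < profile.conversion_rate)
        # only reference Cs convert (a paternal SNP inside a CpG would differ,
        # but the packaged panel keeps SNPs clear of CpGs)
        cols = seqs[:, cpgs]
        cols[to_t & (cols == C)] = T
        seqs[:, cpgs] = cols
    return seqs


def bisulfite_convert(sequence: str, cpg_states: Sequence[int],
                      region: AmpliconRegion, profile: EpialleleProfile,
                      seed: int = 0) -> str:
    """Single-molecule convenience wrapper around :func:`bisulfite_convert_set`."""
    molset = MoleculeSet(
        region=region,
        seqs=np.frombuffer(sequence.encode(), np.uint8).copy()[None, :],
        alleles=np.zeros(1, int),
        state_idx=np.zeros(1, int),
        cpg_states=np.asarray(cpg_states, np.int8)[None, :],
    )
    rng = np.random.default_rng(seed)
    return bisulfite_convert_set(molset, profile, rng)[0].tobytes().decode()


# ---------------------------------------------------------------------------
# PCR amplification + FASTQ output
# ---------------------------------------------------------------------------

def _random_umis(rng: np.random.Generator, n: int, length: int,
                 unique: bool) -> np.ndarray:
    """(n, length) uint8 array of UMI bases."""
    if unique:
        space = 4 ** length
        codes = rng.choice(space, size=n, replace=False)
        digits = np.empty((n, length), dtype=np.int64)
        for j in range(length):
            digits[:, length - 1 - j] = (codes // 4 ** j) % 4
        return _ACGT[digits]
    return _ACGT[rng.integers(0, 4, size=(n, length))]


def _apply_errors(seqs: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitute random bases at the given rate; returns boolean error mask."""
    if rate <= 0:
        return np.zeros(seqs.shape, bool)
    mask = rng.random(seqs.shape) < rate
    if mask.any():
        codes = _CODE[seqs[mask]]
        shift = rng.integers(1, 4, size=codes.shape)
        seqs[mask] = _ACGT[(codes + shift) % 4]
    return mask


@dataclass
class ReadBatch:
    """In-memory paired reads (sequencing orientation) plus their truth table."""

    ids: List[str]
    r1_seq: List[str]
    r1_qual: List[str]
    r2_seq: List[str]
    r2_qual: List[str]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.ids)


def amplify_molecules(
    molsets: Sequence[MoleculeSet],
    profile: EpialleleProfile,
    seed: int,
    read_length: int = 250,
    umi_length: int = 8,
    unique_umis: bool = False,
) -> ReadBatch:
    """Bisulfite-convert, tag with UMIs, PCR-duplicate and 'sequence' molecules.

    Each molecule is converted once (conversion precedes PCR), assigned a
    random N8 UMI, and duplicated ``1 + Poisson(duplication_mean - 1)`` times
    so every molecule is sequenced at least once.  Read 1 is the first
    ``read_length`` bases of the converted molecule; Read 2 is the UMI
    followed by the reverse complement of the molecule 3' end.  Substitution
    errors are applied per read at ``seq_error_rate`` (UMI bases included).
    """
    rng = np.random.default_rng(seed)
    ids: List[str] = []
    r1s: List[str] = []
    q1s: List[str] = []
    r2s: List[str] = []
    q2s: List[str] = []
    truth_rows = []
    mol_counter = 0

    for molset in molsets:
        n = len(molset)
        conv = bisulfite_convert_set(molset, profile, rng)
        umis = _random_umis(rng, n, umi_length, unique_umis)
        dups = 1 + rng.poisson(max(profile.duplication_mean - 1.0, 0.0), size=n)
        labels = molset.allele_labels()

        idx = np.repeat(np.arange(n), dups)
        r1 = conv[idx, :read_length].copy()
        rc = _COMP_LUT[conv][:, ::-1]
        body = rc[idx, : max(read_length - umi_length, 0)]
        r2 = np.concatenate([umis[idx], body], axis=1).copy()

        e1 = _apply_errors(r1, profile.seq_error_rate, rng)
        e2 = _apply_errors(r2, profile.seq_error_rate, rng)

        copy_no = np.concatenate([np.arange(d) for d in dups])
        for k in range(len(idx)):
            i = idx[k]
            mid = mol_counter + i
            ids.append(f"M{mid:07d}:{copy_no[k]}")
            r1s.append(r1[k].tobytes().decode())
            r2s.append(r2[k].tobytes().decode())
            q1s.append(_qual_string(e1[k]))
            q2s.append(_qual_string(e2[k]))
        for i in range(n):
            truth_rows.append(
                (
                    mol_counter + i,
                    molset.region.name,
                    str(labels[i]),
                    int(molset.state_idx[i]),
                    "".join(map(str, molset.cpg_states[i])),
                    umis[i].tobytes().decode(),
                    int(dups[i]),
                )
            )
        mol_counter += n

    truth = pd.DataFrame(
        truth_rows,
        columns=["molecule_id", "region", "allele", "state_index",
                 "cpg_states", "umi", "n_copies"],
    )
    return ReadBatch(ids, r1s, q1s, r2s, q2s, truth)


def _qual_string(err_mask: np.ndarray) -> str:
    if not err_mask.any():
        return Q_GOOD * len(err_mask)
    return "".join(Q_ERR if e else Q_GOOD for e in err_mask)


def write_fastq_pair(batch: ReadBatch, out_prefix: str | Path,
                     gzip_output: bool = True) -> Dict[str, Path]:
    """Write the batch as ``<prefix>_R1/_R2.fastq[.gz]`` plus ``<prefix>_truth.tsv``."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_output else ".fastq"
    paths = {
        "r1": prefix.with_name(prefix.name + "_R1" + ext),
        "r2": prefix.with_name(prefix.name + "_R2" + ext),
        "truth": prefix.with_name(prefix.name + "_truth.tsv"),
    }
    for key, seqs, quals, mate in (("r1", batch.r1_seq, batch.r1_qual, "1"),
                                   ("r2", batch.r2_seq, batch.r2_qual, "2")):
        chunks = [
            f"@{rid}/{mate}\n{s}\n+\n{q}\n"
            for rid, s, q in zip(batch.ids, seqs, quals)
        ]
        data = "".join(chunks).encode()
        if gzip_output:
            with gzip.open(paths[key], "wb", compresslevel=1) as fh:
                fh.write(data)
        else:
            paths[key].write_bytes(data)
    batch.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def amplify_and_write_fastq(
    molsets: Sequence[MoleculeSet],
    profile: EpialleleProfile,
    out_prefix: str | Path,
    seed: int,
    read_length: int = 250,
    umi_length: int = 8,
    unique_umis: bool = False,
    gzip_output: bool = True,
) -> Dict[str, Path]:
    """One-call simulation output: paired FASTQ(.gz) files + truth TSV."""
    if not molsets or all(len(m) == 0 for m in molsets):
        raise ValueError("no molecules to amplify")
    batch = amplify_molecules(
        molsets, profile, seed,
        read_length=read_length, umi_length=umi_length, unique_umis=unique_umis,
    )
    return write_fastq_pair(batch, out_prefix, gzip_output=gzip_output)


def simulate_dataset(
    regions: Sequence[AmpliconRegion],
    profiles: Dict[str, EpialleleProfile],
    n_per_region: int,
    seed: int,
    out_prefix: str | Path | None = None,
    read_length: int = 250,
    umi_length: int = 8,
    unique_umis: bool = False,
    gzip_output: bool = True,
):
    """Simulate a whole panel: one profile per region name.

    Returns the in-memory :class:`ReadBatch`; when ``out_prefix`` is given the
    FASTQ pair and truth table are also written to disk.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(regions) + 1)
    molsets = []
    for region, child in zip(regions, children[:-1]):
        prof = profiles[region.name]
        mol_seed = int(child.generate_state(1)[0] % (2**31))
        molsets.append(simulate_molecules(region, prof, n_per_region, mol_seed))
    amp_seed = int(children[-1].generate_state(1)[0] % (2**31))
    # one shared error model: take the first region's profile rates
    profile = profiles[regions[0].name]
    batch = amplify_molecules(
        molsets, profile, amp_seed,
        read_length=read_length, umi_length=umi_length, unique_umis=unique_umis,
    )
    if out_prefix is not None:
        write_fastq_pair(batch, out_prefix, gzip_output=gzip_output)
    return batch


# ---------------------------------------------------------------------------
# allele-specific expression tables
# ---------------------------------------------------------------------------

_ASE_CHROMS = ["chr1", "chr2", "chr6", "chr7", "chr9", "chr11", "chr12",
               "chr17"]


def simulate_ase_table(
    n_genes: int,
    config: AnalysisConfig,
    seed: int,
    upd_chrom: Optional[str] = None,
    test_sample: str = "iPSC",
    reference_sample: str = "MEF",
    n_replicates: int = 3,
    mean_depth: float = 30.0,
    concentration: float = 60.0,
    imprinted_fraction: float = 0.25,
    out_prefix: str | Path | None = None,
) -> Dict[str, pd.DataFrame]:
    """Per-gene allele-specific count and expression tables with known truth.

    A minority of genes (``imprinted_fraction``) are imprinted and
    monoallelic in the reference tissue per their expected parent (~70% of
    them paternally expressed, mirroring imprinted-gene catalogues); the rest
    are ordinary biallelic background genes (``expected_parent='none'``,
    true maternal fraction 0.5) — the population a chromosome-wide UPD scan
    relies on.  Test-sample replicates keep the same allelic ratio unless the
    gene lies on ``upd_chrom``, in which case the maternal fraction is forced
    to 1.0 (maternal uniparental disomy: the paternal copy is absent, so the
    paternal count is exactly zero).  Counts are beta-binomial around the true
    ratio; expression is Log2 RPKM with a low-expression minority so the
    shortlisting filters have something to reject.  Byte-identical output for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:03d}" for i in range(1, n_genes + 1)]
    chroms = [_ASE_CHROMS[i % len(_ASE_CHROMS)] for i in range(n_genes)]
    imprinted = rng.random(n_genes) < imprinted_fraction
    parent = np.where(rng.random(n_genes) < 0.7, "paternal", "maternal")
    expected = np.where(imprinted, parent, "none")
    lowexpr = rng.random(n_genes) < 0.15
    base_rpkm = np.where(lowexpr, rng.normal(0.3, 0.3, n_genes),
                         rng.normal(3.0, 1.0, n_genes))

    mono = np.select(
        [expected == "maternal", expected == "paternal"], [0.97, 0.03], 0.5)
    truth_rows, count_rows, expr_rows = [], [], []
    for sample in (reference_sample, test_sample):
        for g in range(n_genes):
            frac = mono[g]
            if sample == test_sample and upd_chrom is not None \
                    and chroms[g] == upd_chrom:
                frac = 1.0
            truth_rows.append((genes[g], chroms[g], expected[g], sample, frac))
            for rep in range(1, n_replicates + 1):
                depth = mean_depth * (0.3 if lowexpr[g] else 1.0)
                total = int(rng.poisson(depth))
                if frac <= 0.0 or frac >= 1.0:
                    p = frac
                else:
                    p = rng.beta(frac * concentration, (1 - frac) * concentration)
                mat = int(rng.binomial(total, p)) if total > 0 else 0
                count_rows.append(
                    (genes[g], chroms[g], expected[g], sample, rep,
                     mat, total - mat)
                )
                rpkm = base_rpkm[g] + rng.normal(0, 0.2)
                expr_rows.append((genes[g], sample, rep, round(float(rpkm), 4)))

    counts = pd.DataFrame(
        count_rows,
        columns=["gene", "chrom", "expected_parent", "sample", "replicate",
                 "maternal_count", "paternal_count"],
    )
    expr = pd.DataFrame(expr_rows, columns=["gene", "sample", "replicate",
                                            "log2_rpkm"])
    truth = pd.DataFrame(truth_rows, columns=["gene", "chrom", "expected_parent",
                                              "sample", "true_maternal_fraction"])
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        counts.to_csv(prefix.with_name(prefix.name + "_ase_counts.tsv"),
                      sep="\t", index=False)
        expr.to_csv(prefix.with_name(prefix.name + "_ase_expr.tsv"),
                    sep="\t", index=False)
        truth.to_csv(prefix.with_name(prefix.name + "_ase_truth.tsv"),
                     sep="\t", index=False)
    return {"counts": counts, "expr": expr, "truth": truth}
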