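"""Synthetic-data generator: truth structure, conversion chemistry, FASTQ."""

import gzip

import numpy as np
import pytest
from scipy import stats

from implicon.simulate import (amplify_and_write_fastq, amplify_molecules,
                               bisulfite_convert, canonical_profile,
                               flat_profile, mixture_profile,
                               noise_free_profile, simulate_ase_table,
                               simulate_molecules)


class TestSimulateMolecules:
    def test_canonical_imprint_means(self, peg3):
        prof = canonical_profile(peg3, high=1.0, low=0.0)
        mols = simulate_molecules(peg3, prof, 1000, seed=3)
        mat = mols.cpg_states[mols.alleles == 0]
        pat = mols.cpg_states[mols.alleles == 1]
        assert mat.mean() == 1.0 and pat.mean() == 0.0

    def test_mixture_weight_recovered(self, gnas):
        # 60:40 intact vs erased maternal states; binomial CI at n=1000
        prof = mixture_profile(gnas, 0.6, high=1.0, low=0.0)
        mols = simulate_molecules(gnas, prof, 2000, seed=11)
        mat = mols.cpg_states[mols.alleles == 0]
        full = (mat.mean(axis=1) == 1.0).mean()
        n_mat = mat.shape[0]
        lo, hi = stats.binom.interval(0.999, n_mat, 0.6)
        assert lo / n_mat <= full <= hi / n_mat

    def test_snp_bases_follow_allele(self, peg3):
        prof = canonical_profile(peg3)
        mols = simulate_molecules(peg3, prof, 50, seed=0)
        for snp in peg3.snps:
            col = mols.seqs[:, snp.offset]
            expected = np.where(mols.alleles == 0, ord(snp.maternal_base),
                                ord(snp.paternal_base))
            assert (col == expected).all()

    def test_rejects_bad_inputs(self, peg3, gnas):
        prof = canonical_profile(peg3)
        with pytest.raises(ValueError):
            simulate_molecules(peg3, prof, 0, seed=0)
        with pytest.raises(ValueError, match="CpG"):
            simulate_molecules(gnas, prof, 10, seed=0)  # profile/region mismatch

    def test_deterministic(self, peg3):
        prof = canonical_profile(peg3)
        a = simulate_molecules(peg3, prof, 100, seed=5)
        b = simulate_molecules(peg3, prof, 100, seed=5)
        assert (a.seqs == b.seqs).all() and (a.cpg_states == b.cpg_states).all()


class TestBisulfiteConversion:
    def test_full_conversion_removes_non_cpg_cytosines(self, peg3):
        prof = flat_profile(peg3, 1.0, 1.0, conversion_rate=1.0,
                            inappropriate_conversion=0.0)
        states = [1] * peg3.n_cpgs
        conv = bisulfite_convert(peg3.sequence, states, peg3, prof, seed=1)
        non_cpg_c = [i for i, b in enumerate(conv)
                     if b == "C" and i not in peg3.cpg_positions]
        assert non_cpg_c == []

    def test_methylated_cpgs_retained(self, peg3):
        prof = flat_profile(peg3, 1.0, 1.0, conversion_rate=1.0,
                            inappropriate_conversion=0.0)
        conv = bisulfite_convert(peg3.sequence, [1] * peg3.n_cpgs, peg3, prof,
                                 seed=2)
        assert all(conv[o] == "C" for o in peg3.cpg_positions)

    def test_unmethylated_cpgs_converted(self, peg3):
        prof = flat_profile(peg3, 0.0, 0.0, conversion_rate=1.0)
        conv = bisulfite_convert(peg3.sequence, [0] * peg3.n_cpgs, peg3, prof,
                                 seed=2)
        assert all(conv[o] == "T" for o in peg3.cpg_positions)

    def test_incomplete_conversion_rate(self, peg3):
        # binomial expectation: residual Cs ~ Binomial(n_C, 0.01) per molecule
        prof = flat_profile(peg3, 0.0, 0.0, conversion_rate=0.99)
        n_c = sum(1 for i, b in enumerate(peg3.sequence)
                  if b == "C" and i not in peg3.cpg_positions)
        residuals = []
        for seed in range(50):
            conv = bisulfite_convert(peg3.sequence, [0] * peg3.n_cpgs, peg3,
                                     prof, seed=seed)
            residuals.append(sum(
                1 for i, b in enumerate(conv)
                if b == "C" and i not in peg3.cpg_positions))
        lo, hi = stats.binom.interval(0.999, n_c * 50, 0.01)
        assert lo <= sum(residuals) <= hi


class TestAmplification:
    def test_duplication_one_is_exact(self, peg3):
        prof = noise_free_profile(peg3)
        prof.duplication_mean = 1.0
        mols = simulate_molecules(peg3, prof, 100, seed=4)
        batch = amplify_molecules([mols], prof, seed=4)
        assert len(batch) == 100

    def test_mean_duplication(self, peg3):
        prof = canonical_profile(peg3)  # duplication_mean 3
        mols = simulate_molecules(peg3, prof, 300, seed=6)
        batch = amplify_molecules([mols], prof, seed=6)
        assert len(batch) >= 300
        # 1 + Poisson(2): mean 3, sd sqrt(2/300) per molecule
        assert abs(len(batch) / 300 - 3.0) < 0.35

    def test_read2_starts_with_truth_umi(self, peg3):
        prof = noise_free_profile(peg3)
        mols = simulate_molecules(peg3, prof, 50, seed=7)
        batch = amplify_molecules([mols], prof, seed=7)
        umi_by_mol = dict(zip(batch.truth.molecule_id, batch.truth.umi))
        for rid, r2 in zip(batch.ids, batch.r2_seq):
            mol = int(rid.split(":")[0][1:])
            assert r2.startswith(umi_by_mol[mol])

    def test_truth_conservation(self, peg3, gnas):
        prof = noise_free_profile(peg3)
        mols = [simulate_molecules(peg3, prof, 40, seed=1),
                simulate_molecules(gnas, noise_free_profile(gnas), 30, seed=2)]
        batch = amplify_molecules(mols, prof, seed=3)
        assert len(batch.truth) == 70
        assert batch.truth.n_copies.sum() == len(batch)

    def test_fastq_round_trip_and_determinism(self, peg3, tmp_path):
        prof = canonical_profile(peg3)
        mols = simulate_molecules(peg3, prof, 30, seed=9)
        p1 = amplify_and_write_fastq([mols], prof, tmp_path / "a", seed=9)
        p2 = amplify_and_write_fastq([mols], prof, tmp_path / "b", seed=9)
        assert gzip.open(p1["r1"]).read() == gzip.open(p2["r1"]).read()
        assert gzip.open(p1["r2"]).read() == gzip.open(p2["r2"]).read()
        import pandas as pd
        n_reads = gzip.open(p1["r1"], "rt").read().count("\n") // 4
        assert n_reads == int(pd.read_csv(p1["truth"], sep="\t").n_copies.sum())

    def test_empty_input_rejected(self, peg3):
        prof = canonical_profile(peg3)
        with pytest.raises(ValueError):
            amplify_and_write_fastq([], prof, "x", seed=0)


class TestAseTable:
    def test_upd_chromosome_has_zero_paternal_counts(self, config):
        t = simulate_ase_table(40, config, seed=2, upd_chrom="chr6")
        ipsc = t["counts"].query("sample == 'iPSC' and chrom == 'chr6'")
        assert (ipsc.paternal_count == 0).all()
        assert len(ipsc) > 0

    def test_balanced_truth_recovers_half(self, config):
        t = simulate_ase_table(200, config, seed=3)
        bg = t["counts"].query("sample == 'iPSC' and expected_parent == 'none'")
        frac = bg.maternal_count.sum() / (bg.maternal_count.sum()
                                          + bg.paternal_count.sum())
        assert abs(frac - 0.5) < 0.03

    def test_byte_identical_for_fixed_seed(self, config, tmp_path):
        simulate_ase_table(30, config, seed=5, out_prefix=tmp_path / "x")
        a = (tmp_path / "x_ase_counts.tsv").read_bytes()
        simulate_ase_table(30, config, seed=5, out_prefix=tmp_path / "y")
        b = (tmp_path / "y_ase_counts.tsv").read_bytes()
        assert a == b
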