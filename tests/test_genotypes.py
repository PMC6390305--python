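import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from triadscan.genotypes import (
    MISSING,
    DepthMatrix,
    call_genotypes,
    filter_dataset,
    hwe_exact_test,
    read_genotypes,
    write_vcf,
)

from conftest import from_counts, make_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def write_popmap(tmp_path, samples, pops):
    p = tmp_path / "popmap.tsv"
    p.write_text("".join(f"{s}\t{q}\n" for s, q in zip(samples, pops)))
    return p


class TestReadGenotypes:
    def test_biallelic_filter_drops_triallelic(self, tmp_path):
        vcf = tmp_path / "in.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            + "chr1\t20\t.\tG\tT,C\t.\tPASS\t.\tGT\t0/0\t0/1\t2/2\n"
            + "chr1\t30\t.\tG\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\n"
        )
        pm = write_popmap(tmp_path, ["s1", "s2", "s3"], ["X", "X", "Y"])
        g = read_genotypes(vcf, pm)
        assert g.genotypes.shape == (3, 2)

    def test_empty_vcf_raises(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(VCF_HEADER)
        pm = write_popmap(tmp_path, ["s1", "s2", "s3"], ["X", "X", "Y"])
        with pytest.raises(ValueError, match="no loci"):
            read_genotypes(vcf, pm)

    def test_unknown_sample_raises(self, tmp_path):
        vcf = tmp_path / "in.vcf"
        vcf.write_text(VCF_HEADER + "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        pm = write_popmap(tmp_path, ["s1", "s2"], ["X", "X"])
        with pytest.raises(ValueError, match="absent"):
            read_genotypes(vcf, pm)

    def test_minor_allele_polarization(self, tmp_path):
        # alt allele is the major allele at this site -> dosages flipped
        vcf = tmp_path / "in.vcf"
        vcf.write_text(VCF_HEADER + "chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n")
        pm = write_popmap(tmp_path, ["s1", "s2", "s3"], ["X", "X", "Y"])
        g = read_genotypes(vcf, pm)
        assert list(g.genotypes[:, 0]) == [0, 0, 1]
        assert not g.loci["minor_is_alt"].iloc[0]

    def test_roundtrip_through_vcf(self, small_sim, tmp_path):
        g = small_sim.genotypes
        path = tmp_path / "rt.vcf"
        write_vcf(g, path, depths=small_sim.depths)
        pm = tmp_path / "pm.tsv"
        pm.write_text("".join(
            f"{r.id}\t{r.population}\n" for r in g.individuals.itertuples()))
        g2 = read_genotypes(path, pm)
        assert np.array_equal(g.genotypes, g2.genotypes)


class TestCallGenotypes:
    def _call_one(self, ref, alt, eps=0.01, min_reads=5):
        counts = np.array([[[ref, alt]]], dtype=np.int32)
        g = call_genotypes(DepthMatrix(counts), error_rate=eps, min_reads=min_reads)
        # undo polarization: reconstruct alt dosage
        dos = int(g.genotypes[0, 0])
        return dos if g.loci["minor_is_alt"].iloc[0] else (2 - dos if dos != MISSING else dos)

    def test_hom_ref_dominates(self):
        assert self._call_one(10, 0) == 0

    def test_below_min_reads_is_missing(self):
        counts = np.array([[[3, 1]]], dtype=np.int32)
        g = call_genotypes(DepthMatrix(counts), error_rate=0.01, min_reads=5)
        assert g.genotypes[0, 0] == MISSING

    def test_het_call_matches_likelihood_oracle(self):
        ref, alt, eps = 5, 5, 0.01
        n = ref + alt
        lik = {
            0: binom.pmf(alt, n, eps),
            1: binom.pmf(alt, n, 0.5),
            2: binom.pmf(alt, n, 1 - eps),
        }
        best = max(lik, key=lik.get)
        assert best == 1
        assert self._call_one(ref, alt) == best

    @pytest.mark.parametrize("ref,alt", [(20, 1), (1, 20), (8, 3), (3, 8), (6, 6)])
    def test_calls_match_enumeration(self, ref, alt):
        eps, n = 0.01, ref + alt
        lik = [binom.pmf(alt, n, q) for q in (eps, 0.5, 1 - eps)]
        assert self._call_one(ref, alt) == int(np.argmax(lik))

    def test_cap_enforced(self):
        counts = np.array([[[200, 0]]], dtype=np.int32)
        with pytest.raises(ValueError, match="cap"):
            DepthMatrix(counts)


class TestHweExactTest:
    def enum_p(self, nAA, nAa, naa):
        """Full enumeration over heterozygote counts (independent oracle)."""
        from math import comb

        n = nAA + nAa + naa
        nA = 2 * nAA + nAa
        rare = min(nA, 2 * n - nA)
        probs = {}
        for h in range(rare % 2, rare + 1, 2):
            homr = (rare - h) // 2
            homc = (2 * n - rare - h) // 2
            probs[h] = (
                2**h
                * comb(n, homr) * comb(n - homr, h)
                / comb(2 * n, rare)
            )
        # normalize (multinomial coefficient form)
        tot = sum(probs.values())
        probs = {h: v / tot for h, v in probs.items()}
        obs = probs[nAa]
        return sum(v for v in probs.values() if v <= obs * (1 + 1e-12))

    @pytest.mark.parametrize("counts", [(25, 50, 25), (0, 10, 0), (5, 2, 9),
                                        (12, 4, 1), (3, 3, 3)])
    def test_matches_enumeration_oracle(self, counts):
        p, _ = hwe_exact_test(*counts)
        assert p == pytest.approx(self.enum_p(*counts), rel=1e-9)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(7, 0, 0) == (1.0, 0)

    def test_all_het_direction_and_significance(self):
        p, direction = hwe_exact_test(0, 10, 0)
        assert direction == 1 and p < 0.01

    def test_uniform_conservative_under_hwe(self, rng):
        """Fraction of p < 0.05 under simulated HWE genotypes stays <= nominal."""
        n, reps, freq = 100, 2000, 0.3
        hits = 0
        for _ in range(reps):
            dos = rng.binomial(2, freq, n)
            p, _ = hwe_exact_test(int((dos == 0).sum()), int((dos == 1).sum()),
                                  int((dos == 2).sum()))
            hits += p < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * se


class TestFilterDataset:
    def test_individual_missingness_stage(self):
        dos = np.zeros((4, 3), dtype=np.int8)
        dos[3, :2] = MISSING  # 2/3 missing
        dos[0, 0] = 1  # keep loci polymorphic enough
        g = make_matrix(dos, ["P"] * 4)
        filtered, rep = filter_dataset(g, min_maf=0.0, min_locus_callrate=0.5)
        assert rep.individuals_removed["individual_missingness"] == 1
        assert filtered.n_individuals == 3

    def test_perfect_hwe_locus_retained(self):
        g = from_counts(25, 50, 25)
        filtered, rep = filter_dataset(g, min_maf=0.0)
        assert rep.loci_removed["hwe_excess_heterozygosity"] == 0

    def test_all_het_locus_dropped(self):
        g = from_counts(0, 50, 0)
        with pytest.raises(ValueError, match="hwe"):
            # the only locus is dropped -> empty result error names the stage
            filter_dataset(g, min_maf=0.0)

    def test_het_deficit_locus_retained(self):
        g = from_counts(30, 2, 28)  # massive deficit, still kept
        filtered, rep = filter_dataset(g, min_maf=0.0)
        assert filtered.n_loci == 1

    def test_maf_strict_inequality(self):
        # MAF exactly at threshold is retained ("less than" removes)
        dos = np.zeros((50, 1), dtype=np.int8)
        dos[0, 0] = 1  # freq 1/100 = 0.01
        g = make_matrix(dos, ["P"] * 50)
        filtered, _ = filter_dataset(g, min_maf=0.01, hwe_alpha=0.0)
        assert filtered.n_loci == 1

    def test_idempotent(self, small_sim):
        g1, _ = filter_dataset(small_sim.genotypes)
        g2, rep2 = filter_dataset(g1)
        assert g2.genotypes.shape == g1.genotypes.shape
        assert sum(rep2.loci_removed.values()) == 0
        assert sum(rep2.individuals_removed.values()) == 0
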