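"""Genotype I/O, Nei-corrected locus statistics and the Hill partition."""

import numpy as np
import pandas as pd
import pytest

from reefdisparity.popgen import (
    MISSING,
    GenotypeMatrix,
    downsample_diversity,
    hill_partition,
    nei_locus_stats,
    read_genotypes_csv,
    read_genotypes_vcf,
    write_genotypes_csv,
    write_vcf,
)


def _gm(geno, pops):
    geno = np.asarray(geno, dtype=np.int8)
    return GenotypeMatrix(
        genotypes=geno,
        populations=np.asarray(pops, dtype=object),
        samples=[f"s{i}" for i in range(geno.shape[0])],
        locus_ids=[f"L{j}" for j in range(geno.shape[1])],
    )


def nei_oracle(geno, pops):
    """Brute-force per-locus recomputation of the corrected estimators,
    written independently with explicit loops."""
    geno = np.asarray(geno)
    out = []
    for j in range(geno.shape[1]):
        per_pop = []
        for p in dict.fromkeys(pops):
            g = [x for x, pp in zip(geno[:, j], pops) if pp == p and x != MISSING]
            if len(g) == 0:
                continue
            n = len(g)
            freq = sum(g) / (2 * n)
            het = sum(1 for x in g if x == 1) / n
            per_pop.append((n, freq, het))
        if len(per_pop) < 2:
            out.append(None)
            continue
        npop = len(per_pop)
        n_harm = npop / sum(1 / n for n, _, _ in per_pop)
        if n_harm <= 1:
            out.append(None)
            continue
        ho = sum(h for _, _, h in per_pop) / npop
        hs_tilde = sum(2 * f * (1 - f) for _, f, _ in per_pop) / npop
        hs = n_harm / (n_harm - 1) * (hs_tilde - ho / (2 * n_harm))
        pbar = sum(f for _, f, _ in per_pop) / npop
        ht_tilde = 2 * pbar * (1 - pbar)
        ht = ht_tilde + hs / (n_harm * npop) - ho / (2 * n_harm * npop)
        out.append((ho, hs, ht))
    return out


class TestVCF:
    def test_roundtrip_and_coding(self, tmp_path):
        gm = _gm([[0, 1], [1, 2], [2, MISSING], [0, 0]], ["p1", "p1", "p2", "p2"])
        path = tmp_path / "t.vcf"
        write_vcf(gm, path)
        back = read_genotypes_vcf(path, {s: p for s, p in zip(gm.samples, gm.populations)})
        np.testing.assert_array_equal(back.genotypes, gm.genotypes)
        assert back.samples == gm.samples
        assert list(back.populations) == list(gm.populations)

    def test_triallelic_and_nonsnp_skipped(self, tmp_path):
        text = "\n".join(
            [
                "##fileformat=VCFv4.2",
                "##contig=<ID=1>",
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb",
                "1\t1\tbi\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1",
                "1\t2\ttri\tA\tT,C\t.\tPASS\t.\tGT\t0/0\t0/2",
                "1\t3\tindel\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/1",
                "1\t4\tmiss\tA\tG\t.\tPASS\t.\tGT\t./.\t1/1",
            ]
        )
        path = tmp_path / "t.vcf"
        path.write_text(text + "\n")
        gm = read_genotypes_vcf(path, {"a": "p1", "b": "p2"})
        assert gm.locus_ids == ["bi", "miss"]
        np.testing.assert_array_equal(gm.genotypes[:, 0], [0, 1])
        np.testing.assert_array_equal(gm.genotypes[:, 1], [MISSING, 2])

    def test_sample_missing_from_popmap_errors(self, tmp_path):
        gm = _gm([[0], [1]], ["p1", "p2"])
        path = tmp_path / "t.vcf"
        write_vcf(gm, path)
        with pytest.raises(ValueError, match="s1"):
            read_genotypes_vcf(path, {"s0": "p1"})

    def test_csv_fallback_roundtrip(self, tmp_path):
        gm = _gm([[0, 1], [2, MISSING]], ["p1", "p2"])
        path = tmp_path / "g.csv"
        write_genotypes_csv(gm, path)
        back = read_genotypes_csv(path, {"s0": "p1", "s1": "p2"})
        np.testing.assert_array_equal(back.genotypes, gm.genotypes)


class TestNeiLocusStats:
    def test_worked_two_population_locus(self):
        # pop1 = {AA, Aa}, pop2 = {aa, aa}; alt allele = a
        gm = _gm([[0], [1], [2], [2]], ["p1", "p1", "p2", "p2"])
        stats = nei_locus_stats(gm)
        row = stats.iloc[0]
        assert row["ho"] == pytest.approx(0.25)
        assert row["hs"] == pytest.approx(0.25)
        assert row["ht"] == pytest.approx(0.5)

    def test_monomorphic_locus_all_zero(self):
        gm = _gm([[0], [0], [0], [0]], ["p1", "p1", "p2", "p2"])
        stats = nei_locus_stats(gm)
        assert stats.iloc[0][["ho", "hs", "ht"]].abs().max() == pytest.approx(0.0)

    def test_identical_population_compositions_symmetry(self):
        gm = _gm([[1], [0], [1], [0]], ["p1", "p1", "p2", "p2"])
        stats = nei_locus_stats(gm)
        assert stats.iloc[0]["ht_tilde"] == pytest.approx(stats.iloc[0]["hs_tilde"])

    def test_matches_bruteforce_oracle_on_random_tables(self, rng):
        for _ in range(50):
            n_pops = rng.integers(2, 4)
            n_per = rng.integers(2, 6)
            n_loci = rng.integers(1, 6)
            geno = rng.integers(0, 3, size=(n_pops * n_per, n_loci))
            # sprinkle missingness
            mask = rng.random(geno.shape) < 0.1
            geno = np.where(mask, MISSING, geno)
            pops = np.repeat([f"p{i}" for i in range(n_pops)], n_per)
            expected = nei_oracle(geno, pops)
            kept = [e for e in expected if e is not None]
            if not kept:
                with pytest.raises(ValueError):
                    nei_locus_stats(_gm(geno, pops))
                continue
            stats = nei_locus_stats(_gm(geno, pops))
            assert len(stats) == len(kept)
            for (ho, hs, ht), (_, row) in zip(kept, stats.iterrows()):
                assert row["ho"] == pytest.approx(ho, abs=1e-12)
                assert row["hs"] == pytest.approx(hs, abs=1e-12)
                assert row["ht"] == pytest.approx(ht, abs=1e-12)

    def test_locus_with_one_genotyped_population_dropped(self):
        geno = [[0, 0], [1, MISSING], [2, MISSING], [1, MISSING]]
        gm = _gm(geno, ["p1", "p1", "p2", "p2"])
        stats = nei_locus_stats(gm)
        assert list(stats.index) == ["L0"]


class TestHillPartition:
    def test_worked_locus_partition(self):
        gm = _gm([[0], [1], [2], [2]], ["p1", "p1", "p2", "p2"])
        hd = hill_partition(nei_locus_stats(gm))
        assert hd.h_st == pytest.approx(1 / 3)
        assert hd.j_s == pytest.approx(4 / 3)
        assert hd.j_st == pytest.approx(1.5)
        assert hd.j_t == pytest.approx(2.0)

    def test_multiplicative_identity_random_data(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            geno = r.integers(0, 3, size=(12, 40))
            pops = np.repeat(["a", "b", "c"], 4)
            hd = hill_partition(nei_locus_stats(_gm(geno, pops)))
            assert hd.j_t == pytest.approx(hd.j_s * hd.j_st, abs=1e-12)

    def test_monomorphic_data_all_ones(self):
        gm = _gm(np.zeros((8, 5)), np.repeat(["a", "b"], 4))
        hd = hill_partition(nei_locus_stats(gm))
        assert (hd.j_s, hd.j_st, hd.j_t) == (1.0, 1.0, 1.0)

    def test_fixed_alternative_alleles_large_n_limit(self):
        n = 1000
        geno = np.concatenate([np.zeros((n, 50)), np.full((n, 50), 2)])
        gm = _gm(geno, np.repeat(["a", "b"], n))
        hd = hill_partition(nei_locus_stats(gm))
        assert hd.j_st == pytest.approx(2.0, abs=0.01)


class TestDownsample:
    def test_noop_subsampling_equals_plain_partition(self, rng):
        geno = rng.integers(0, 3, size=(10, 30))
        gm = _gm(geno, np.repeat(["a", "b"], 5))
        plain = hill_partition(nei_locus_stats(gm))
        ds = downsample_diversity(gm, max_ind_per_pop=10, n_snps=30, n_reps=1, seed=0)
        assert ds.summary["J_T"] == pytest.approx(plain.j_t, abs=1e-12)
        assert ds.summary["J_ST"] == pytest.approx(plain.j_st, abs=1e-12)

    def test_deterministic_replicate_table(self, rng):
        geno = rng.integers(0, 3, size=(24, 50))
        gm = _gm(geno, np.repeat(["a", "b", "c"], 8))
        d1 = downsample_diversity(gm, max_ind_per_pop=4, n_snps=20, n_reps=9, seed=5)
        d2 = downsample_diversity(gm, max_ind_per_pop=4, n_snps=20, n_reps=9, seed=5)
        pd.testing.assert_frame_equal(d1.replicates, d2.replicates)

    def test_replicate_mean_stabilizes_with_reps(self, rng):
        """The spread of replicate J_T values shrinks the spread of the mean."""
        geno = rng.integers(0, 3, size=(60, 200))
        gm = _gm(geno, np.repeat(["a", "b", "c"], 20))
        sds = []
        for n_reps in (9, 99):
            means = [
                downsample_diversity(gm, max_ind_per_pop=5, n_snps=50,
                                     n_reps=n_reps, seed=s).summary["J_T"]
                for s in range(8)
            ]
            sds.append(np.std(means))
        assert sds[1] < sds[0]

    def test_too_many_snps_requested_errors(self, rng):
        gm = _gm(rng.integers(0, 3, size=(8, 10)), np.repeat(["a", "b"], 4))
        with pytest.raises(ValueError, match="10"):
            downsample_diversity(gm, n_snps=11)
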