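"""Genotype I/O and the ordered quality-control filters."""

import numpy as np
import pandas as pd
import pytest

from adaptscape.genotypes import (GenotypeMatrix, filter_individuals,
                                  filter_loci, global_missing_rate,
                                  read_snp_table, run_qc,
                                  thin_one_per_fragment, write_snp_table)


def test_snp_table_round_trip(tmp_path, sim_species):
    g = sim_species["genotypes"]
    path = tmp_path / "geno.csv"
    write_snp_table(g, path)
    g2 = read_snp_table(path, dialect="snp-csv")
    np.testing.assert_array_equal(g.counts, g2.counts)
    assert list(g.loci["locus_id"]) == list(g2.loci["locus_id"])
    assert list(g.loci["fragment_id"]) == list(g2.loci["fragment_id"])
    np.testing.assert_allclose(g.loci["reproducibility"],
                               g2.loci["reproducibility"])


def test_hand_written_csv(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text("locus_id,fragment_id,reproducibility,s1,s2,s3\n"
                    "L1,f1,0.99,0,1,2\n"
                    "L2,f1,1.0,-,2,0\n")
    g = read_snp_table(path)
    assert g.counts.shape == (3, 2)
    np.testing.assert_array_equal(g.counts[:, 0], [0, 1, 2])
    np.testing.assert_array_equal(g.counts[:, 1], [-1, 2, 0])


def test_malformed_row_names_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("locus_id,fragment_id,reproducibility,s1\n"
                    "L1,f1,1.0,0\n"
                    "L2,f1,1.0,0,9\n")
    with pytest.raises(ValueError, match="line 3"):
        read_snp_table(path)


def test_vcf_read_missing_and_multiallelic(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "1\t10\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t./.\n"
        "1\t20\tsnp2\tA\tG,T\t.\t.\t.\tGT\t0/0\t1/1\t0/2\n"
        "1\t30\tsnp3\tC\tT\t.\t.\t.\tGT\t1/1\t0/1\t0/0\n")
    g = read_snp_table(vcf, dialect="vcf")
    assert g.n_loci == 2  # multi-allelic record skipped
    np.testing.assert_array_equal(g.counts[:, 0], [0, 1, -1])
    np.testing.assert_array_equal(g.counts[:, 1], [2, 1, 0])


class TestFilterLoci:
    def _matrix(self, counts, repro=None, frags=None):
        counts = np.asarray(counts, dtype=np.int16)
        n, m = counts.shape
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                                "population": "A", "lon": 0.0, "lat": 0.0})
        loci = pd.DataFrame({
            "locus_id": [f"L{j}" for j in range(m)],
            "fragment_id": frags or [f"f{j}" for j in range(m)],
            "reproducibility": repro if repro is not None else [1.0] * m,
        })
        return GenotypeMatrix(counts=counts, samples=samples, loci=loci)

    def test_boundary_missing_fraction_is_strict(self):
        # locus 0: exactly 5% missing (1 of 20) -> removed
        counts = np.ones((20, 2), dtype=np.int16)
        counts[::2, :] = 0  # keep MAF at 0.5
        counts[0, 0] = -1
        g = self._matrix(counts)
        out, stages = filter_loci(g)
        assert stages["missing"] == 1
        assert list(out.loci["locus_id"]) == ["L1"]

    def test_four_locus_toy_keeps_one(self):
        # per-locus: missing 0/0.1/0/0; repro 1/1/0.97/1; MAF .3/.3/.3/.04
        rng = np.random.default_rng(0)
        n = 40
        counts = np.zeros((n, 4), dtype=np.int16)
        for j, maf in enumerate([0.3, 0.3, 0.3, 0.04]):
            counts[:, j] = rng.binomial(2, maf, size=n)
        # fix realized MAF exactly: set allele counts deterministically
        counts[:, 0] = ([1] * 24 + [0] * 16)          # p = 0.3
        counts[:, 1] = ([1] * 24 + [0] * 16)
        counts[:, 2] = ([1] * 24 + [0] * 16)
        counts[:, 3] = ([1] * 3 + [0] * 37)           # p = 0.0375
        counts[:4, 1] = -1                            # 10% missing
        g = self._matrix(counts.astype(np.int16), repro=[1, 1, 0.97, 1])
        out, stages = filter_loci(g)
        assert (stages["missing"], stages["reproducibility"], stages["maf"]) \
            == (1, 1, 1)
        assert list(out.loci["locus_id"]) == ["L0"]

    def test_clean_matrix_unchanged_and_idempotent(self):
        counts = np.tile([0, 1, 2, 1], (5, 1)).T.astype(np.int16)
        counts = np.tile([[0], [1], [2], [1], [1]], (1, 3)).astype(np.int16)
        g = self._matrix(counts)
        out, stages = filter_loci(g)
        assert out.n_loci == g.n_loci
        assert sum(stages.values()) == 0
        again, stages2 = filter_loci(out)
        np.testing.assert_array_equal(again.counts, out.counts)
        assert sum(stages2.values()) == 0


class TestFilterIndividuals:
    def test_boundary_is_strict(self):
        # missing fractions 0.05, 0.20, 0.19 over 100 loci -> one removed
        counts = np.ones((3, 100), dtype=np.int16)
        counts[0, :5] = -1
        counts[1, :20] = -1
        counts[2, :19] = -1
        samples = pd.DataFrame({"sample_id": ["a", "b", "c"],
                                "population": "A", "lon": 0.0, "lat": 0.0})
        loci = pd.DataFrame({"locus_id": [f"L{j}" for j in range(100)],
                             "fragment_id": [f"f{j}" for j in range(100)],
                             "reproducibility": 1.0})
        g = GenotypeMatrix(counts=counts, samples=samples, loci=loci)
        out, removed = filter_individuals(g, max_missing=0.20)
        assert removed == ["b"]

    def test_complete_data_no_removals(self, toy_genotypes):
        out, removed = filter_individuals(toy_genotypes)
        assert removed == []
        assert out.n_samples == toy_genotypes.n_samples


class TestThinning:
    def test_fragment_sizes_and_forced_choice(self):
        counts = np.random.default_rng(0).integers(0, 3, (4, 6)).astype(np.int16)
        samples = pd.DataFrame({"sample_id": list("abcd"), "population": "A",
                                "lon": 0.0, "lat": 0.0})
        loci = pd.DataFrame({"locus_id": [f"L{j}" for j in range(6)],
                             "fragment_id": ["f1", "f2", "f2", "f3", "f3", "f3"],
                             "reproducibility": 1.0})
        g = GenotypeMatrix(counts=counts, samples=samples, loci=loci)
        out = thin_one_per_fragment(g, seed=0)
        assert out.n_loci == 3
        assert "L0" in list(out.loci["locus_id"])  # singleton always kept
        # count (but not identity) is seed-invariant
        for seed in (1, 2, 3):
            assert thin_one_per_fragment(g, seed=seed).n_loci == 3
        np.testing.assert_array_equal(
            thin_one_per_fragment(g, seed=7).counts,
            thin_one_per_fragment(g, seed=7).counts)

    def test_all_singletons_identity(self, toy_genotypes):
        g = toy_genotypes.subset_loci([2, 3])  # fragments f1, f2
        out = thin_one_per_fragment(g, seed=0)
        np.testing.assert_array_equal(out.counts, g.counts)


def test_global_missing_rate(toy_genotypes):
    assert global_missing_rate(toy_genotypes) == 0.0
    counts = toy_genotypes.counts.copy()
    counts[0, 0] = -1
    g = GenotypeMatrix(counts=counts, samples=toy_genotypes.samples,
                       loci=toy_genotypes.loci)
    assert global_missing_rate(g) == pytest.approx(1 / 24)


def test_qc_report_reconciles_and_bounds_missingness(sim_species):
    g = sim_species["genotypes"]
    out, report = run_qc(g, seed=1)
    assert report.n_loci_in == g.n_loci
    assert out.n_loci == report.n_loci_out
    assert out.n_samples == report.n_samples_out
    assert set(out.loci["locus_id"]) <= set(g.loci["locus_id"])
    # QC removes high-missingness loci, so the rate can only shrink
    assert 0 <= report.global_missing_after <= sim_species["config"].missing_rate
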