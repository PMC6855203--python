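import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from crossase import ase as am
from crossase import phasing, synthetic


def loci_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


class TestSnpToGeneMapping:
    def test_coordinate_conversion_and_intron(self):
        loci = loci_frame([("1", 100, "A", "G"), ("1", 150, "C", "T")])
        exons = pd.DataFrame(
            {"chrom": ["1"], "start": [99], "end": [100], "gene_id": ["g1"]}
        )
        snp_map, dropped = am.map_snps_to_gene_exons(loci, exons)
        assert list(snp_map.itertuples(index=False))[0][:3] == ("1", 100, "g1")
        assert dropped == 1  # the intronic/intergenic SNP

    def test_overlapping_genes_flagged_ambiguous(self):
        loci = loci_frame([("1", 100, "A", "G")])
        exons = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [90, 95], "end": [110, 105],
             "gene_id": ["g1", "g2"]}
        )
        snp_map, _ = am.map_snps_to_gene_exons(loci, exons)
        assert sorted(snp_map["gene_id"]) == ["g1", "g2"]
        assert snp_map["ambiguous"].all()

    def test_malformed_interval_rejected(self):
        loci = loci_frame([("1", 100, "A", "G")])
        exons = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [100], "gene_id": ["g1"]})
        with pytest.raises(ValueError):
            am.map_snps_to_gene_exons(loci, exons)


class TestResolveMultiSnpReads:
    LOCI = loci_frame([("1", 10, "A", "G"), ("1", 20, "C", "T")])

    def read_rows(self, rows):
        return pd.DataFrame(
            rows, columns=["read_id", "sample", "tissue", "chrom", "pos", "allele"]
        )

    def test_read_counted_once_at_lowest_position(self):
        reads = self.read_rows(
            [("r1", "s1", "liver", "1", 10, "A"), ("r1", "s1", "liver", "1", 20, "C")]
        )
        agg, discarded = am.resolve_multi_snp_reads(reads, self.LOCI)
        assert len(agg) == 1 and agg.iloc[0].pos == 10
        assert agg.iloc[0].ref_count == 1 and discarded == 0

    def test_allele_aggregation(self):
        reads = self.read_rows(
            [("r1", "s1", "liver", "1", 10, "A"), ("r2", "s1", "liver", "1", 10, "G")]
        )
        agg, _ = am.resolve_multi_snp_reads(reads, self.LOCI)
        assert (agg.iloc[0].ref_count, agg.iloc[0].alt_count) == (1, 1)

    def test_mismatching_base_discarded(self):
        reads = self.read_rows([("r1", "s1", "liver", "1", 10, "T")])
        agg, discarded = am.resolve_multi_snp_reads(reads, self.LOCI)
        assert len(agg) == 0 and discarded == 1

    def test_read_conservation(self):
        rng = np.random.default_rng(9)
        rows = []
        for r in range(300):
            n_snps = rng.integers(1, 3)
            for pos in rng.choice([10, 20], size=n_snps, replace=False):
                allele = rng.choice(["A", "G", "C", "T"])
                rows.append((f"r{r}", "s1", "liver", "1", int(pos), allele))
        agg, discarded = am.resolve_multi_snp_reads(self.read_rows(rows), self.LOCI)
        assert int(agg[["ref_count", "alt_count"]].sum().sum()) + discarded == 300


class TestGeneAllelicCounts:
    def test_orientation_by_phase(self):
        counts = pd.DataFrame(
            {
                "sample": ["s1", "s1"],
                "tissue": ["liver", "liver"],
                "chrom": ["1", "1"],
                "pos": [10, 20],
                "ref": ["A", "C"],
                "alt": ["G", "T"],
                "ref_count": [3, 4],
                "alt_count": [7, 6],
            }
        )
        phase = pd.DataFrame(
            {"sample": ["s1", "s1"], "chrom": ["1", "1"], "pos": [10, 20],
             "paternal_allele": [0, 1]}
        )
        snp_map = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [10, 20], "gene_id": ["g1", "g1"]}
        )
        gene_counts, dropped = am.gene_allelic_counts(counts, phase, snp_map)
        row = gene_counts.iloc[0]
        assert (row.pat_count, row.mat_count) == (3 + 6, 7 + 4)
        assert dropped == 0

    def test_unphased_rows_dropped(self):
        counts = pd.DataFrame(
            {"sample": ["s1"], "tissue": ["liver"], "chrom": ["1"], "pos": [10],
             "ref": ["A"], "alt": ["G"], "ref_count": [10], "alt_count": [0]}
        )
        phase = pd.DataFrame(columns=["sample", "chrom", "pos", "paternal_allele"])
        snp_map = pd.DataFrame({"chrom": ["1"], "pos": [10], "gene_id": ["g1"]})
        gene_counts, dropped = am.gene_allelic_counts(counts, phase, snp_map)
        assert len(gene_counts) == 0 and dropped == 1


class TestBinomialTest:
    def test_frozen_exact_values(self):
        # computed with the exact integer-tail oracle
        assert oracles.binom_two_sided_exact(10, 10) == 2 / 1024
        assert oracles.binom_two_sided_exact(9, 10) == 22 / 1024
        assert am.binomial_ase_test(5, 5) == 1.0
        assert am.binomial_ase_test(10, 0) == pytest.approx(2 / 1024, abs=1e-15)
        assert am.binomial_ase_test(9, 1) == pytest.approx(22 / 1024, abs=1e-15)

    def test_minimum_count_rule(self):
        assert np.isnan(am.binomial_ase_test(5, 4))  # total 9 < 10
        assert not np.isnan(am.binomial_ase_test(5, 5))

    def test_matches_scipy_binomtest(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(10, 400))
            k = int(rng.integers(0, n + 1))
            expected = stats.binomtest(k, n, 0.5).pvalue
            assert am.binomial_ase_test(k, n - k) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            am.binomial_ase_test(-1, 5)


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(am.bonferroni_adjust([0.001], m=50), [0.05])
        np.testing.assert_allclose(am.bonferroni_adjust([0.5], m=3), [1.0])
        np.testing.assert_allclose(am.bonferroni_adjust([0.3]), [0.3])  # m = 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            am.bonferroni_adjust([1.2])


def records_from_counts(pat_mat, **kwargs):
    gene_counts = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(pat_mat))],
            "sample": "s1",
            "tissue": "liver",
            "pat_count": [p for p, _ in pat_mat],
            "mat_count": [m for _, m in pat_mat],
            "n_snps": 1,
        }
    )
    return am.classify_genes(gene_counts, **kwargs)


class TestClassification:
    def test_alpha_boundary_is_strict(self):
        # single tested gene: adjusted p = p = 2/1024 exactly
        p = 2 / 1024
        assert records_from_counts([(10, 0)], alpha=p).iloc[0].classification == am.NA
        assert records_from_counts([(10, 0)], alpha=p * 1.01).iloc[0].classification == am.ASE

    def test_low_count_gene_is_na(self):
        rec = records_from_counts([(4, 3)]).iloc[0]
        assert rec.classification == am.NA and np.isnan(rec.p_value)

    def test_no_het_snp_from_universe(self):
        universe = pd.DataFrame(
            {"gene_id": ["g0", "gx"], "sample": "s1", "tissue": "liver"}
        )
        records = am.classify_genes(
            pd.DataFrame(
                {"gene_id": ["g0"], "sample": ["s1"], "tissue": ["liver"],
                 "pat_count": [20], "mat_count": [0], "n_snps": [1]}
            ),
            gene_universe=universe,
        )
        by_gene = records.set_index("gene_id")["classification"]
        assert by_gene["gx"] == am.NO_HET_SNP and by_gene["g0"] == am.ASE

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(4)
        pat_mat = [(int(a), int(b)) for a, b in rng.integers(0, 60, size=(200, 2))]
        records = records_from_counts(pat_mat)
        assert set(records.classification) <= {am.ASE, am.NA, am.NO_HET_SNP}
        assert len(records) == 200
        ratio = records.allelic_ratio.dropna()
        assert (ratio >= 0.5).all() and (ratio <= 1.0).all()


class TestHighConfidence:
    def make_records(self, gene_sample_class):
        rows = []
        for gene, sample, cls in gene_sample_class:
            rows.append(
                {"gene_id": gene, "sample": sample, "tissue": "liver",
                 "classification": cls, "allelic_ratio": 0.8}
            )
        return pd.DataFrame(rows)

    def test_support_threshold(self):
        records = self.make_records(
            [("g1", "s1", am.ASE), ("g1", "s4", am.ASE), ("g2", "s1", am.ASE),
             ("g2", "s2", am.NA)]
        )
        out = am.call_high_confidence_ase(records)
        assert list(out.gene_id) == ["g1"] and out.iloc[0].n_ase_samples == 2

    def test_planted_effects_recovered(self):
        """End-to-end recovery: with effects planted at a 0.8 paternal ratio
        and deep coverage, at least 90% of true ASE genes reach the
        high-confidence set and their median allelic ratio is close to 0.8."""
        freqs = synthetic.simulate_breed_frequencies(
            synthetic.BreedModel(n_loci=30_000, seed=1)
        )
        fam = synthetic.simulate_dly_family(freqs, seed=2)
        exons = synthetic.simulate_gene_model(freqs, n_genes=200, seed=3)
        truth = synthetic.simulate_allelic_counts(fam, exons, seed=3)
        phased = phasing.phase_family(fam.matrix, fam.pedigree)
        snp_map, _ = am.map_snps_to_gene_exons(fam.matrix.loci, exons)
        gene_counts, _ = am.gene_allelic_counts(truth.counts, phased.phase_table(), snp_map)
        records = am.classify_genes(gene_counts)
        high = am.call_high_confidence_ase(records)
        planted = truth.truth[truth.truth.true_ratio != 0.5]
        hit = high.merge(planted, on=["gene_id", "tissue"])
        assert len(hit) / len(planted) >= 0.9
        assert np.median(hit.median_allelic_ratio) == pytest.approx(0.8, abs=0.03)


class TestTissueSpecificity:
    def test_examples(self):
        overlap, frac = am.tissue_specificity({"A": {"g1", "g2"}, "B": {"g2"}})
        assert frac == 0.5
        only_a = overlap.set_index("tissues").loc["A", "n_genes"]
        both = overlap.set_index("tissues").loc["A+B", "n_genes"]
        assert only_a == 1 and both == 1

    def test_disjoint_and_identical(self):
        assert am.tissue_specificity({"A": {"g1"}, "B": {"g2"}})[1] == 1.0
        assert am.tissue_specificity({"A": {"g1"}, "B": {"g1"}})[1] == 0.0

    def test_requires_two_tissues(self):
        with pytest.raises(ValueError):
            am.tissue_specificity({"A": {"g1"}})
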