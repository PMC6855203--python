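import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import freq_table
from crossase import phs
from crossase.phs import Cross, CrossScheme, PHSTable

DLY = CrossScheme.from_code("DLY")


def table_from_phs(values) -> PHSTable:
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(len(values)) + 1) * 10,
            "ref": "A",
            "alt": "G",
            "pRR": 0.0,
            "pHet": values,
            "pAA": 0.0,
            "phs": values,
        }
    )
    return PHSTable(scheme="toy", table=df, n_excluded=0)


class TestTransmittedFrequency:
    def test_leaf_and_cross(self):
        freqs = freq_table(D=[1.0], L=[0.0], Y=[0.5])
        assert phs.transmitted_allele_frequency("D", freqs)[0] == 1.0
        assert phs.transmitted_allele_frequency("Y", freqs)[0] == 0.5
        # F1 of a fixed difference transmits each allele equally
        assert phs.transmitted_allele_frequency(Cross("D", "L"), freqs)[0] == 0.5

    def test_leaf_from_genotype_triple(self):
        # genotype frequencies (0.25, 0.5, 0.25) correspond to f = 0.5
        assert 0.25 + 0.5 / 2 == 0.5

    def test_unknown_breed(self):
        with pytest.raises(KeyError):
            phs.transmitted_allele_frequency("Z", freq_table(1, 1, 1))


class TestPhsForScheme:
    def test_fixed_and_symmetric_cases(self):
        freqs = freq_table(D=[1.0, 0.5, 0.9], L=[0.0, 0.5, 0.1], Y=[0.0, 0.5, 0.1])
        table = phs.phs_for_scheme(DLY, freqs)
        np.testing.assert_allclose(table.phs, [1.0, 0.5, 0.82])
        np.testing.assert_allclose(
            table.table[["pRR", "pHet", "pAA"]].sum(axis=1), 1.0, atol=1e-12
        )

    def test_082_against_enumeration(self):
        # brute-force all parental genotype pairs x gamete transmissions
        triples = {
            "D": (0.81, 0.18, 0.01),  # HWE at f = 0.9
            "L": (0.01, 0.18, 0.81),
            "Y": (0.01, 0.18, 0.81),
        }
        dist = oracles.enumerate_offspring_distribution(DLY.root, triples)
        assert dist[1] == pytest.approx(0.82, abs=1e-12)

    def test_leaf_only_scheme_rejected(self):
        with pytest.raises(ValueError):
            phs.phs_for_scheme(CrossScheme(name="D", root="D"), freq_table(1, 1, 1))

    def test_missing_breed_loci_excluded(self):
        freqs = freq_table(D=[0.5, np.nan], L=[0.5, 0.5], Y=[0.5, 0.5])
        table = phs.phs_for_scheme(DLY, freqs)
        assert len(table.table) == 1 and table.n_excluded == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6))
    def test_closed_form_equals_enumeration(self, raw):
        """Closed form over transmitted frequencies must equal brute-force
        genotype-pair enumeration for arbitrary (non-HWE) genotype triples."""
        trip = {}
        for i, breed in enumerate(("D", "L", "Y")):
            a, b = raw[2 * i], raw[2 * i + 1]
            p0, p1 = min(a, b), abs(a - b)
            trip[breed] = (p0, p1, 1.0 - p0 - p1)
        f = {b: t[0] + t[1] / 2 for b, t in trip.items()}
        table = phs.phs_for_scheme(DLY, freq_table(f["D"], f["L"], f["Y"]))
        expected = oracles.enumerate_offspring_distribution(DLY.root, trip)
        np.testing.assert_allclose(
            table.table[["pRR", "pHet", "pAA"]].to_numpy()[0], expected, atol=1e-12
        )

    def test_dam_side_order_symmetry(self, default_freqs):
        dly = phs.phs_for_scheme(CrossScheme.from_code("DLY"), default_freqs)
        dyl = phs.phs_for_scheme(CrossScheme.from_code("DYL"), default_freqs)
        np.testing.assert_array_equal(dly.phs, dyl.phs)

    def test_two_way_symmetry(self, default_freqs):
        ly = phs.phs_for_scheme(CrossScheme.from_code("LY"), default_freqs)
        yl = phs.phs_for_scheme(CrossScheme.from_code("YL"), default_freqs)
        np.testing.assert_array_equal(ly.phs, yl.phs)

    def test_phs_one_iff_sides_oppositely_fixed(self):
        rng = np.random.default_rng(3)
        freqs = freq_table(rng.uniform(size=500), rng.uniform(size=500), rng.uniform(size=500))
        freqs.loc[0, ["D", "L", "Y"]] = [1.0, 0.0, 0.0]
        freqs.loc[1, ["D", "L", "Y"]] = [1.0, 1.0, 1.0]
        table = phs.phs_for_scheme(DLY, freqs)
        f_s = freqs["D"].to_numpy()
        f_d = (freqs["L"].to_numpy() + freqs["Y"].to_numpy()) / 2
        is_one = np.isclose(table.phs, 1.0)
        opposite = (np.isclose(f_s, 1) & np.isclose(f_d, 0)) | (
            np.isclose(f_s, 0) & np.isclose(f_d, 1)
        )
        np.testing.assert_array_equal(is_one, opposite)
        assert table.phs[1] == 0.0  # all leaves fixed for the same allele


class TestBinning:
    def test_edge_convention(self):
        binned = phs.bin_phs_counts(table_from_phs([0.0, 0.049, 0.05, 1.0]))
        counts = binned.set_index("bin")["n_loci"]
        assert counts[0] == 2 and counts[1] == 1 and counts[19] == 1

    def test_all_in_one_bin_and_conservation(self):
        binned = phs.bin_phs_counts(table_from_phs([0.51] * 7))
        assert binned.set_index("bin")["n_loci"][10] == 7
        assert binned["n_loci"].sum() == 7

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            phs.bin_phs_counts(table_from_phs([]))

    def test_bin_means(self):
        series = phs.expected_het_by_bin(table_from_phs([0.52, 0.54, 0.31]))
        assert series[10] == pytest.approx(0.53)
        assert series[6] == pytest.approx(0.31)
        assert np.isnan(series[0])

    def test_bin_means_monotone(self, default_freqs):
        table = phs.phs_for_scheme(DLY, default_freqs)
        means = phs.expected_het_by_bin(table).dropna()
        assert means.is_monotonic_increasing


class TestSchemeComparison:
    @staticmethod
    def binning_of(counts):
        return pd.DataFrame({"bin": range(len(counts)), "n_loci": counts})

    def test_identical_and_antilinear(self):
        cmp_ = phs.scheme_pairwise_correlation(
            {"a": self.binning_of([1, 2, 3]), "b": self.binning_of([1, 2, 3]),
             "c": self.binning_of([3, 2, 1])}
        )
        assert cmp_.r.loc["a", "b"] == pytest.approx(1.0)
        assert cmp_.r.loc["a", "c"] == pytest.approx(-1.0)
        assert cmp_.mean_r("a") == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        cmp_ = phs.scheme_pairwise_correlation(
            {"a": self.binning_of([2, 2, 2]), "b": self.binning_of([1, 2, 3])}
        )
        assert np.isnan(cmp_.r.loc["a", "b"])


class TestObservedHet:
    def test_observed_fraction(self):
        table = table_from_phs([0.52, 0.52, 0.52, 0.52, 0.11])
        fit = phs.observed_het_by_bin(np.array([1, 1, 0, 0, 1]), table)
        row = fit.per_bin.set_index("bin").loc[10]
        assert row.obs_het_fraction == 0.5 and row.n_called == 4

    def test_offspring_track_expected_curve_better_than_purebred(self, default_freqs, family):
        table = phs.phs_for_scheme(DLY, default_freqs)
        r_child = phs.observed_het_by_bin(family.matrix.vector("DLY_01"), table).r
        r_duroc = phs.observed_het_by_bin(family.matrix.vector("D_SIRE"), table).r
        assert r_child >= 0.9
        assert r_duroc < r_child


class TestHighPhsMarkers:
    def test_threshold_is_strict(self):
        table = table_from_phs([0.95, 0.8, 0.91])
        assert len(phs.high_phs_markers(table, 0.9)) == 2
        assert len(phs.high_phs_markers(table, 1.0)) == 0
        assert len(phs.high_phs_markers(table, 0.0)) == 3

    def test_zero_threshold_keeps_only_polymorphic(self):
        table = table_from_phs([0.0, 0.2])
        assert list(phs.high_phs_markers(table, 0.0)["phs"]) == [0.2]
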