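"""Density maps, overlaps, proportions, expected/observed, TATA scan."""

import numpy as np
import pandas as pd
import pytest

import promkic as pk


class TestDensityMap:
    def test_counts_conserved(self, rng):
        centers = [tuple(c) for c in rng.uniform(0, 100, size=(57, 2))]
        m = pk.density_map(centers)
        assert m.total == 57

    def test_same_bin_accumulates(self):
        m = pk.density_map([(10.2, 20.3), (10.4, 20.9), (10.9, 20.1)], bin_size=1.0)
        assert m.grid[10, 20] == 3
        assert m.total == 3

    def test_edge_goes_to_higher_bin(self):
        m = pk.density_map([(10.0, 0.0)], bin_size=1.0)
        assert m.grid[10, 0] == 1

    def test_hundred_lands_in_top_bin(self):
        m = pk.density_map([(100.0, 100.0)], bin_size=1.0)
        assert m.grid[99, 99] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pk.density_map([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pk.density_map([(101.0, 5.0)])


class TestOverlap:
    def test_identical_is_one(self, rng):
        centers = [tuple(c) for c in rng.uniform(0, 100, size=(40, 2))]
        m = pk.density_map(centers)
        assert pk.overlap(m, m) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        a = pk.density_map([(10.0, 10.0)])
        b = pk.density_map([(90.0, 90.0)])
        assert pk.overlap(a, b) == 0.0

    def test_symmetric(self, rng):
        a = pk.density_map([tuple(c) for c in rng.uniform(0, 100, (30, 2))])
        b = pk.density_map([tuple(c) for c in rng.uniform(0, 100, (45, 2))])
        assert pk.overlap(a, b) == pytest.approx(pk.overlap(b, a))

    def test_equals_one_minus_total_variation(self, rng):
        # independent TV computation: 0.5 * sum |pa - pb|
        a = pk.density_map([tuple(c) for c in rng.uniform(0, 100, (60, 2))])
        b = pk.density_map([tuple(c) for c in rng.uniform(0, 100, (80, 2))])
        pa = a.grid / a.grid.sum()
        pb = b.grid / b.grid.sum()
        tv = 0.5 * np.abs(pa - pb).sum()
        assert pk.overlap(a, b) == pytest.approx(1.0 - tv)

    def test_binning_mismatch_rejected(self, rng):
        a = pk.density_map([(5.0, 5.0)], bin_size=1.0)
        b = pk.density_map([(5.0, 5.0)], bin_size=2.0)
        with pytest.raises(ValueError):
            pk.overlap(a, b)


class TestProportions:
    def test_single_class_row(self):
        labels = {f"s{i}": "CG_based" for i in range(10)}
        groups = {f"s{i}": "Human" for i in range(10)}
        table = pk.class_proportions(labels, groups)
        assert table.loc["Human", "CG_based"] == 100.0

    def test_rows_sum_to_hundred(self, rng):
        classes = ["AT_based", "CG_based", "AT_spike"]
        labels = {f"s{i}": classes[rng.integers(3)] for i in range(60)}
        groups = {f"s{i}": f"g{rng.integers(4)}" for i in range(60)}
        table = pk.class_proportions(labels, groups)
        assert np.allclose(table.sum(axis=1), 100.0)

    def test_identical_groups_identical_rows(self):
        labels = {}
        groups = {}
        for g in ("a", "b"):
            for i, lab in enumerate(["AT_based"] * 3 + ["CG_based"] * 7):
                labels[f"{g}{i}"] = lab
                groups[f"{g}{i}"] = g
        table = pk.class_proportions(labels, groups)
        assert table.loc["a"].equals(table.loc["b"])

    def test_ungrouped_pooled(self):
        labels = {"s1": "AT_based", "s2": "CG_based"}
        table = pk.class_proportions(labels)
        assert list(table.index) == ["ungrouped"]

    def test_transposed_view_rows_sum_to_hundred(self, rng):
        classes = ["AT_based", "CG_based"]
        labels = {f"s{i}": classes[rng.integers(2)] for i in range(40)}
        groups = {f"s{i}": f"t{rng.integers(3)}" for i in range(40)}
        t = pk.group_distribution_per_class(labels, groups)
        assert np.allclose(t.sum(axis=1), 100.0)


class TestExpectedObserved:
    REF = {"AT_based": 30.0, "CG_based": 50.0, "AT_spike": 20.0}

    def test_subset_equals_reference_population(self):
        subset = ["AT_based"] * 30 + ["CG_based"] * 50 + ["AT_spike"] * 20
        table = pk.expected_observed(self.REF, subset)
        assert np.allclose(table["observed_pct"], table["expected_pct"])
        assert np.allclose(table["ratio"], 1.0)

    def test_absent_class_flagged(self):
        subset = ["AT_based"] * 10
        table = pk.expected_observed(self.REF, subset)
        assert table.loc["CG_based", "observed_pct"] == 0.0
        assert table.loc["CG_based", "ratio"] == 0.0
        assert table.loc["CG_based", "absent"]

    def test_iid_subsample_ratios_near_one(self, rng):
        labels = list(self.REF)
        probs = np.array(list(self.REF.values())) / 100.0
        subset = [labels[i] for i in rng.choice(3, size=4000, p=probs)]
        table = pk.expected_observed(self.REF, subset)
        assert np.allclose(table["ratio"], 1.0, atol=0.12)

    def test_biased_subsample_detected(self, rng):
        subset = ["AT_spike"] * 300 + ["CG_based"] * 100
        table = pk.expected_observed(self.REF, subset)
        assert table.loc["AT_spike", "ratio"] > 2.0
        assert table.loc["AT_based", "ratio"] == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            pk.expected_observed(self.REF, [])

    def test_bad_reference_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            pk.expected_observed({"a": 10.0, "b": 10.0}, ["a"])


class TestPairwiseRelation:
    def _table(self, a, b):
        return pd.DataFrame({"A": a, "B": b}, index=["g1", "g2", "g3"])

    def test_perfect_anticorrelation_complementary(self):
        r, tag = pk.pairwise_relation(self._table([10, 20, 30], [30, 20, 10]), "A", "B")
        assert r == pytest.approx(-1.0)
        assert tag == "complementary"

    def test_identical_columns_proportional(self):
        r, tag = pk.pairwise_relation(self._table([10, 20, 30], [10, 20, 30]), "A", "B")
        assert r == pytest.approx(1.0)
        assert tag == "proportional"

    def test_constant_column_undefined(self):
        r, tag = pk.pairwise_relation(self._table([10, 10, 10], [30, 20, 10]), "A", "B")
        assert np.isnan(r)
        assert tag == "undefined"

    def test_too_few_groups_rejected(self):
        table = pd.DataFrame({"A": [1, 2], "B": [2, 1]})
        with pytest.raises(ValueError, match="3 groups"):
            pk.pairwise_relation(table, "A", "B")


class TestTataScan:
    @staticmethod
    def _promoter(insert="", at=-28):
        # 600 nt all-C segment, TSS at offset 500, with an optional
        # motif planted at a TSS-relative position
        seq = ["C"] * 600
        for i, ch in enumerate(insert):
            seq[500 + at + i] = ch
        return pk.PromoterSequence(id="p", sequence="".join(seq), tss_offset=500)

    def test_planted_tata_found(self):
        s = self._promoter("TATAAAA", at=-28)
        res = pk.scan_tata(s)
        assert res.tata_containing
        assert res.hits[0] == (472, "TATAAAA")

    def test_gc_sequence_has_no_hit(self):
        res = pk.scan_tata(self._promoter())
        assert not res.tata_containing
        assert res.hits == ()

    def test_iupac_w_matches_a_and_t(self):
        for w in ("TATAAAT", "TATATAA"):
            assert pk.scan_tata(self._promoter(w, at=-30)).tata_containing

    def test_hit_must_lie_fully_inside_region(self):
        # motif starts inside the region but runs past its right edge
        s = self._promoter("TATAAAA", at=-22)
        assert not pk.scan_tata(s, region=(-40, -19)).tata_containing

    def test_region_outside_sequence_rejected(self):
        s = self._promoter()
        with pytest.raises(ValueError, match="outside"):
            pk.scan_tata(s, region=(-600, -550))

    def test_bad_iupac_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            pk.scan_tata(self._promoter(), motif="TAZA")
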