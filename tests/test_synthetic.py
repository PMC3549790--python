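"""Synthetic promoter generation, structural audits, mutation model."""

import numpy as np
import pytest

import promkic as pk
from promkic.classifier import CLASS_LABELS
from promkic.synthetic import ClassRecipe, expected_at_fraction, max_run_length


class TestRecipes:
    def test_ten_distinct_recipes(self):
        recipes = [pk.default_recipe(lab) for lab in CLASS_LABELS]
        assert len({r.label for r in recipes}) == 10

    def test_spike_recipes_demand_long_tracts(self):
        for lab in ("AT_spike", "CG_spike"):
            r = pk.default_recipe(lab)
            assert r.n_long_tracts >= 1
            assert r.long_tract_len[0] >= 30

    def test_compact_recipe_interspersed_quarter_each(self):
        r = pk.default_recipe("ATCG_compact")
        assert r.at_fraction == pytest.approx(0.5)  # A=T=C=G=25%

    def test_depletion_mirror_pair(self):
        at_less = pk.default_recipe("AT_less")
        cg_less = pk.default_recipe("CG_less")
        assert at_less.depletion_blocks[0].bases == "AT"  # CG-depleted block
        assert cg_less.depletion_blocks[0].bases == "CG"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            pk.default_recipe("XY_based")


class TestGenerate:
    def test_deterministic(self):
        r = pk.default_recipe("AT_based")
        assert pk.generate(r, seed=5).sequence == pk.generate(r, seed=5).sequence

    def test_seed_changes_sequence(self):
        r = pk.default_recipe("AT_based")
        assert pk.generate(r, seed=5).sequence != pk.generate(r, seed=6).sequence

    @pytest.mark.parametrize("label", CLASS_LABELS)
    def test_structural_audit_passes(self, label):
        recipe = pk.default_recipe(label)
        for seed in range(5):
            seq = pk.generate(recipe, seed=seed)
            assert pk.audit_sequence(seq, recipe) == []

    def test_spike_has_long_run(self):
        recipe = pk.default_recipe("AT_spike")
        for seed in range(10):
            seq = pk.generate(recipe, seed=seed)
            assert max_run_length(seq.sequence, "AT") >= 30

    def test_compact_composition_quarter_each(self):
        counts = {b: 0 for b in "ACGT"}
        recipe = pk.default_recipe("ATCG_compact")
        n = 50
        for seed in range(n):
            s = pk.generate(recipe, seed=seed).sequence
            for b in "ACGT":
                counts[b] += s.count(b)
        total = sum(counts.values())
        for b in "ACGT":
            assert counts[b] / total == pytest.approx(0.25, abs=0.05)

    def test_infeasible_recipe_rejected(self):
        bad = ClassRecipe(
            label="AT_based",
            length=100,
            short_tracts=((40, "AT"),),
            short_tract_len=(8, 8),
        )
        with pytest.raises(ValueError, match="(infeasible|budget)"):
            pk.generate(bad, seed=0)

    def test_expected_at_fraction_tracks_observation(self):
        for label in CLASS_LABELS:
            recipe = pk.default_recipe(label)
            exp = expected_at_fraction(recipe)
            obs = np.mean(
                [
                    sum(
                        1 for c in pk.generate(recipe, seed=s).sequence if c in "AT"
                    )
                    / recipe.length
                    for s in range(10)
                ]
            )
            assert obs == pytest.approx(exp, abs=0.05)


class TestFixtureSet:
    def test_balanced_and_sized(self):
        pairs = pk.make_fixture_set(3, seed=1)
        assert len(pairs) == 30
        labels = [lab for _, lab in pairs]
        for lab in CLASS_LABELS:
            assert labels.count(lab) == 3

    def test_canonical_training_scale(self):
        pairs = pk.make_fixture_set(20, seed=1)
        assert len(pairs) == 200

    def test_deterministic(self):
        a = pk.make_fixture_set(2, seed=9)
        b = pk.make_fixture_set(2, seed=9)
        assert [(s.sequence, lab) for s, lab in a] == [
            (s.sequence, lab) for s, lab in b
        ]

    def test_ids_unique(self):
        pairs = pk.make_fixture_set(2, seed=9)
        ids = [s.id for s, _ in pairs]
        assert len(set(ids)) == len(ids)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            pk.make_fixture_set(0, seed=1)


class TestMutate:
    def _seq(self):
        return pk.generate(pk.default_recipe("ATCG_balanced"), seed=4)

    @staticmethod
    def hamming(a, b):
        return sum(1 for x, y in zip(a, b) if x != y)

    def test_rate_zero_identity(self):
        s = self._seq()
        assert pk.mutate(s, pk.MutationSpec(rate=0.0, seed=1)).sequence == s.sequence

    def test_rate_one_changes_every_site(self):
        s = self._seq()
        m = pk.mutate(s, pk.MutationSpec(rate=1.0, seed=1))
        assert self.hamming(s.sequence, m.sequence) == len(s.sequence)

    def test_expected_hamming_distance(self):
        s = self._seq()
        dists = [
            self.hamming(
                s.sequence, pk.mutate(s, pk.MutationSpec(rate=0.02, seed=k)).sequence
            )
            for k in range(300)
        ]
        # binomial mean 0.02 * 600 = 12, sd of the mean ~ 0.2
        assert np.mean(dists) == pytest.approx(12.0, abs=1.0)

    def test_alphabet_preserved(self):
        s = self._seq()
        m = pk.mutate(s, pk.MutationSpec(rate=0.5, seed=2))
        assert set(m.sequence) <= set("ACGT")

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            pk.MutationSpec(rate=1.5, seed=0)


class TestSeparability:
    def test_classes_further_apart_than_within(self):
        # silhouette-style check: mean between-class raster distance
        # exceeds mean within-class distance
        pairs = pk.make_fixture_set(4, seed=21)
        rasters = {}
        for s, lab in pairs:
            rasters.setdefault(lab, []).append(
                pk.rasterize(pk.build_pattern(s), width=87, height=67)
            )
        within, between = [], []
        labs = list(rasters)
        for lab in labs:
            rs = rasters[lab]
            for i in range(len(rs)):
                for j in range(i + 1, len(rs)):
                    within.append(pk.pattern_distance(rs[i], rs[j]))
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                between.append(
                    pk.pattern_distance(rasters[labs[i]][0], rasters[labs[j]][0])
                )
        assert np.mean(between) > np.mean(within)
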