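"""Comparison classification, enumeration, quartets, and diet contrasts."""

from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
import pytest

import paravec as pv
from paravec.comparisons import EXCLUDED, NONPARALLEL, PARALLEL
from paravec.ordination import CentroidSet


def make_centroids(points: dict[str, list[float]]) -> CentroidSet:
    coords = pd.DataFrame.from_dict(points, orient="index")
    coords.columns = [f"PC{i+1}" for i in range(coords.shape[1])]
    return CentroidSet(coordinates=coords, counts=pd.Series(3, index=coords.index))


class TestClassify:
    def test_same_diet_sets_are_parallel(self):
        assert (
            pv.classify_comparison(("plants", "meat-fish"), ("meat-fish", "plants"))
            == PARALLEL
        )

    def test_different_diet_sets_are_nonparallel(self):
        assert (
            pv.classify_comparison(("plants", "meat-fish"), ("plants", "invertebrates"))
            == NONPARALLEL
        )

    def test_within_diet_pair_is_excluded(self):
        assert (
            pv.classify_comparison(("plants", "plants"), ("plants", "meat-fish"))
            == EXCLUDED
        )

    def test_symmetric_in_arguments(self):
        pairs = [("plants", "seeds"), ("fruits", "seeds"), ("plants", "plants")]
        for p1 in pairs:
            for p2 in pairs:
                assert pv.classify_comparison(p1, p2) == pv.classify_comparison(p2, p1)

    def test_unknown_diet_rejected(self):
        with pytest.raises(pv.ValidationError):
            pv.classify_comparison(("plants", "nectar"), ("plants", "seeds"))


@pytest.fixture()
def toy():
    """Four species, two diets, on a balanced cherry-pair tree."""
    tree = dendropy.Tree.get(
        data="((A1:10,B1:10):30,(A2:10,B2:10):30);", schema="newick"
    )
    cents = make_centroids(
        {"A1": [0, 0], "B1": [1, 0], "A2": [0, 1], "B2": [1, 1.5]}
    )
    diet_map = {"A1": "plants", "A2": "plants", "B1": "meat-fish", "B2": "meat-fish"}
    return tree, cents, diet_map


class TestEnumerate:
    def test_raw_comparison_count_is_fifteen(self, toy):
        tree, cents, dm = toy
        vecs = pv.all_pair_vectors(cents, dm)
        comps = pv.enumerate_comparisons(vecs, tree, allow_shared_species=True)
        assert len(vecs) == 6 and len(comps) == 15  # C(6,2)

    def test_no_self_comparisons_and_unique_pairs(self, study):
        comps = pv.enumerate_comparisons(
            study["vectors"], study["tree"], allow_shared_species=True
        )
        keys = set()
        for _, r in comps.iterrows():
            k1 = frozenset([(r.v1_from, r.v1_to), (r.v2_from, r.v2_to)])
            assert (r.v1_from, r.v1_to) != (r.v2_from, r.v2_to)
            assert k1 not in keys
            keys.add(k1)
        n = len(study["vectors"])
        assert len(comps) == n * (n - 1) // 2

    def test_shared_species_excluded_by_default(self, toy):
        tree, cents, dm = toy
        vecs = pv.all_pair_vectors(cents, dm)
        comps = pv.enumerate_comparisons(vecs, tree)
        assert not comps["shares_species"].any()
        assert len(comps) == 3  # three disjoint vector pairs among 4 species

    def test_mean_divergence_time_on_toy_tree(self, toy):
        """Quartet of two cherries at depth 40: within-cherry time 10,
        all four cross times 40 -> mean over six pairs (10+10+4*40)/6."""
        tree, cents, dm = toy
        vecs = pv.all_pair_vectors(cents, dm)
        comps = pv.enumerate_comparisons(vecs, tree)
        pairs = comps.apply(
            lambda r: (frozenset([r.v1_from, r.v1_to]), frozenset([r.v2_from, r.v2_to])),
            axis=1,
        )
        want = (frozenset(["A1", "B1"]), frozenset(["A2", "B2"]))
        row = comps[pairs.map(lambda p: set(p) == set(want))].iloc[0]
        assert row["mean_divergence_time_all_pairs"] == pytest.approx((20 + 160) / 6)
        assert row["mean_divergence_time_within"] == pytest.approx(10.0)

    def test_category_counts_partition_comparisons(self, study):
        comps = pv.enumerate_comparisons(study["vectors"], study["tree"])
        assert set(comps["category"]) <= {PARALLEL, NONPARALLEL, EXCLUDED}
        assert comps["category"].value_counts().sum() == len(comps)

    def test_missing_tree_species_raises(self, toy):
        _, cents, dm = toy
        small_tree = dendropy.Tree.get(data="(A1:10,B1:10);", schema="newick")
        vecs = pv.all_pair_vectors(cents, dm)
        with pytest.raises(pv.MissingSpeciesError):
            pv.enumerate_comparisons(vecs, small_tree)

    def test_shared_diet_orientation_changes_only_shared_diet_angles(self, study):
        base = pv.enumerate_comparisons(study["vectors"], study["tree"])
        reor = pv.enumerate_comparisons(
            study["vectors"], study["tree"], orientation="shared-diet"
        )
        merged = base.merge(
            reor, on=["v1_from", "v1_to", "v2_from", "v2_to"], suffixes=("_a", "_b")
        )
        for _, r in merged.iterrows():
            d1 = set(r["v1_diets_a"].split("|"))
            d2 = set(r["v2_diets_a"].split("|"))
            if np.isnan(r["angle_a"]):
                continue
            if len(d1 & d2) == 1:
                continue  # may flip
            assert r["angle_a"] == pytest.approx(r["angle_b"], abs=1e-12)


class TestQuartets:
    def test_matched_cherries_accepted(self, toy):
        tree, cents, dm = toy
        q = pv.build_quartets(cents, dm, tree)
        assert len(q) == 1
        row = q.iloc[0]
        # diet a is the alphabetically earlier category (meat-fish), so the
        # A-slots hold the meat-fish species
        assert (row.a1, row.b1, row.a2, row.b2) == ("B1", "A1", "B2", "A2")
        assert (row.diet_a, row.diet_b) == ("meat-fish", "plants")

    def test_ecotype_cherries_rejected(self):
        """If same-diet species are each other's closest relatives the
        within-pair relatedness constraint fails."""
        tree = dendropy.Tree.get(
            data="((A1:10,A2:10):30,(B1:10,B2:10):30);", schema="newick"
        )
        cents = make_centroids(
            {"A1": [0, 0], "A2": [1, 0], "B1": [0, 1], "B2": [1, 1]}
        )
        dm = {"A1": "plants", "A2": "plants", "B1": "meat-fish", "B2": "meat-fish"}
        with pytest.warns(UserWarning, match="no qualifying quartets"):
            q = pv.build_quartets(cents, dm, tree)
        assert len(q) == 0

    def test_quartet_diet_structure_implies_parallel_category(self, study):
        q = pv.build_quartets(study["centroids"], study["diet_map"], study["tree"])
        for _, row in q.iterrows():
            assert row.diet_a != row.diet_b
            assert (
                pv.classify_comparison(
                    (row.diet_a, row.diet_b), (row.diet_a, row.diet_b)
                )
                == PARALLEL
            )
            assert len({row.a1, row.a2, row.b1, row.b2}) == 4

    def test_partner_swap_within_half_rejected(self):
        """Swapping cherry partners makes a cross time equal the within
        time, so the strict relatedness constraint must fail."""
        tree = dendropy.Tree.get(
            data="((p1:10,f1:10):30,(p2:10,f2:10):30);", schema="newick"
        )
        cents = make_centroids(
            {"p1": [0, 0], "f1": [1, 0], "p2": [0, 1], "f2": [1, 1]}
        )
        dm = {"p1": "plants", "p2": "plants", "f1": "meat-fish", "f2": "meat-fish"}
        q = pv.build_quartets(cents, dm, tree)
        got = {(r.a1, r.b1, r.a2, r.b2) for _, r in q.iterrows()}
        assert got == {("f1", "p1", "f2", "p2")}


class TestDietContrast:
    def test_partition_is_exhaustive_and_disjoint(self, study):
        contrasts = pv.diet_contrast_groups(study["vectors"], study["tree"])
        assert len(contrasts) == len(study["vectors"])
        assert set(contrasts["group"]) == {"same_diet", "different_diet"}

    def test_group_labels_follow_diet_equality(self, study):
        contrasts = pv.diet_contrast_groups(study["vectors"], study["tree"])
        for _, r in contrasts.iterrows():
            expected = "same_diet" if r.from_diet == r.to_diet else "different_diet"
            assert r.group == expected

    def test_lengths_and_times_match_sources(self, toy):
        tree, cents, dm = toy
        vecs = pv.all_pair_vectors(cents, dm)
        contrasts = pv.diet_contrast_groups(vecs, tree)
        tmat = pv.divergence_time_matrix(tree)
        for v, (_, r) in zip(vecs, contrasts.iterrows()):
            assert r.length == pytest.approx(v.length)
            assert r.divergence_time == pytest.approx(
                tmat.loc[v.from_species, v.to_species]
            )
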