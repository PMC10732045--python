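"""Bray-Curtis, PCoA, axis retention, and centroids against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import pdist, squareform

import paravec as pv
from paravec.ordination import Ordination


def bc_hand(u, v):
    """Closed-form Bray-Curtis, written independently of the pipeline."""
    num = sum(min(a, b) for a, b in zip(u, v))
    return 1.0 - 2.0 * num / (sum(u) + sum(v))


class TestBrayCurtis:
    def test_identical_samples_are_zero(self):
        t = pd.DataFrame({"s1": [3, 1, 4], "s2": [3, 1, 4]}, index=list("abc"))
        assert pv.bray_curtis(t)["s1", "s2"] == 0.0

    def test_disjoint_supports_are_one(self):
        t = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=list("ab"))
        assert pv.bray_curtis(t)["s1", "s2"] == 1.0

    def test_hand_example(self):
        # 1 - 2*(1+2)/(4+4) = 0.25
        t = pd.DataFrame({"s1": [2, 2], "s2": [1, 3]}, index=list("ab"))
        assert pv.bray_curtis(t)["s1", "s2"] == pytest.approx(0.25, abs=1e-15)

    def test_all_zero_sample_rejected(self):
        t = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=list("ab"))
        with pytest.raises(pv.ValidationError, match="all-zero"):
            pv.bray_curtis(t)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        hnp.arrays(
            np.int64, (4, 3), elements=st.integers(min_value=0, max_value=500)
        )
    )
    def test_matches_closed_form(self, counts):
        if (counts.sum(axis=0) == 0).any():
            counts = counts + 1
        t = pd.DataFrame(counts, index=list("abcd"), columns=list("xyz"))
        dm = pv.bray_curtis(t)
        for i, ci in enumerate(t.columns):
            for j, cj in enumerate(t.columns):
                if i < j:
                    expected = bc_hand(t[ci].tolist(), t[cj].tolist())
                    assert dm[ci, cj] == pytest.approx(expected, abs=1e-12)

    def test_feature_permutation_and_zero_padding_invariance(self, rng):
        counts = rng.integers(1, 100, size=(6, 4))
        t = pd.DataFrame(counts, columns=list("wxyz"))
        base = pv.bray_curtis(t).data
        perm = t.sample(frac=1, random_state=0)
        assert np.allclose(pv.bray_curtis(perm).data, base)
        padded = pd.concat([t, pd.DataFrame(np.zeros((2, 4)), columns=t.columns,
                                            index=["z1", "z2"])])
        assert np.allclose(pv.bray_curtis(padded).data, base)


class TestPcoa:
    def test_collinear_points_recover_one_axis(self):
        # points at 0, 1, 3 on a line: Euclidean distances are exact
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        ordn = pv.pcoa(d, sample_ids=list("abc"))
        big = ordn.proportion_explained > 1e-10
        assert big.sum() == 1
        coords = ordn.coordinates.to_numpy()[:, 0]
        recon = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(recon, d, atol=1e-10)

    def test_equilateral_gives_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        ordn = pv.pcoa(d)
        assert len(ordn.eigenvalues) == 2
        assert ordn.eigenvalues[0] == pytest.approx(ordn.eigenvalues[1], rel=1e-10)

    def test_euclidean_cloud_distances_reproduced(self, rng):
        points = rng.normal(size=(40, 5))
        d = squareform(pdist(points))
        ordn = pv.pcoa(d)
        recon = squareform(pdist(ordn.coordinates.to_numpy()))
        assert np.allclose(recon, d, atol=1e-8)

    def test_matches_skbio_pcoa(self, study):
        """Independent cross-check against scikit-bio's implementation."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        dm = pv.bray_curtis(study["table"])
        ours = pv.pcoa(dm)
        theirs = skbio_pcoa(dm, method="eigh")
        th_eigs = theirs.eigvals.to_numpy()
        th_eigs = th_eigs[th_eigs > th_eigs.max() * 1e-12]
        k = min(len(th_eigs), len(ours.eigenvalues))
        assert np.allclose(ours.eigenvalues[:k], th_eigs[:k], rtol=1e-8)
        # coordinates agree up to per-axis sign on non-degenerate axes
        th_coords = theirs.samples.to_numpy()[:, :5]
        our_coords = ours.coordinates.to_numpy()[:, :5]
        for ax in range(5):
            dot = np.dot(th_coords[:, ax], our_coords[:, ax])
            sign = 1.0 if dot >= 0 else -1.0
            assert np.allclose(our_coords[:, ax], sign * th_coords[:, ax], atol=1e-8)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(pv.ValidationError, match="symmetric"):
            pv.pcoa(d)

    def test_too_few_samples_rejected(self):
        with pytest.raises(pv.ValidationError, match="at least 3"):
            pv.pcoa(np.zeros((2, 2)))

    def test_sign_canonicalization_is_deterministic(self, study):
        dm = pv.bray_curtis(study["table"])
        a = pv.pcoa(dm).coordinates
        b = pv.pcoa(dm).coordinates
        assert a.equals(b)
        for col in a.columns[:10]:
            assert a[col].abs().max() == a[col].max()  # top loading positive


class TestRetainAxes:
    def _make(self, props):
        props = np.asarray(props, dtype=float)
        eigs = props * 10.0
        coords = pd.DataFrame(
            np.zeros((3, len(props))),
            columns=[f"PC{i+1}" for i in range(len(props))],
        )
        return Ordination(eigenvalues=eigs, coordinates=coords,
                          proportion_explained=props)

    def test_threshold_drops_small_axes(self):
        kept = pv.retain_axes(self._make([0.6, 0.399, 0.0009]))
        assert kept.n_axes == 2

    def test_exact_threshold_is_dropped(self):
        kept = pv.retain_axes(self._make([0.6, 0.399, 0.001]))
        assert kept.n_axes == 2

    def test_all_above_threshold_all_retained(self):
        kept = pv.retain_axes(self._make([0.5, 0.3, 0.2]))
        assert kept.n_axes == 3

    def test_nothing_retained_is_error(self):
        with pytest.raises(pv.ValidationError):
            pv.retain_axes(self._make([0.0005, 0.0004]))

    def test_retained_proportions_sum_below_one(self, study):
        assert study["ordination"].proportion_explained.sum() <= 1.0 + 1e-12


class TestCentroids:
    def test_single_sample_species_equals_sample(self, study):
        ordn = study["ordination"]
        md = study["metadata"].copy()
        one = md.iloc[[0]].copy()
        one["species"] = "lonely"
        md = pd.concat([md.iloc[1:], one])
        cents = pv.species_centroids(ordn, md)
        expected = ordn.coordinates.loc[one["sample_id"].iloc[0]]
        assert np.allclose(cents.vector("lonely"), expected.to_numpy())

    def test_centroids_match_brute_force_column_means(self, study):
        ordn, md = study["ordination"], study["metadata"]
        cents = pv.species_centroids(ordn, md)
        sp = md["species"].iloc[0]
        members = md.loc[md["species"] == sp, "sample_id"]
        brute = ordn.coordinates.loc[members].to_numpy().mean(axis=0)
        assert np.allclose(cents.vector(sp), brute)
        assert cents.counts[sp] == len(members)

    def test_symmetric_pair_centroid_is_zero(self):
        coords = pd.DataFrame(
            [[1.0, -2.0], [-1.0, 2.0], [0.5, 0.5]],
            index=["s1", "s2", "s3"], columns=["PC1", "PC2"],
        )
        ordn = Ordination(np.array([1.0, 0.5]), coords, np.array([0.6, 0.4]))
        md = pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3"], "species": ["A", "A", "B"]}
        )
        cents = pv.species_centroids(ordn, md)
        assert np.allclose(cents.vector("A"), 0.0)

    def test_sample_without_metadata_is_error(self, study):
        md = study["metadata"].iloc[:-1]
        with pytest.raises(pv.ValidationError, match="without metadata"):
            pv.species_centroids(study["ordination"], md)
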