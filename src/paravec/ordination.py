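"""Bray-Curtis dissimilarity, PCoA, axis retention, and species centroids.

PCoA is classical multidimensional scaling of the Gower-centered squared
dissimilarity matrix. Bray-Curtis is non-Euclidean, so negative
eigenvalues can occur; the policy here is to discard non-positive axes
and report each retained axis' proportion of variation relative to the
sum of positive eigenvalues (no Cailliez/Lingoes correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import ValidationError

#: Eigenvalues below this fraction of the largest are treated as zero.
_EIG_RTOL = 1e-12


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the samples of a feature table.

    ``d(a, b) = 1 - 2 * sum_f min(x_af, x_bf) / (sum_f x_af + sum_f x_bf)``,
    bounded in [0, 1]. The table is features x samples.
    """
    X = table.to_numpy(dtype=float).T
    if (X < 0).any():
        raise ValidationError("feature table contains negative abundances")
    zero = X.sum(axis=1) == 0
    if zero.any():
        bad = table.columns[zero].tolist()
        raise ValidationError(f"all-zero samples have undefined distances: {bad}")
    d = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(c) for c in table.columns])


@dataclass
class Ordination:
    """PCoA result: positive eigenvalues, coordinates, and proportions.

    ``coordinates`` is samples x axes (columns ``PC1..PCk``), scaled so
    axis k has sum of squares equal to eigenvalue k. ``proportion_explained``
    is each eigenvalue over the sum of positive eigenvalues of the full
    decomposition, so it is unchanged by axis retention.
    """

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    proportion_explained: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: DistanceMatrix | np.ndarray, sample_ids: list[str] | None = None) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Gower-centers ``-0.5 * d**2``, eigendecomposes, discards non-positive
    axes, and scales eigenvectors by the square root of their eigenvalue.
    Each axis' sign is canonicalized so its largest-magnitude loading is
    positive. Ties in eigenvalues keep their original order (stable sort).
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValidationError("distance matrix must have a zero diagonal")
        ids = [str(i) for i in range(d.shape[0])] if sample_ids is None else list(sample_ids)
    n = d.shape[0]
    if n < 3:
        raise ValidationError("PCoA requires at least 3 samples")

    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)

    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]

    positive = vals > max(vals.max(), 0.0) * _EIG_RTOL
    if not positive.any():
        raise ValidationError("no positive eigenvalues; degenerate distance matrix")
    vals_pos = vals[positive]
    coords = vecs[:, positive] * np.sqrt(vals_pos)

    # canonical per-axis sign: largest-magnitude loading positive
    for k in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]

    prop = vals_pos / vals_pos.sum()
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PC{k + 1}" for k in range(coords.shape[1])]
    )
    return Ordination(eigenvalues=vals_pos, coordinates=frame, proportion_explained=prop)


def retain_axes(ordination: Ordination, min_proportion: float = 0.001) -> Ordination:
    """Keep axes whose proportion of variation is strictly greater than
    ``min_proportion`` (default 0.1%), preserving order."""
    keep = ordination.proportion_explained > min_proportion
    if not keep.any():
        raise ValidationError("no axes exceed the retention threshold")
    return Ordination(
        eigenvalues=ordination.eigenvalues[keep],
        coordinates=ordination.coordinates.loc[:, keep],
        proportion_explained=ordination.proportion_explained[keep],
    )


@dataclass
class CentroidSet:
    """Per-species mean coordinates over retained axes, plus sample counts."""

    coordinates: pd.DataFrame  # species x axes
    counts: pd.Series  # species -> n samples

    @property
    def species(self) -> list[str]:
        return list(self.coordinates.index)

    def vector(self, species: str) -> np.ndarray:
        if species not in self.coordinates.index:
            from .errors import MissingSpeciesError

            raise MissingSpeciesError(f"no centroid for species {species!r}")
        return self.coordinates.loc[species].to_numpy()


def species_centroids(ordination: Ordination, metadata: pd.DataFrame) -> CentroidSet:
    """Arithmetic mean of member-sample coordinates per species."""
    md = metadata.set_index("sample_id")
    missing = [s for s in ordination.sample_ids if s not in md.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    species = md.loc[ordination.sample_ids, "species"]
    coords = ordination.coordinates.copy()
    coords["__species__"] = species.to_numpy()
    grouped = coords.groupby("__species__")
    means = grouped.mean().sort_index()
    means.index.name = None
    counts = grouped.size().sort_index()
    counts.index.name = None
    return CentroidSet(coordinates=means, counts=counts)
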