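"""Species-pair divergence vectors, angles, and the random-angle null.

A divergence vector connects two species' centroids in retained PCoA
space. The angle between two such vectors measures how parallel the two
community shifts are (0 deg = same direction, 90 deg = unrelated, 180 deg
= opposite); the vector length measures the magnitude of divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import UndefinedAngleError, ValidationError
from .io import DIET_CATEGORIES
from .ordination import CentroidSet

#: Vectors shorter than this are treated as zero for angle purposes.
ZERO_LENGTH_TOL = 1e-12


@dataclass(frozen=True)
class DivergenceVector:
    """Difference of two species centroids, oriented from -> to."""

    from_species: str
    to_species: str
    from_diet: str
    to_diet: str
    delta: np.ndarray
    length: float

    @property
    def diets(self) -> frozenset[str]:
        return frozenset((self.from_diet, self.to_diet))

    @property
    def diet_pair(self) -> tuple[str, str]:
        """Unordered diet pair as a sorted tuple (may repeat a label)."""
        return tuple(sorted((self.from_diet, self.to_diet)))

    @property
    def species_pair(self) -> frozenset[str]:
        return frozenset((self.from_species, self.to_species))

    @property
    def is_zero(self) -> bool:
        return self.length <= ZERO_LENGTH_TOL

    def reversed(self) -> "DivergenceVector":
        return DivergenceVector(
            from_species=self.to_species,
            to_species=self.from_species,
            from_diet=self.to_diet,
            to_diet=self.from_diet,
            delta=-self.delta,
            length=self.length,
        )

    @property
    def label(self) -> str:
        return f"{self.from_species}->{self.to_species}"


def divergence_vector(
    centroids: CentroidSet,
    from_species: str,
    to_species: str,
    diet_map: dict[str, str],
) -> DivergenceVector:
    """Vector from ``from_species``'s centroid to ``to_species``'s."""
    a = centroids.vector(from_species)
    b = centroids.vector(to_species)
    delta = b - a
    return DivergenceVector(
        from_species=from_species,
        to_species=to_species,
        from_diet=diet_map[from_species],
        to_diet=diet_map[to_species],
        delta=delta,
        length=float(np.linalg.norm(delta)),
    )


def _as_array(v) -> np.ndarray:
    if isinstance(v, DivergenceVector):
        return v.delta
    return np.asarray(v, dtype=float)


def angle_between(v1, v2) -> float:
    """Angle in degrees in [0, 180] between two vectors.

    The cosine is clamped to [-1, 1] before ``arccos`` to absorb
    floating-point drift. Zero-length input is an error.
    """
    a = _as_array(v1)
    b = _as_array(v2)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na <= ZERO_LENGTH_TOL or nb <= ZERO_LENGTH_TOL:
        raise UndefinedAngleError("angle undefined for zero-length vector")
    cos = float(np.dot(a, b) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def all_pair_vectors(
    centroids: CentroidSet,
    diet_map: dict[str, str],
    orientation_rule: str = "global-order",
) -> list[DivergenceVector]:
    """One divergence vector per unordered species pair (C(S, 2) total).

    Orientation under ``"global-order"``: a vector points from the species
    whose diet ranks lower under the fixed alphabetical diet order to the
    higher-ranked one, so vectors spanning the same two diets are
    co-oriented; within-same-diet pairs point from the lexicographically
    smaller species name to the larger.
    """
    if orientation_rule != "global-order":
        raise ValidationError(f"unknown orientation rule: {orientation_rule!r}")
    species = sorted(centroids.species)
    missing = [sp for sp in species if sp not in diet_map]
    if missing:
        raise ValidationError(f"species without diet assignment: {missing}")
    for sp in species:
        if diet_map[sp] not in DIET_CATEGORIES:
            raise ValidationError(f"unknown diet category: {diet_map[sp]!r}")
    out = []
    for sp1, sp2 in combinations(species, 2):
        d1, d2 = diet_map[sp1], diet_map[sp2]
        if (d1, sp1) <= (d2, sp2):
            frm, to = sp1, sp2
        else:
            frm, to = sp2, sp1
        out.append(divergence_vector(centroids, frm, to, diet_map))
    return out


@dataclass
class AngleNull:
    """Monte-Carlo sample of angles between random vector pairs."""

    angles: np.ndarray
    dim: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.angles.mean())

    @property
    def sd(self) -> float:
        return float(self.angles.std(ddof=1))


def random_angle_null(dim: int, n_draws: int, seed: int) -> AngleNull:
    """Null distribution of angles between independent random directions.

    Draws ``n_draws`` pairs of independent standard-normal vectors in
    ``dim`` dimensions and returns their pairwise angles. By symmetry the
    distribution is centered at 90 degrees and concentrates around it as
    ``dim`` grows.
    """
    if dim < 2:
        raise ValidationError("dim must be at least 2")
    if n_draws < 1:
        raise ValidationError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_draws, dim))
    y = rng.standard_normal((n_draws, dim))
    cos = np.einsum("ij,ij->i", x, y) / (
        np.linalg.norm(x, axis=1) * np.linalg.norm(y, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return AngleNull(angles=angles, dim=dim, seed=seed)
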