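"""Classification and enumeration of vector-pair comparisons.

A comparison pairs two species-pair divergence vectors. If both vectors
span the same two diet categories the comparison represents parallel host
trophic divergence; if they span different category combinations it is
nonparallel; pairs whose two member species share a diet are excluded
from the direction analysis. Phylogenetically constrained quartets
(A1, B1, A2, B2) separate ecology-driven from phylogeny-driven
parallelism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .errors import MissingSpeciesError, ValidationError
from .io import DIET_CATEGORIES
from .ordination import CentroidSet
from .trees import divergence_time_matrix
from .vectors import DivergenceVector, angle_between, divergence_vector

PARALLEL = "parallel_trophic"
NONPARALLEL = "nonparallel_trophic"
EXCLUDED = "excluded_same_diet"


def classify_comparison(
    diets_pair1: tuple[str, str], diets_pair2: tuple[str, str]
) -> str:
    """Category of a two-vector comparison from its unordered diet pairs.

    Either pair with two equal diets -> ``excluded_same_diet``; equal diet
    sets -> ``parallel_trophic``; otherwise ``nonparallel_trophic``.
    Symmetric in its arguments.
    """
    for pair in (diets_pair1, diets_pair2):
        for d in pair:
            if d not in DIET_CATEGORIES:
                raise ValidationError(f"unknown diet category: {d!r}")
    s1, s2 = frozenset(diets_pair1), frozenset(diets_pair2)
    if len(s1) == 1 or len(s2) == 1:
        return EXCLUDED
    return PARALLEL if s1 == s2 else NONPARALLEL


def _mean_time_all_pairs(species: frozenset[str], tmat: pd.DataFrame) -> float:
    sp = sorted(species)
    times = [tmat.loc[a, b] for a, b in combinations(sp, 2)]
    return float(np.mean(times))


def enumerate_comparisons(
    vectors: list[DivergenceVector],
    tree: dendropy.Tree,
    allow_shared_species: bool = False,
    time_definition: str = "all-pairs",
    orientation: str = "global-order",
) -> pd.DataFrame:
    """All unordered pairs of distinct vectors with category and angle.

    Each row carries the two vectors' endpoints and diets, the category
    from :func:`classify_comparison`, a ``shares_species`` flag, the angle
    (NaN when either vector has zero length; such exclusions are
    reported), and two divergence-time summaries: ``mean_divergence_time``
    (mean over all unordered pairs of the distinct species involved — six
    pairs when all four species are distinct) and
    ``mean_divergence_time_within`` (mean of the two within-vector times).
    ``time_definition`` selects which of the two fills
    ``mean_divergence_time``; both are always emitted.

    Comparisons whose vectors share a species are excluded unless
    ``allow_shared_species``. Under ``orientation="shared-diet"`` the
    angle of a comparison whose diet sets share exactly one category is
    computed with both vectors re-oriented to point away from the shared
    diet; ``"global-order"`` keeps the orientation the vectors were built
    with.
    """
    if time_definition not in ("all-pairs", "within-vector"):
        raise ValidationError(f"unknown time definition: {time_definition!r}")
    if orientation not in ("global-order", "shared-diet"):
        raise ValidationError(f"unknown orientation: {orientation!r}")
    tmat = divergence_time_matrix(tree)
    tree_species = set(tmat.index)
    needed = {sp for v in vectors for sp in (v.from_species, v.to_species)}
    missing = sorted(needed - tree_species)
    if missing:
        raise MissingSpeciesError(f"species missing from tree: {missing}")

    n_zero = sum(v.is_zero for v in vectors)
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-length vector(s); their comparisons carry no angle",
            stacklevel=2,
        )

    rows = []
    for v1, v2 in combinations(vectors, 2):
        shared = v1.species_pair & v2.species_pair
        if shared and not allow_shared_species:
            continue
        category = classify_comparison(v1.diet_pair, v2.diet_pair)
        a1, a2 = v1, v2
        if orientation == "shared-diet":
            common = v1.diets & v2.diets
            if len(common) == 1:
                (d,) = common
                if a1.from_diet != d and a1.to_diet == d:
                    a1 = a1.reversed()
                if a2.from_diet != d and a2.to_diet == d:
                    a2 = a2.reversed()
        angle = (
            np.nan
            if (v1.is_zero or v2.is_zero)
            else angle_between(a1.delta, a2.delta)
        )
        all_species = v1.species_pair | v2.species_pair
        t_all = _mean_time_all_pairs(all_species, tmat)
        t_within = float(
            (
                tmat.loc[v1.from_species, v1.to_species]
                + tmat.loc[v2.from_species, v2.to_species]
            )
            / 2.0
        )
        rows.append(
            {
                "v1_from": v1.from_species,
                "v1_to": v1.to_species,
                "v2_from": v2.from_species,
                "v2_to": v2.to_species,
                "v1_diets": "|".join(v1.diet_pair),
                "v2_diets": "|".join(v2.diet_pair),
                "category": category,
                "shares_species": bool(shared),
                "angle": angle,
                "mean_divergence_time": t_all if time_definition == "all-pairs" else t_within,
                "mean_divergence_time_all_pairs": t_all,
                "mean_divergence_time_within": t_within,
                "v1_length": v1.length,
                "v2_length": v2.length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "v1_from", "v1_to", "v2_from", "v2_to", "v1_diets", "v2_diets",
            "category", "shares_species", "angle", "mean_divergence_time",
            "mean_divergence_time_all_pairs", "mean_divergence_time_within",
            "v1_length", "v2_length",
        ],
    )


@dataclass(frozen=True)
class Quartet:
    """Four species, two per diet, with within-pair ecotypes closest kin.

    ``(a1, b1)`` and ``(a2, b2)`` are the two ecotype pairs; the a-species
    share diet ``diet_a`` and the b-species share ``diet_b``. The three
    derived comparisons are ecology (A1B1-A2B2), phylogeny (A1A2-B1B2),
    and cross (A1B2-A2B1).
    """

    a1: str
    b1: str
    a2: str
    b2: str
    diet_a: str
    diet_b: str
    angle_ecology: float
    angle_phylogeny: float
    angle_cross: float


def build_quartets(
    centroids: CentroidSet,
    diet_map: dict[str, str],
    tree: dendropy.Tree,
) -> pd.DataFrame:
    """Enumerate qualifying quartets and their three comparison angles.

    A quartet (A1, B1, A2, B2) requires diet(A1) = diet(A2) = a,
    diet(B1) = diet(B2) = b, a != b, all four species distinct, and the
    within-pair relatedness constraint
    ``max(t(A1,B1), t(A2,B2)) < min(t(A1,A2), t(A1,B2), t(B1,A2), t(B1,B2))``.
    Ecology vectors are oriented a -> b with a the alphabetically earlier
    diet; within-diet vectors are oriented pair 1 -> pair 2. All
    qualifying quartets are returned (overlapping species allowed across
    quartets); an empty result triggers a warning.
    """
    tmat = divergence_time_matrix(tree)
    species = [sp for sp in centroids.species if sp in diet_map]
    by_diet: dict[str, list[str]] = {}
    for sp in sorted(species):
        by_diet.setdefault(diet_map[sp], []).append(sp)

    rows = []
    diets = sorted(by_diet)
    for da, db in combinations(diets, 2):
        for A in combinations(by_diet[da], 2):
            for B in combinations(by_diet[db], 2):
                for pairing in ((0, 1), (1, 0)):
                    a1, a2 = A
                    b1, b2 = B[pairing[0]], B[pairing[1]]
                    t_within = max(tmat.loc[a1, b1], tmat.loc[a2, b2])
                    t_cross = min(
                        tmat.loc[a1, a2],
                        tmat.loc[b1, b2],
                        tmat.loc[a1, b2],
                        tmat.loc[a2, b1],
                    )
                    if not t_within < t_cross:
                        continue
                    vec = lambda f, t: divergence_vector(centroids, f, t, diet_map)
                    ecology = angle_between(vec(a1, b1).delta, vec(a2, b2).delta)
                    phylogeny = angle_between(vec(a1, a2).delta, vec(b1, b2).delta)
                    cross = angle_between(vec(a1, b2).delta, vec(a2, b1).delta)
                    rows.append(
                        {
                            "a1": a1, "b1": b1, "a2": a2, "b2": b2,
                            "diet_a": da, "diet_b": db,
                            "angle_ecology": ecology,
                            "angle_phylogeny": phylogeny,
                            "angle_cross": cross,
                        }
                    )
    if not rows:
        warnings.warn("no qualifying quartets found", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=[
            "a1", "b1", "a2", "b2", "diet_a", "diet_b",
            "angle_ecology", "angle_phylogeny", "angle_cross",
        ],
    )


def diet_contrast_groups(
    vectors: list[DivergenceVector], tree: dendropy.Tree
) -> pd.DataFrame:
    """Partition species-pair vectors into same-diet vs different-diet.

    Exhaustive and disjoint over all vectors; each row carries the vector
    length and the pairwise divergence time of its two species.
    """
    tmat = divergence_time_matrix(tree)
    rows = []
    for v in vectors:
        rows.append(
            {
                "from_species": v.from_species,
                "to_species": v.to_species,
                "from_diet": v.from_diet,
                "to_diet": v.to_diet,
                "group": "same_diet" if v.from_diet == v.to_diet else "different_diet",
                "length": v.length,
                "divergence_time": float(tmat.loc[v.from_species, v.to_species]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "from_species", "to_species", "from_diet", "to_diet",
            "group", "length", "divergence_time",
        ],
    )
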