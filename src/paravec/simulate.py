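"""Synthetic host trees, diets, metadata, and count tables.

The generator produces data with known parallel/nonparallel structure so
the downstream vector analysis can be validated end to end. The model is
deliberately minimal: per-feature latent log-abundances evolve by Brownian
motion along the host tree, diet adds a fixed effect to a small
diet-responsive feature subset, individuals add Gaussian noise, and counts
are drawn by softmax + (Dirichlet-)multinomial sampling at a configured
sequencing depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import DIET_CATEGORIES, DIET_COLUMNS, METADATA_COLUMNS, diet_column


@dataclass
class SimulationParams:
    """Parameters of the community simulator.

    Parameters
    ----------
    n_features
        Number of features (ASV-like taxa or pathways).
    individuals_per_species
        Either a fixed integer or an inclusive ``(low, high)`` range from
        which the per-species sample size is drawn uniformly.
    depth
        Sequencing depth (total counts) per sample.
    sigma_phylo
        Brownian-motion rate of the latent log-abundance along the tree:
        the increment along an edge of length ``t`` myr has standard
        deviation ``sigma_phylo * sqrt(t)``.
    diet_effect
        Effect added to the latent log-abundance of each feature in the
        diet-responsive set of the species' assigned diet category.
    sigma_individual
        Standard deviation of per-individual, per-feature latent noise.
    overdispersion
        Dirichlet-multinomial concentration; ``None`` or ``inf`` gives
        plain multinomial sampling.
    responsive_fraction
        Fraction of features assigned to each diet category's responsive
        set; sets are disjoint across categories.
    seed
        Global seed; expanded into independent substreams for tree traits,
        individual noise, and count draws.
    """

    n_features: int = 200
    individuals_per_species: int | tuple[int, int] = (3, 20)
    depth: int = 5000
    sigma_phylo: float = 0.1
    diet_effect: float = 1.0
    sigma_individual: float = 0.5
    overdispersion: float | None = None
    responsive_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 2:
            raise ValidationError("n_features must be at least 2")
        if self.depth < 1:
            raise ValidationError("depth must be at least 1")
        for name in ("sigma_phylo", "diet_effect", "sigma_individual"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.overdispersion is not None and not math.isinf(self.overdispersion):
            if self.overdispersion <= 0:
                raise ValidationError("overdispersion must be positive or None")
        if not 0 < self.responsive_fraction <= 1 / len(DIET_CATEGORIES):
            raise ValidationError(
                "responsive_fraction must be in (0, 1/6] so per-diet sets can "
                "stay disjoint"
            )


def simulate_tree(n_species: int, depth_myr: float, seed: int) -> dendropy.Tree:
    """Simulate a pure-birth ultrametric tree with ``n_species`` tips.

    The topology is a Yule (birth-death with zero death) tree; edge lengths
    are rescaled so every root-to-tip distance equals ``depth_myr``. Tips
    are labelled ``sp01 .. spNN`` in Newick traversal order. Deterministic
    given ``seed``.
    """
    if n_species < 2:
        raise ValidationError("n_species must be at least 2")
    if depth_myr <= 0:
        raise ValidationError("depth_myr must be positive")
    rng = np.random.default_rng(seed)

    # Forward Yule process (rate 1): start with the root split, wait
    # Exp(k) between events, split a uniformly chosen lineage, and after
    # the (n-1)th split extend all pending branches by one more
    # exponential waiting time so no tip ends exactly at a speciation.
    next_id = iter(range(10**9))
    root = {"id": next(next_id), "time": 0.0, "children": []}
    active = []
    for _ in range(2):
        child = {"id": next(next_id), "time": None, "children": [], "parent": root}
        root["children"].append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node["time"] = t
        for _ in range(2):
            child = {"id": next(next_id), "time": None, "children": [], "parent": node}
            node["children"].append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_species)
    for node in active:
        node["time"] = t_end

    scale = depth_myr / t_end
    width = max(2, len(str(n_species)))
    label_counter = iter(range(1, n_species + 1))

    def newick(node, parent_time: float) -> str:
        length = (node["time"] - parent_time) * scale
        if not node["children"]:
            return f"sp{next(label_counter):0{width}d}:{length:.10f}"
        inner = ",".join(newick(c, node["time"]) for c in node["children"])
        return f"({inner}):{length:.10f}"

    inner = ",".join(newick(c, 0.0) for c in root["children"])
    tree = dendropy.Tree.get(data=f"({inner});", schema="newick")
    return tree


def assign_diets(
    tree: dendropy.Tree, categories: tuple[str, ...] = ("meat-fish", "plants")
) -> dict[str, str]:
    """Assign diet categories round-robin over tips sorted by label.

    With the default two categories and a tree whose cherries pair adjacent
    labels this yields many mixed-diet clades, which is the structure the
    quartet analysis expects.
    """
    for c in categories:
        if c not in DIET_CATEGORIES:
            raise ValidationError(f"unknown diet category: {c!r}")
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    return {sp: categories[i % len(categories)] for i, sp in enumerate(labels)}


def _responsive_sets(
    n_features: int, categories: list[str], fraction: float
) -> dict[str, np.ndarray]:
    """Disjoint per-category blocks of feature indices, deterministic."""
    per = max(1, int(round(fraction * n_features)))
    sets = {}
    for k, cat in enumerate(sorted(categories)):
        idx = np.arange(k * per, (k + 1) * per)
        if idx[-1] >= n_features:
            raise ValidationError("not enough features for disjoint responsive sets")
        sets[cat] = idx
    return sets


def simulate_dataset(
    tree: dendropy.Tree,
    diet_assignment: dict[str, str],
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a count table and metadata for hosts on ``tree``.

    Per species: latent log-abundance = feature baseline + Brownian
    deviation along the tree + diet effect on the responsive set of its
    assigned category. Per individual: Gaussian noise, softmax to
    proportions, counts at the configured depth.

    Returns
    -------
    (table, metadata)
        ``table`` is features x samples (integer counts); ``metadata``
        follows :data:`paravec.io.METADATA_COLUMNS`.
    """
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = [sp for sp in tips if sp not in diet_assignment]
    if missing:
        raise ValidationError(f"tips without diet assignment: {missing}")
    for sp, cat in diet_assignment.items():
        if cat not in DIET_CATEGORIES:
            raise ValidationError(f"unknown diet category: {cat!r}")

    ss = np.random.SeedSequence(params.seed)
    rng_traits, rng_ind, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))

    p = params
    baseline = rng_traits.normal(0.0, 1.0, p.n_features)

    # Brownian motion on the log scale along the tree, one value per feature.
    latent: dict[str, np.ndarray] = {}
    node_state: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = baseline.copy()
        else:
            t = node.edge.length or 0.0
            state = node_state[id(node.parent_node)] + rng_traits.normal(
                0.0, p.sigma_phylo * math.sqrt(t), p.n_features
            )
        node_state[id(node)] = state
        if node.is_leaf():
            latent[node.taxon.label] = state
    # rng_traits draws above follow dendropy's preorder, which is
    # deterministic for a given tree; tips below are processed sorted.

    categories = sorted(set(diet_assignment.values()))
    responsive = _responsive_sets(p.n_features, categories, p.responsive_fraction)

    if isinstance(p.individuals_per_species, int):
        n_ind = {sp: p.individuals_per_species for sp in tips}
    else:
        lo, hi = p.individuals_per_species
        if not 1 <= lo <= hi:
            raise ValidationError("individuals_per_species range must satisfy 1 <= lo <= hi")
        n_ind = {sp: int(rng_ind.integers(lo, hi + 1)) for sp in tips}

    plain_multinomial = p.overdispersion is None or math.isinf(p.overdispersion)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for sp in tips:
        mu = latent[sp].copy()
        cat = diet_assignment[sp]
        mu[responsive[cat]] += p.diet_effect
        for i in range(1, n_ind[sp] + 1):
            z = mu + rng_ind.normal(0.0, p.sigma_individual, p.n_features)
            z -= z.max()
            props = np.exp(z)
            props /= props.sum()
            if plain_multinomial:
                counts = rng_counts.multinomial(p.depth, props)
            else:
                alpha = props * p.overdispersion
                counts = rng_counts.multinomial(p.depth, rng_counts.dirichlet(alpha))
            sample_id = f"{sp}.s{i:02d}"
            columns[sample_id] = counts
            row = {
                "sample_id": sample_id,
                "individual_id": f"{sp}_ind{i:02d}",
                "species": sp,
                "age_category": "adult",
                "health": "healthy",
                "captive_wild": "wild",
                "seq_count": int(counts.sum()),
            }
            for col in DIET_COLUMNS:
                row[col] = 0.0
            row[diet_column(cat)] = 1.0
            meta_rows.append(row)

    feature_ids = [f"f{j:04d}" for j in range(p.n_features)]
    table = pd.DataFrame(columns, index=feature_ids)
    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    return table, metadata


#: Hand-enumerated expectation for :func:`make_filter_fixture` under the
#: default FilterConfig (min 1000 reads, 3-20 individuals, subsample seed
#: from the config). For ``sp_big`` the retained set is seed-dependent by
#: design, so the expectation pins its size and candidate pool instead.
FILTER_FIXTURE_EXPECTED: dict = {
    "surviving_samples_fixed": [
        # sp_edge: e01 has 999 reads (dropped); e02 sits exactly on the
        # 1000-read boundary (kept); exactly 3 individuals remain.
        "sp_edge.e02",
        "sp_edge.e03",
        "sp_edge.e04",
        # sp_nonspec passes every sample-level rule (its 0.69 max diet
        # fraction only matters for the specialist step).
        "sp_nonspec.n01",
        "sp_nonspec.n02",
        "sp_nonspec.n03",
        # sp_ok: o01 kept over its duplicate o01x (lexicographic first);
        # o02 is juvenile and o03 diseased (dropped); o06 has no
        # individual ID (dropped).
        "sp_ok.o01",
        "sp_ok.o04",
        "sp_ok.o05",
    ],
    "sp_big_candidates": [f"sp_big.b{i:02d}" for i in range(1, 26)],
    "sp_big_retained": 20,
    "dropped_samples": {
        "sp_ok.o01x": "duplicate individual",
        "sp_ok.o02": "age category",
        "sp_ok.o03": "health status",
        "sp_ok.o06": "missing individual ID",
        "sp_edge.e01": "below 1000 reads",
        "sp_small.m01": "species below 3 individuals",
        "sp_small.m02": "species below 3 individuals",
    },
    # specialist map over the species that survive the sample filters
    "specialists": {"sp_ok": "fruits", "sp_edge": "plants", "sp_big": "invertebrates"},
    "non_specialists": ["sp_nonspec"],
}


def make_filter_fixture(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic small dataset exercising every filter rule.

    Contains, by construction: a sample with 999 reads, a duplicate
    individual, a juvenile, a diseased individual, a sample without an
    individual ID, a species with 2 individuals, a species with 25
    individuals, and a species whose maximum diet fraction is 0.69. The
    expected survivors are documented in :data:`FILTER_FIXTURE_EXPECTED`.
    """
    rows: list[dict] = []

    def add(sample_id, individual_id, species, diet_cat, diet_frac, *,
            age="adult", health="healthy", seq_count=5000):
        row = {
            "sample_id": sample_id,
            "individual_id": individual_id,
            "species": species,
            "age_category": age,
            "health": health,
            "captive_wild": "wild",
            "seq_count": seq_count,
        }
        for col in DIET_COLUMNS:
            row[col] = 0.0
        row[diet_column(diet_cat)] = diet_frac
        if diet_frac < 1.0:
            # put the remainder on another category so fractions sum to 1
            other = "seeds" if diet_cat != "seeds" else "plants"
            row[diet_column(other)] = round(1.0 - diet_frac, 10)
        rows.append(row)

    # sp_ok (fruits specialist): 6 samples, 3 survive
    add("sp_ok.o01", "sp_ok_ind01", "sp_ok", "fruits", 1.0)
    add("sp_ok.o01x", "sp_ok_ind01", "sp_ok", "fruits", 1.0)  # duplicate individual
    add("sp_ok.o02", "sp_ok_ind02", "sp_ok", "fruits", 1.0, age="juvenile")
    add("sp_ok.o03", "sp_ok_ind03", "sp_ok", "fruits", 1.0, health="diseased")
    add("sp_ok.o04", "sp_ok_ind04", "sp_ok", "fruits", 1.0)
    add("sp_ok.o05", "sp_ok_ind05", "sp_ok", "fruits", 1.0)
    add("sp_ok.o06", "", "sp_ok", "fruits", 1.0)  # no individual ID

    # sp_edge (plants specialist at exactly 0.70): read-count boundary,
    # ends with exactly 3 individuals
    add("sp_edge.e01", "sp_edge_ind01", "sp_edge", "plants", 0.70, seq_count=999)
    add("sp_edge.e02", "sp_edge_ind02", "sp_edge", "plants", 0.70, seq_count=1000)
    add("sp_edge.e03", "sp_edge_ind03", "sp_edge", "plants", 0.70)
    add("sp_edge.e04", "sp_edge_ind04", "sp_edge", "plants", 0.70)

    # sp_small (meat-fish): only 2 individuals, dropped at the species rule
    add("sp_small.m01", "sp_small_ind01", "sp_small", "meat-fish", 1.0)
    add("sp_small.m02", "sp_small_ind02", "sp_small", "meat-fish", 1.0)

    # sp_big (invertebrates): 25 individuals, subsampled to 20
    for i in range(1, 26):
        add(f"sp_big.b{i:02d}", f"sp_big_ind{i:02d}", "sp_big", "invertebrates", 0.80)

    # sp_nonspec: passes sample filters but max diet fraction 0.69
    add("sp_nonspec.n01", "sp_nonspec_ind01", "sp_nonspec", "plants", 0.69)
    add("sp_nonspec.n02", "sp_nonspec_ind02", "sp_nonspec", "plants", 0.69)
    add("sp_nonspec.n03", "sp_nonspec_ind03", "sp_nonspec", "plants", 0.69)

    metadata = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))

    # Small deterministic count table whose column sums equal seq_count.
    rng = np.random.default_rng(seed)
    n_features = 5
    feature_ids = [f"f{j:02d}" for j in range(n_features)]
    cols = {}
    for _, row in metadata.iterrows():
        props = rng.dirichlet(np.ones(n_features) * 2.0)
        cols[row["sample_id"]] = rng.multinomial(int(row["seq_count"]), props)
    table = pd.DataFrame(cols, index=feature_ids)
    return table, metadata
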