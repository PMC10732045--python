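"""Ultrametric host trees and divergence times.

Divergence time between two host species is the depth of their most recent
common ancestor on an ultrametric tree (equivalently half the patristic
path length between the two tips), in millions of years.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd

from .errors import MissingSpeciesError, ValidationError

#: Relative tolerance (times tree depth) for the ultrametricity check.
ULTRAMETRIC_RTOL = 1e-6


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip distance for every tip, keyed by taxon label."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    depths = np.array(list(tip_depths(tree).values()))
    depth = depths.max()
    return bool(np.all(np.abs(depths - depth) <= rtol * depth))


def divergence_time_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """All pairwise divergence times (MRCA depths from the tip side), as a
    symmetric labels x labels DataFrame with a zero diagonal.

    On an ultrametric tree this equals half the patristic distance. For a
    tree that is non-ultrametric beyond tolerance a warning is issued and
    the time for (sp1, sp2) is the MRCA depth measured below sp1, then
    symmetrized by the (sp1, sp2) label order of the returned frame.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    root_dist = {id(lf): lf.root_distance for lf in leaves}
    ultra = is_ultrametric(tree)
    if not ultra:
        warnings.warn(
            "tree is not ultrametric within tolerance; divergence times are "
            "taken as the MRCA depth below the first species of each pair",
            stacklevel=2,
        )
    pdm = tree.phylogenetic_distance_matrix()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if ultra:
                t = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon) / 2.0
            else:
                mrca = pdm.mrca(leaves[i].taxon, leaves[j].taxon)
                t = root_dist[id(leaves[i])] - mrca.root_distance
            out[i, j] = out[j, i] = t
    return pd.DataFrame(out, index=labels, columns=labels)


def divergence_time(tree: dendropy.Tree, sp1: str, sp2: str) -> float:
    """Divergence time in myr between two tips; 0 iff sp1 == sp2."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for sp in (sp1, sp2):
        if sp not in labels:
            raise MissingSpeciesError(f"species {sp!r} is not a tip of the tree")
    if sp1 == sp2:
        return 0.0
    mat = divergence_time_matrix(tree)
    return float(mat.loc[sp1, sp2])


def validate_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> None:
    if not is_ultrametric(tree, rtol=rtol):
        raise ValidationError("tree is not ultrametric within tolerance")
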