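import numpy as np
import pytest

import paravec as pv


@pytest.fixture(scope="session")
def study():
    """A small three-diet simulated study shared across test modules.

    Three diet categories guarantee that parallel, nonparallel, and
    same-diet-excluded comparison categories are all populated.
    """
    tree = pv.simulate_tree(12, 80, seed=42)
    diet_map = pv.assign_diets(tree, ("fruits", "meat-fish", "plants"))
    params = pv.SimulationParams(
        individuals_per_species=6, n_features=120, diet_effect=2.0, seed=42
    )
    table, metadata = pv.simulate_dataset(tree, diet_map, params)
    ordination = pv.retain_axes(pv.pcoa(pv.bray_curtis(table)))
    centroids = pv.species_centroids(ordination, metadata)
    vectors = pv.all_pair_vectors(centroids, diet_map)
    return {
        "tree": tree,
        "diet_map": diet_map,
        "table": table,
        "metadata": metadata,
        "ordination": ordination,
        "centroids": centroids,
        "vectors": vectors,
    }


@pytest.fixture()
def filter_fixture():
    table, metadata = pv.make_filter_fixture(seed=0)
    return table, metadata


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
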