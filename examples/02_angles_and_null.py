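"""Quantify (non)parallelism: divergence-vector angles vs the random null.

Simulates two diet-specialist guilds (meat-fish vs plants) across 16 host
species with a strong diet effect, builds species-pair divergence vectors
in retained PCoA space, and compares the parallel-category angle
distribution with the Monte-Carlo null for random directions. Angles
below 90 degrees indicate parallel community shifts.
"""

import paravec as pv

tree = pv.simulate_tree(n_species=16, depth_myr=80, seed=7)
diet_map = pv.assign_diets(tree)  # alternating meat-fish / plants
params = pv.SimulationParams(individuals_per_species=10, diet_effect=3.0,
                             sigma_phylo=0.0, seed=7)
table, metadata = pv.simulate_dataset(tree, diet_map, params)

ordination = pv.retain_axes(pv.pcoa(pv.bray_curtis(table)))
centroids = pv.species_centroids(ordination, metadata)
vectors = pv.all_pair_vectors(centroids, diet_map)
comparisons = pv.enumerate_comparisons(vectors, tree)

parallel = comparisons.loc[comparisons.category == "parallel_trophic", "angle"]
null = pv.random_angle_null(dim=ordination.n_axes, n_draws=100_000, seed=7)

print(f"retained PCoA axes: {ordination.n_axes}")
print(f"parallel-category comparisons: {len(parallel)}")
print(f"mean angle, parallel host trophic divergence: {parallel.mean():.2f} deg")
print(f"mean angle, random-direction null ({null.dim}-D): {null.mean:.2f} deg")
print(f"null standard deviation: {null.sd:.2f} deg")
# A parallel-category mean well below the ~90 deg null mean shows that
# pairs spanning the same two diets shift their communities in a shared
# direction; with diet_effect=0 the mean returns to the null.
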