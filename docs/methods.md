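# Methods

## The measurement

`paravec` treats each host species as a point — the arithmetic mean
(centroid) of its samples' coordinates in PCoA space — and each ordered
species pair as a vector between centroids. Direction of community
change is the angle between two such vectors,
θ = arccos(clamp(⟨v₁,v₂⟩/(‖v₁‖‖v₂‖), −1, 1))·180/π, in [0°, 180°];
magnitude is the Euclidean length. The cosine clamp absorbs
floating-point drift; vectors of length ≤ 1e−12 are excluded from angle
analyses (and kept in length analyses) with a logged warning.

Angles are only meaningful under a shared orientation rule. The default
(`global-order`) points every vector from the species whose diet ranks
lower in the fixed alphabetical order of the six diet categories
(fruits, invertebrates, meat-endotherms, meat-fish, plants, seeds) to
the higher-ranked one, so vectors spanning the same two diets are
co-oriented; within-same-diet vectors point from the lexicographically
smaller species name. An alternative (`shared-diet`) re-orients a
comparison's two vectors away from their single shared diet category
when exactly one is shared; it changes only those comparisons' angles.

## Ordination

Dissimilarity is Bray-Curtis,
d(a,b) = 1 − 2·Σ_f min(x_af, x_bf)/(Σ_f x_af + Σ_f x_bf), computed with
scipy on raw counts (no rarefaction or transform; Bray-Curtis on counts
is what the sequencing-depth filter protects). PCoA is the
eigendecomposition of the Gower-centered matrix −½d²; coordinates are
eigenvectors scaled by √λ. Bray-Curtis is non-Euclidean, so negative
eigenvalues occur: the policy is to discard non-positive axes and
report proportions of variation over the sum of positive eigenvalues —
no Cailliez/Lingoes correction — matching the dominant behaviour of
standard PCoA implementations. Axes with proportion strictly greater
than 0.1% are retained. Eigenvalue ties keep their original order
(stable sort); each axis' sign is canonicalized so its
largest-magnitude loading is positive, which fixes the otherwise
arbitrary eigenvector sign for bitwise reproducibility. Eigenvalues
below 1e−12 of the largest are treated as numerically zero.

## Filters

Rules run in a fixed order (each recorded in a `FilterReport` that
accounts for every input sample exactly once): drop samples without an
individual ID; keep one sample per individual — the lexicographically
first sample ID, a deterministic and auditable stand-in for an
unspecified choice; keep health statuses in {healthy, unknown/blank};
keep age categories in {adult, after hatch year, unknown}; drop samples
below 1,000 sequences; drop species with fewer than 3 remaining
individuals; subsample species above 20 individuals uniformly at random
under a recorded seed. A species is a diet specialist when its maximum
diet-category fraction is ≥ 0.70 (inclusive threshold); fractions must
agree across a species' samples to 1e−6 — disagreement is an error, not
an average. Filtering is idempotent and deterministic given the seed.

## Divergence times

Host divergence time between two species is the depth of their MRCA on
an ultrametric tree (half the patristic distance), in myr.
Ultrametricity is checked to a relative tolerance of 1e−6 of tree
depth; a non-ultrametric tree triggers a warning and times fall back to
the MRCA depth measured below the first species of the pair. For a
two-vector comparison, "mean divergence time" is the mean over all
unordered pairs of the distinct species involved (six pairs when all
four are distinct); the alternative — the mean of the two within-vector
times — is always emitted alongside and selectable by config.

## Comparison design

All C(S,2) species-pair vectors are built; all unordered pairs of
distinct vectors are enumerated. Comparisons whose vectors share a
species are excluded by default (their endpoints are not independent);
a flag restores them. Classification is by diet multisets: either pair
with two equal diets → excluded; equal unordered diet pairs → parallel
trophic divergence; otherwise nonparallel. Quartets (A₁,B₁,A₂,B₂)
require two species per each of two diets, all distinct, and
max(t(A₁,B₁), t(A₂,B₂)) < min of the four cross times — i.e. each
ecotype pair's members are each other's closest relatives within the
quartet. All qualifying quartets are enumerated (overlap across
quartets is allowed and visible in the output, so downstream users can
subsample to independence); ecology vectors are oriented a→b with a the
alphabetically earlier diet, and within-diet vectors pair-1→pair-2 so
the phylogeny comparison is well-defined.

## Statistics

Two-sample location: Welch's t by default (pooled variance by flag) and
the Wilcoxon rank-sum test — exact when the combined sample is ≤ 50
without ties, otherwise a normal approximation with continuity
correction. k groups: Kruskal-Wallis with tie correction, pairwise
rank-sum post hocs under Holm adjustment (bonferroni/none selectable),
and an insert-absorb compact-letter display at α = 0.05. Rather than
silently switching tests on a normality gate, the report emits the
Shapiro-Wilk gate and both parametric and nonparametric results, so the
choice is explicit.

Shapiro-Wilk is implemented in-package as a direct transcription of
Royston's AS R94 approximation with full double-precision normal
quantiles. This is a deliberate numerical choice: the widely used
translation of the original routine carries a lower-precision internal
normal-quantile approximation, and the transcription here agrees with
R's `shapiro.test` to ~1e−13 relative in p. Samples above n = 5000 (the
approximation's validity limit) are subsampled with a recorded seed.

Trends of angles/lengths against divergence time are fit two ways:
ordinary least squares (slope p, R²) and a cubic B-spline GAM (basis
dimension 10, reduced for few unique x) whose penalty weight is chosen
by generalized cross-validation over a fixed logarithmic grid,
GCV(α) = n·RSS/(n − edf)²; the smooth reports the joint Wald p of the
spline coefficients and deviance explained (with an effective-df
adjusted variant alongside, since "R²" for a GAM is ambiguous). Both
fits are returned so the caller can mirror the usual
"report the model explaining more variance" choice. Degenerate inputs:
constant y returns flat fits with zero variance explained; fewer than 4
unique x values skips the smooth with a warning.

## The synthetic-data generator

The generator is the package's test bed, emulating the statistical
structure the analysis assumes rather than 16S realism. Host trees are
pure-birth (Yule) topologies rescaled to a chosen depth in myr, with an
extra exponential waiting time after the last split so no tip ends
exactly at a speciation event. Per-feature latent log-abundances start
from a N(0,1) baseline and evolve by Brownian motion along the tree
(increment sd = `sigma_phylo`·√t per branch of length t myr — log-scale
BM keeps proportions positive and phylogenetic signal multiplicative);
each diet category owns a disjoint block of responsive features
(fraction `responsive_fraction` = 0.05 per category) shifted by
`diet_effect`; individuals add N(0, `sigma_individual`) noise; softmax
converts to proportions and counts are multinomial at the configured
depth (Dirichlet-multinomial when a finite `overdispersion` is set). A
single seed expands into separate substreams for traits, individuals,
and counts, so stages are independently reproducible.

Defaults — 200 features, 3–20 individuals per species, depth 5000,
`sigma_phylo` 0.1, `diet_effect` 1.0, `sigma_individual` 0.5, plain
multinomial — are chosen for testability: the diet effect is comfortably
detectable against individual noise at these sample sizes without
saturating the angle scale. What the generator does *not* emulate:
sequencing error profiles, chimeras, compositional zero-inflation
beyond multinomial sampling, within-species diet variation, or
strain-level dynamics. Passing tests therefore demonstrate that the
measurement machinery recovers known structure, not that real gut data
contain such structure.

A property worth knowing when interpreting nulls: with phylogenetic
structuring on (`sigma_phylo` > 0) and no diet effect, the
parallel-category mean angle sits systematically *above* 90° (≈94° at
the defaults) — Brownian covariance among centroid differences makes
non-overlapping vectors slightly anti-correlated under the diet-based
orientation rule. The parameter-recovery experiments therefore switch
phylogenetic structuring off (`sigma_phylo` = 0) so the manipulated
diet effect is the only deterministic signal and the zero-effect mean
is the ≈90° random-direction null. The upward bias under phylogenetic
structure is real and mirrors the observation that host-group structure
belongs in the null hypothesis for parallelism studies.

## Problem sizes

The test suite and examples run at deliberately modest scale — 8–16
species, 5–10 individuals each, 80–200 features, 10⁵ Monte-Carlo draws
for the angle null, 20 replicate seeds for the directional
parameter-recovery experiment — sizes at which every quantity checked
is stable to well within its asserted tolerance.

## Known limitations

- Feature-table ingestion is TSV-only; BIOM containers must be exported
  to TSV upstream.
- No phylogenetic comparative correction (e.g. PGLS) is applied to the
  angle/length regressions; divergence-time trends are descriptive.
- UniFrac and other phylogeny-aware community metrics are out of scope;
  the pipeline is Bray-Curtis throughout.
- Quartet enumeration returns all qualifying quartets; their angle
  samples overlap in species and are not independent draws.
- The specialist rule assumes species-level diet fractions; per-sample
  diet variation is rejected rather than modelled.
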