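# Methods

## Model and procedure

The scan treats a rooted, branch-length-bearing bacterial strain phylogeny as
the object of inference and asks, clade by clade, whether within-clade
diversification tracks host phylogeny or geography. The unit of testing is an
internal node in the *distal window*: the set of nodes whose clade diameter
(maximum within-clade tip-to-tip patristic distance) is at most
`max_diameter_fraction` (default 0.1, inclusive — "10% or less") of the
tree-wide maximum. The window restricts testing to shallow clades whose
diversification is plausibly contemporaneous with the host radiation; nested
qualifying nodes are all tested, and overlap is resolved only when branch
lengths are aggregated.

For a clade with tips 1..n, three n×n matrices are formed: the strain
patristic distances **D**, host distances **H** (patristic distance between
the strains' host taxa on the species/subspecies host tree, hence exactly 0
for conspecific strains), and geographic distances **G** (haversine
great-circle distance between sampling sites, Earth radius 6371.0 km, exactly
0 for a shared site — sites, not noisy coordinates, are the unit of
geography). The Mantel statistic is the Pearson correlation over
strictly-upper-triangle entries. Significance is assessed one-tailed
(greater, since both hypotheses predict positive association) by jointly
permuting rows and columns of the reference matrix: with N permutations
(default 1000) and k permuted statistics ≥ the observed one,
p = (1 + k)/(1 + N). Ties count toward k (conservative), and the +1 terms
prevent p = 0. Benjamini–Hochberg correction is applied separately to the
host-phylogeny family and the geography family, each across all tested
nodes; clades with fewer than 2 distinct host taxa (or sites), or a
zero-variance reference triangle, are untestable on that axis and are
excluded from that family rather than assigned p = 1 — they carry no
evidence either way.

Classification uses r > 0.7 with BH-adjusted p < 0.05 per axis;
Δ = r_phylo − r_geo with |Δ| > 0.5 and a non-significant opposite axis
upgrades an associated clade to "independent" of the other driver. Branch
length per class is the sum over the union of edges inside clades of that
class (each edge once), divided by the tree's total branch length. The edge
subtending a clade's root is counted as part of the clade
(`include_subtending_edge`, default on): that edge is diversification history
unique to the clade. Both conventions are toggleable.

The sympatry fidelity test operationalises "more closely related" as minimum
patristic distance (the distance-matrix analog of sister-strain
relationships; a mean-distance variant is available). For each strain whose
site hosts clade members of both host genera, A = min distance to a
same-genus strain at a different site, B = min distance to a different-genus
strain at the same site; the strain is host-faithful iff A < B, with ties
flagged and counted as not faithful. A clade is `host_faithful` only if every
evaluated strain is (unanimity, matching an all-or-nothing claim like 17/17;
a majority-rule option exists), `geography_faithful` if none is, and
`not_applicable` when no strain has both comparator sets non-empty.

Taxon-level aggregation weights each tested node by its clade branch length;
nested nodes both contribute (no de-overlap rule is imposed; a union-weight
alternative can be computed from the same report). A clade is assigned to a
phylum/genus only when all its tips agree at that rank. Between-phylum
comparisons of per-genus values use a Welch-type t-test on weighted means
with reliability weights: n_eff = (Σw)²/Σw², unbiased weighted variance,
Satterthwaite degrees of freedom on the effective sizes; with equal weights
this is exactly the ordinary Welch test, and it is invariant to rescaling
all weights. Genus weights are the total branch length of the minimal
spanning subtree of the genus's tips (each edge once, stem excluded).
Pairwise tests run over all unordered pairs of phyla with ≥ 5 genera and are
Holm-adjusted.

Sign tests are exact binomial tails against 1/2. The default is the
one-sided upper tail (the direction is predicted a priori): 12 successes in
15 trials gives 0.0176. For 99/156 the one-sided tail is 0.00048 and the
two-sided tail 0.00097; only the latter rounds to 0.001 at three decimals,
so the genus-level headline value is computed two-sided
(`alternative="two-sided"`). Both options are exposed.

The phylogenetic ANOVA compares the observed one-way ANOVA F for a trait on
a taxon tree against F values from Brownian-motion simulations of the trait
along the tree (default 1000), with p = (1 + #{F_sim ≥ F_obs})/(1 + n_sim).
The BM rate is the maximum-likelihood estimate from the observed trait via
the GLS mean and tree covariance; F is scale-invariant, so the rate does not
affect p, but the simulation is faithful to the fitted model. On a star tree
BM reduces to i.i.d. normals and the simulation p converges to the
parametric F-distribution p — the test suite checks this reduction. When no
independent genus-level phylogeny is supplied, the taxon tree is the strain
tree pruned to one (lexicographically first) representative tip per genus.

## Randomness and determinism

One master seed governs a run. Per-node permutation streams are derived from
a stable SHA-256 hash of the node identifier (itself a hash of the sorted
tip-label set) and the test family, so results are independent of node
iteration order and of file layout; identical inputs and seed reproduce
output TSVs byte-identically. Floats are written at 10 significant digits.

## Synthetic data: what it emulates

The generator mirrors the sampling design the method is built for: a
six-taxon host clade in two genera (four *Pan*-like taxa — three subspecies
plus a bonobo analog — on shallow branches; two *Gorilla*-like species), with
a deep between-genus divergence (tip-to-tip diameter 6.0 in arbitrary units),
and 17 sampling sites with realistic equatorial-African coordinates. Ranges:
4 far-western sites for one chimp-like taxon, 3 central and 3 eastern sites
for the others, 7 sites for the bonobo analog, and each gorilla-like species
confined to a single site shared with a chimp-like taxon — giving two
sympatric heterogeneric sites and, crucially, host phylogenetic distance
largely decoupled from geographic distance (close relatives live far apart;
distant relatives share sites).

Per-clade regimes:

- **codiv**: the clade is a copy of the host tree (normalised to diameter 1)
  with each host tip replaced by a fan of `strains_per_host_taxon` (default
  3) strains on branches |N(0, σ)|, σ = `within_taxon_noise_sd` (default
  0.05, i.e. 5% of the clade diameter); sites are drawn uniformly from the
  taxon's range. At σ = 0 with one strain per taxon the strain and expanded
  host matrices are exactly proportional, so r_phylo = 1.
- **geo**: an ultrametric site tree is built by average-linkage agglomeration
  of the haversine site distances perturbed elementwise by
  N(0, `geo_tree_noise_sd`) (default 50 km, against between-site distances of
  hundreds to thousands of km); patristic distance between site tips equals
  their cophenetic distance. Strains attach to site tips; host taxa are
  drawn from the site's occupants, and each sympatric site is seeded with
  one strain from each genus, so heterogeneric hosts share nearby strains.
- **random**: a random-join topology with exponential branch lengths
  (normalised to diameter 1) and uniform host/site assignment within ranges;
  the null for calibration.

Clades (default 20 per regime) hang from a star backbone with edges of
`backbone_scale` = 25 diameter units; since the assembled tree diameter then
exceeds 50, every simulated clade (diameter ≈ 1) sits inside the distal
tenth and no backbone node qualifies. Assembly verifies this and raises,
naming the offending clade, if the configuration violates it.

What the generator does *not* emulate: finite-sequence phylogenetic
estimation error (trees are exact, not inferred from alignments),
topological discordance within clades (noise perturbs branch lengths, not
topology, for reproducibility — an NNI-style topology-noise option would sit
on top of the same machinery), incomplete lineage sorting, host switching at
rates between the pure regimes, unequal strain counts per clade, and the
heavy-tailed clade-size and taxon-composition distributions of real MAG
collections. Passing regime-recovery tests therefore demonstrates that the
statistical machinery identifies the generative signal it targets under
clean conditions with realistic design geometry — not that real datasets,
with their estimation noise and intermediate regimes, will separate this
cleanly.

## Problem sizes and numerical choices

The reference design (3 regimes × 20 clades × 18 tips = 1080 tips, ~280
tested nodes, 1000 permutations per node and axis) runs in seconds; the
null-calibration study uses 500 independent neutral clades at 999
permutations, and Mantel-vs-enumeration checks use clades of ≤ 7 tips where
all n! relabelings are enumerable. Zero-variance triangles return an
undefined correlation (NaN) rather than raising; permuted statistics are
compared to the observed one with a 1e-12 tolerance so floating-point jitter
cannot flip tie counting; diameters are compared to the distal cutoff with a
relative 1e-12 tolerance so an exact-equality clade is included on either
side of rounding. Negative-definite jitter in the BM covariance is handled
with a 1e-12 ridge before Cholesky.

## Known limitations

- Mantel tests on distance matrices have known anti-conservative tendencies
  under spatial autocorrelation of residuals; the per-clade permutation
  calibration checked here (type-I within binomial error of α on neutral
  clades) covers the generator's null, not every real-world dependence
  structure.
- BH is applied per reference family; pooling both families into one family
  is a defensible alternative (counts would change slightly).
- The "independent" classes condition on the opposite axis being
  non-significant (q > α), which mixes an effect-size criterion (Δ) with a
  significance criterion; clades with both axes strongly significant are
  reported as `both` regardless of Δ.
- Branch-length fractions depend on the subtending-edge convention; both
  variants are computable and the default is stated above.
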