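# Methods

This note documents the models and procedures implemented in `foreco`, the
defaults and numerical choices, what the synthetic generator does and does
not emulate, and the design decisions taken where the methodology left
genuine latitude.

## Dominance filtering (IVI)

The Importance Value Index of species *s* in a plot is the arithmetic mean
of three relative components, each summing to 100% over the plot's species:

- relative density: 100 · stems(s) / stems(plot);
- relative dominance: 100 · BA(s) / BA(plot), with per-stem basal area
  π(DBH/2)² (DBH in cm, BA in m²; no further allometry);
- relative frequency: 100 · presences(s) / Σ_species presences, where a
  presence is a subplot containing the species. The denominator is the
  classical Curtis–McIntosh one (sum of presence counts over species, not
  the subplot count); it is the only choice for which the component — and
  hence the composite IVI — sums to exactly 100 per plot.

Dividing the three-component sum by 3 puts IVI on a 0–100 scale; the usual
0–300 scale would make a "5%" dominance threshold meaningless. The
threshold comparison is inclusive (IVI ≥ t), so boundary species are kept.
Records with DBH < 10 cm are rejected at load, mirroring standard
inventory protocol. Plots where no species reaches the threshold are
dropped with a warning rather than erroring, since degenerate synthetic
inputs can produce them. Cumulative-IVI retention curves are averaged as
the unweighted mean over plots (plots are the sampling unit; a
pooled-stems average would weight large plots more).

## Turnover dissimilarity and clustering

`bray_turnover` implements the balanced-variation (turnover) component of
abundance-based Bray–Curtis dissimilarity, min(B,C)/(A+min(B,C)). It is 0
for identical or nested site pairs, 1 for pairs sharing no species, and is
bounded above by the full Bray–Curtis index (B+C)/(2A+B+C). The unit tests
verify the implementation against an independent brute-force evaluation of
the raw definitions on ~1000 random small matrices.

UPGMA (average linkage) is order-sensitive only through ties in the
agglomeration. The tree search therefore permutes the site order of the
dissimilarity matrix `n_randomizations` times (default 1000), builds the
scipy average-linkage tree for each ordering (scipy's tie resolution is
deterministic given the order, which is exactly where the randomization
acts), and keeps the first tree attaining the maximal cophenetic
correlation. The whole search is deterministic under a fixed seed.

`pc_distance(labels)` is the between-cluster share of total pairwise
dissimilarity; it is 0 for one cluster, 1 for all-singletons, and
non-decreasing along refinement chains. The cluster count is the elbow of
the pc-distance curve over `k ∈ [2, min(20, n−1)]`, detected as the point
of maximum perpendicular distance to the chord joining the curve's
endpoints — the standard parameter-free detector; a numerically collinear
curve falls back to the smallest k with a warning.

Single-site clusters are resolved by presence-based Simpson similarity
(1 − min(b,c)/(a+min(b,c)) on species sets) between the singleton and each
multi-site cluster's pooled species set. The base threshold is 50%
similarity. The literature invokes a Bonferroni correction here without
defining a test statistic; we implement it as threshold tightening over
the m candidate clusters — effective threshold 1 − (1 − t)/m — behind a
toggle (default on). Singletons below the threshold everywhere are
excluded from the partition and logged.

## Test values and the interaction network

For species *i* and cluster *j* with n sites total, n_j in the cluster,
global mean μ and population variance σ² (divisor n), the test value is

    ρ_ij = (μ_ij − μ) / sqrt( ((n − n_j)/(n − 1)) · σ²/n_j ).

The denominator is the exact standard deviation of the mean of n_j draws
without replacement from the n sites; the tests confirm this against
exhaustive enumeration of all site subsets for n ≤ 8. Species with zero
variance get ρ = 0 (they carry no clustering signal) rather than NaN.
Significance uses δ = 1.96, the one-tailed 2.5% Gaussian quantile,
boundary inclusive.

ρ⁺ is the positive part of ρ for all clusters (default), not the
δ-censored value; species enter the λ computation only through membership
in some contributive set A_j, so sub-threshold positive contributions can
appear as interaction mass but never create a network row. The δ-censored
variant ("significant" mode) is available behind a flag because the
methodology's wording admits both readings. Species with no positive ρ
anywhere are dropped from ρ̂⁺ with a log entry; rows of ρ̂⁺ and of λ sum
to 1 by construction (machine precision; renormalized if a cluster with an
empty A_j is dropped). Network edges keep off-diagonal λ strictly above
5% ("higher than" is read strictly); node coordinates are per-cluster
medians of two environmental variables (pandas median: midpoint of the
middle two for even counts).

## Ecosystem classification

Segments are summarized by q25/q50/q75 per variable (numpy linear
interpolation). Training segments adopt the cluster of the plot they
contain; clusters under `min_cluster_size = 15` labeled sites are
excluded; multi-plot conflicts do not arise in the synthetic generator
(at most one plot per segment) and would be excluded if present.

Feature selection is nested by default: within each stratified CV fold the
candidates are ranked by random-forest impurity importance on the training
part and every subset size (default 5–30, clipped to the number of
candidates) is scored on the validation part by support-weighted F1; the
best mean size wins, ties to the smaller size, and the returned ranking is
refit on all data. Collinearity pruning then scans the selected subset in
rank order and drops any variable with |Pearson r| > 0.7 against an
already-kept one — a deterministic, auditable stand-in for manual removal
by expert judgment.

Evaluation pools out-of-fold predictions from stratified 10-fold CV
(folds reduced with a warning if the smallest class is smaller) into a
row-percentage confusion matrix; the aggregate "F1" is the support-weighted
mean of per-class F1 (the natural aggregate on imbalanced classes, and
distinct from the macro F1, the unweighted mean). The forest default is
500 trees with sklearn's default feature subsampling, exposed in config.

Permutation importance shuffles each feature column `n_permutations`
(default 100) times: the importance is the mean accuracy drop (per class:
mean F1 drop) and the p-value is (1 + #{permuted score ≥ baseline score})
/ (n_permutations + 1). A sole separating variable therefore gets
p = 1/101 at the default; a constant column gets exactly zero change and
p = 1; a noise column's p is approximately uniform. Impurity (Gini)
importance is read from the fitted forest; its p-values, which require one
forest refit per response permutation, are behind a `gini_refits` flag.
Partial dependence substitutes each grid value (grid clamped to the
observed range) into every row, averages class probabilities and reports
log-odds log(p/(1−p)) with probabilities clipped to [1e-6, 1−1e-6].

## Synthetic generator

The generator emulates the inventory structure the pipeline consumes:
K planted clusters of plots (imbalanced site counts allowed), each with a
disjoint pool of potential dominants plus a shared background pool;
heavy-tailed abundances; lognormal DBH truncated at 10 cm (inverse-CDF
sampling); uniform subplot membership; cluster-correlated Gaussian
environmental covariates; segments with q25/q50/q75 of simulated pixels
(informative variables from the cluster distribution, distractors pure
N(0,1)); and a pixel landscape with cluster-dependent Bernoulli SF/OGF
types. All three generators draw from independent streams spawned from
one seed and are byte-identical under a fixed seed.

Abundances are hierarchical: one Dirichlet profile per cluster over its
pool (concentration = `abundance_dispersion`, default 0.3 — strongly
oligarchic), one global Dirichlet profile over the shared pool, combined
with deterministic mass split so that the expected shared-stem share is
n_shared/(n_pool·dominant_weight + n_shared); each plot then draws its
proportions from a Dirichlet centred on its cluster profile
(`plot_concentration` = 50, moderate plot-to-plot wobble) and stem counts
from a multinomial with Poisson plot size (default mean 160 stems, in line
with ~1 ha tropical plots at a 10 cm cutoff). Drawing the oligarchy at the
cluster level — rather than independently per plot — is what makes plots
of one bioregion floristically coherent, which is the property the whole
workflow presumes; a per-plot Dirichlet produces within-cluster turnover
almost as high as between-cluster turnover and no recoverable structure.
No published abundance-distribution family is being matched here; the
Dirichlet-multinomial is a stand-in chosen for its single dispersion knob.

Two named study conditions are provided: `zero_noise_config` (no shared
species, widely separated environmental means — downstream recovery is
exact by construction) and `moderate_noise_config` (30% expected shared
stem share via `with_shared_fraction(0.3)`). Both use 4 clusters with
sites (8, 7, 6, 5) and ~120 stems per plot — sizes chosen so the full
recovery analyses (including the 20-seed moderate-noise replicate) run in
seconds while leaving every statistic well away from small-sample
degeneracy.

What the generator does **not** emulate: spatial autocorrelation of
environment or composition, succession dynamics, detection error,
multi-plot segments, non-forest landscape classes, or any geographic
realism. Passing recovery tests therefore show the pipeline is correct
and well-calibrated under its own assumptions, not that it would achieve
comparable accuracy on real inventory data, where environmental overlap,
spatial structure and taxonomic noise are all harsher.

## Pipeline and reproducibility

`run_pipeline` fans the global seed out to per-stage seeds through
`numpy.random.SeedSequence` (each reduced below 2³¹), writes every stage
artifact (CSV, Newick, GraphML, JSON) into a run directory, and records a
manifest with all parameters, stage seeds and SHA-256 digests; reruns with
the same config reproduce identical digests. A stage failure aborts with
the stage named, retaining completed artifacts.

## Known limitations

- The elbow detector is heuristic; on pc-distance curves without curvature
  it falls back to the smallest k. Fixed-k cutting is available everywhere.
- The singleton Bonferroni rule is a threshold adjustment, not a formal
  test; with many clusters the effective threshold approaches 1 and most
  singletons are excluded.
- RFE cost grows as folds × subset-sizes forest fits; at the default 26
  sizes and 500 trees it is the slowest stage and the pipeline caps the
  RFE forests at 200 trees.
- Permutation-importance p-values are lower-bounded at 1/(n_permutations+1)
  and are not corrected for multiplicity across variables.
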