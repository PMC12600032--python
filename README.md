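# foreco

Delineation of forest ecosystems (bioregions) from national forest-inventory
data, and their extrapolation over a landscape with an object-oriented
random-forest classifier.

The package is aimed at community ecologists and biodiversity-informatics
practitioners who need to go from raw tree records (plot, subplot, species,
DBH) to (i) a floristic partition of inventory sites, (ii) the species
assemblages that characterize each partition and the interaction network
between partitions, (iii) a segment-level ecosystem map, and (iv) the
old-growth / secondary forest (OGF/SF) composition of each ecosystem.
A synthetic-data generator with planted ground truth makes every stage of
the workflow testable without access to a real inventory.

## The methods in brief

**Dominance (IVI).** For each plot, every species gets an Importance Value
Index — the mean of its relative density (share of stems), relative
dominance (share of basal area, π(DBH/2)²) and relative frequency (share of
subplot presences) — normalized so the plot total is 100%. Species with
IVI ≥ 5% are the plot's dominant species.

**Bioregionalization.** Sites are compared with the balanced-variation
(turnover) component of abundance-based Bray–Curtis dissimilarity,

&emsp; β<sub>BrayTurn</sub> = min(B, C) / (A + min(B, C)),

where A is the summed minimum abundance of shared species and B, C the
abundances exclusive to each site. UPGMA trees are built for many random
orderings of the dissimilarity matrix and the tree with the best cophenetic
correlation is kept; the cluster count is chosen by an elbow rule on
`pc_distance` (the between-cluster share of total dissimilarity); single-site
clusters are merged into the most similar cluster (presence-based Simpson
similarity, 50% threshold with optional Bonferroni-style tightening) or
excluded.

**Contribution network.** The test value
ρ<sub>ij</sub> = (μ<sub>ij</sub> − μ) / √( (n − n<sub>j</sub>)/(n − 1) · σ²/n<sub>j</sub> )
standardizes each species' within-cluster mean abundance against its
finite-population sampling distribution; ρ ≥ δ = 1.96 (one-tailed 2.5%)
defines the contributive set A<sub>j</sub> of a cluster. Positive
contributions are row-normalized per species (ρ̂⁺) and averaged over each
A<sub>j</sub> to give the cluster-interaction matrix
λ<sub>jj′</sub> = |A<sub>j</sub>|⁻¹ Σ<sub>i∈A<sub>j</sub></sub> ρ̂⁺<sub>ij′</sub>,
whose rows sum to 1: the diagonal is a cluster's specificity, off-diagonal
entries its species sharing with other clusters. The network is projected
onto per-cluster medians of two environmental variables (by default annual
precipitation × elevation).

**Ecosystem model.** Image segments summarized by q25/q50/q75 of each
candidate variable inherit the cluster of the plot they contain; clusters
with fewer than 15 sites are excluded. Features are selected by recursive
feature elimination with a random forest over subset sizes 5–30 (optimising
the support-weighted F1), then greedily pruned for collinearity
(|Pearson r| > 0.7). The model (500 trees) is evaluated by stratified
10-fold cross-validation (row-percentage confusion matrix, per-class /
weighted / macro F1), interrogated with permutation variable importance
(100 permutations per variable, permutation p-values) and partial
dependence on the log-odds scale, and applied to the unlabeled segments.

**Composition.** OGF/SF shares are computed per in situ cluster (plots)
and per mapped ecosystem (pixels) and compared (per-row |ΔOGF|, mean ± SD,
dominance-inversion flags).

## Worked example

```python
import pandas as pd
from foreco import (compute_ivi, select_dominant, cluster_sites, test_values,
                    contributive_species, normalize_contributions,
                    interaction_matrix, adjusted_rand_index, generate_inventory)
from foreco.synthetic import moderate_noise_config

cfg = moderate_noise_config(seed=42)        # 4 planted clusters, 30% shared stems
trees, plots, truth = generate_inventory(cfg)

ivi = compute_ivi(trees)
matrix = select_dominant(ivi, threshold_pct=5.0)
result = cluster_sites(matrix, n_randomizations=100, seed=1)
print("k:", result.k, "cophenetic corr:", round(result.tree.cophenetic_corr, 4))

planted = pd.Series(truth.plot_cluster).loc[result.labels.index]
print("ARI vs planted:", adjusted_rand_index(result.labels, planted))

tv = test_values(matrix.loc[result.labels.index], result.labels)
sets = contributive_species(tv)
im = interaction_matrix(normalize_contributions(tv), sets)
print("contributive species per cluster:", {c: len(s) for c, s in sets.sets.items()})
print("mean specificity:", round(float(im.specificity.mean()), 3))
```

prints

```
k: 4 cophenetic corr: 0.9508
ARI vs planted: 1.0
contributive species per cluster: {1: 9, 2: 11, 3: 5, 4: 11}
mean specificity: 0.996
```

The elbow recovers the 4 planted clusters exactly (ARI 1.0 against the
generator's truth); each cluster is characterized by 5–11 significantly
over-represented species, and specificity near 1 means those assemblages
are almost entirely private to their cluster — as expected when the planted
pools are disjoint and only background species are shared.

The same workflow is available from the shell:

```bash
foreco simulate --seed 42 --out run/
foreco ivi --records run/trees.csv --threshold 5 \
       --out-matrix run/abundance.csv --out-ivi run/ivi.csv
foreco cluster --matrix run/abundance.csv --n-random 1000 --seed 1 --out run/
foreco pipeline --seed 42 --out run/   # everything, with a provenance manifest
```

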