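"""Turnover-based hierarchical bioregionalization.

Sites (forest plots) are clustered on the balanced-variation (turnover)
component of abundance-based Bray–Curtis dissimilarity,

    beta_bray_turn = min(B, C) / (A + min(B, C)),

where A is the summed minimum abundance of species shared by the two sites
and B, C the abundance totals exclusive to each site.  The component
isolates compositional replacement from nestedness: identical sites score
0, sites sharing no species score 1, and a site nested inside another
scores 0.

Because UPGMA is sensitive to the order of tied entries, the tree is built
for many random orderings of the dissimilarity matrix and the tree with
the highest cophenetic correlation is retained.  The number of clusters is
chosen with an elbow rule on ``pc_distance`` (the between-cluster share of
total dissimilarity), and single-site clusters are merged into the most
similar multi-site cluster or excluded, using presence-based Simpson
dissimilarity with an optional Bonferroni-style threshold tightening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """UPGMA tree retained from the order-randomization search.

    ``linkage`` is a scipy linkage matrix over the permuted site order
    ``order`` (``order[i]`` is the position of leaf ``i`` in ``sites``).
    """

    linkage: np.ndarray
    order: np.ndarray
    sites: list
    cophenetic_corr: float
    seed: int | None = None
    selected_randomization: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def cut(self, k: int) -> pd.Series:
        """Partition the sites into ``k`` clusters (flat cut of the tree)."""
        if not 1 <= k <= self.n_sites:
            raise ValueError(f"k must be in [1, {self.n_sites}], got {k}")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=[self.sites[i] for i in self.order])
        return relabel_contiguous(labels.reindex(self.sites))

    def cophenetic_matrix(self) -> pd.DataFrame:
        coph = squareform(hierarchy.cophenet(self.linkage))
        sites_in_order = [self.sites[i] for i in self.order]
        out = pd.DataFrame(coph, index=sites_in_order, columns=sites_in_order)
        return out.loc[self.sites, self.sites]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)
        names = [str(self.sites[i]) for i in self.order]

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass
class ClusteringResult:
    labels: pd.Series          # site -> cluster id (contiguous from 1)
    k: int
    pc_curve: pd.Series | None = None
    singleton_log: list = field(default_factory=list)
    tree: Dendrogram | None = None

    def to_frame(self) -> pd.DataFrame:
        disposition = {}
        for entry in self.singleton_log:
            disposition[entry["site"]] = (
                f"merged->{entry['merged_into']}" if entry["merged_into"] is not None
                else "excluded"
            )
        return pd.DataFrame({
            "site_id": self.labels.index,
            "cluster_id": self.labels.to_numpy(),
            "disposition": [disposition.get(s, "clustered") for s in self.labels.index],
        })


def relabel_contiguous(labels: pd.Series) -> pd.Series:
    """Renumber cluster ids to 1..k in order of first appearance."""
    mapping = {}
    out = []
    for v in labels:
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out.append(mapping[v])
    return pd.Series(out, index=labels.index)


def bray_turnover(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise balanced-variation turnover dissimilarity between sites."""
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DataError("need at least 2 sites")
    if (X < 0).any():
        raise DataError("abundances must be non-negative")
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = matrix.index[totals <= 0].tolist()
        raise DataError(f"sites with zero total abundance: {bad}")

    A = np.minimum(X[:, None, :], X[None, :, :]).sum(axis=-1)
    B = totals[:, None] - A
    C = totals[None, :] - A
    m = np.minimum(B, C)
    denom = A + m
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # symmetrize away float noise
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def upgma_best_tree(
    D: pd.DataFrame,
    n_randomizations: int = 1000,
    seed: int | None = None,
) -> Dendrogram:
    """Best-of-``n_randomizations`` UPGMA tree by cophenetic correlation.

    Each randomization permutes the site order of the dissimilarity matrix
    before average-linkage clustering; ties in the agglomeration are then
    resolved by the permuted order, which is the only way order can matter.
    The first tree attaining the maximal Pearson correlation between
    cophenetic and observed dissimilarities is kept (deterministic under a
    fixed seed).
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    sites = list(D.index)
    n = len(sites)
    Dv = D.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    if n < 3:
        Z = hierarchy.linkage(squareform(Dv, checks=False), method="average")
        return Dendrogram(Z, np.arange(n), sites, 1.0, seed, 0)

    best = None
    for b in range(n_randomizations):
        perm = rng.permutation(n)
        Dp = Dv[np.ix_(perm, perm)]
        cond = squareform(Dp, checks=False)
        Z = hierarchy.linkage(cond, method="average")
        corr, _ = hierarchy.cophenet(Z, cond)
        corr = float(corr)
        if best is None or corr > best.cophenetic_corr + 1e-15:
            best = Dendrogram(Z, perm, sites, corr, seed, b)
    return best


def pc_distance(D: pd.DataFrame, labels) -> float:
    """Between-cluster share of total dissimilarity, in [0, 1]."""
    labels = pd.Series(labels).reindex(D.index)
    if labels.isna().any():
        raise KeyError("labels do not cover all sites in the matrix")
    if len(labels) < 2:
        raise DataError("pc_distance is undefined for a single site")
    Dv = D.to_numpy(dtype=float)
    lab = labels.to_numpy()
    iu = np.triu_indices(len(lab), k=1)
    total = Dv[iu].sum()
    if total == 0:
        logger.warning("all dissimilarities are zero; pc_distance defined as 0")
        return 0.0
    between = Dv[iu][lab[iu[0]] != lab[iu[1]]].sum()
    return float(between / total)


def elbow_index(xs: np.ndarray, ys: np.ndarray) -> int:
    """Index of the point farthest (perpendicular) from the endpoint chord."""
    p0 = np.array([xs[0], ys[0]], dtype=float)
    p1 = np.array([xs[-1], ys[-1]], dtype=float)
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 0
    pts = np.column_stack([xs, ys]).astype(float) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    dist[dist < 1e-9 * norm] = 0.0  # treat numerically-collinear points as on the chord
    return int(np.argmax(dist))


def select_k_elbow(
    tree: Dendrogram,
    D: pd.DataFrame,
    k_range: tuple[int, int] | None = None,
) -> tuple[int, pd.Series]:
    """Choose the cluster count by the elbow of the pc_distance curve."""
    n = tree.n_sites
    if k_range is None:
        k_range = (2, min(20, n - 1))
    k_min, k_max = k_range
    if not (2 <= k_min <= k_max <= n):
        raise ValueError(f"k_range {k_range} not within [2, {n}]")
    ks = np.arange(k_min, k_max + 1)
    pcs = np.array([pc_distance(D, tree.cut(int(k))) for k in ks])
    pc_curve = pd.Series(pcs, index=ks, name="pc_distance")

    chord_flat = np.allclose(
        pcs, np.interp(ks, [ks[0], ks[-1]], [pcs[0], pcs[-1]]), atol=1e-12
    )
    if chord_flat:
        logger.warning("pc_distance curve has no elbow; returning smallest k=%d", k_min)
        return int(ks[0]), pc_curve
    return int(ks[elbow_index(ks, pcs)]), pc_curve


def simpson_dissimilarity(pa1, pa2) -> float:
    """Presence-based Simpson (turnover) dissimilarity between species sets."""
    s1, s2 = set(pa1), set(pa2)
    if not s1 or not s2:
        raise DataError("species sets must be non-empty")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    m = min(b, c)
    if a + m == 0:
        return 0.0
    return m / (a + m)


def resolve_singletons(
    labels: pd.Series,
    matrix: pd.DataFrame,
    similarity_threshold: float = 0.5,
    n_comparisons_correction: bool = True,
) -> ClusteringResult:
    """Merge or exclude single-site clusters by floristic similarity.

    Each singleton's species set is compared with the pooled species set of
    every multi-site cluster via 1 - Simpson dissimilarity.  With the
    correction enabled, the similarity threshold is tightened over the m
    candidate clusters to 1 - (1 - t)/m, a Bonferroni-style adjustment of
    the tolerated dissimilarity.  Singletons below the (adjusted) threshold
    everywhere are excluded from the partition.
    """
    labels = pd.Series(labels).reindex(matrix.index)
    if labels.isna().any():
        raise KeyError("labels do not cover all sites in the matrix")
    counts = labels.value_counts()
    multi = counts.index[counts >= 2].tolist()
    singles = counts.index[counts == 1].tolist()
    if not multi:
        raise DataError("every cluster is a singleton; no reference clusters exist")

    m = len(multi)
    eff = 1.0 - (1.0 - similarity_threshold) / m if n_comparisons_correction else similarity_threshold

    pooled = {
        c: set(matrix.columns[(matrix.loc[labels == c] > 0).any(axis=0)])
        for c in multi
    }
    out = labels.copy()
    log = []
    for c in singles:
        site = labels.index[labels == c][0]
        species = set(matrix.columns[matrix.loc[site] > 0])
        sims = {cl: 1.0 - simpson_dissimilarity(species, pooled[cl]) for cl in multi}
        best_cluster = max(sims, key=lambda cl: (sims[cl], -multi.index(cl)))
        best_sim = sims[best_cluster]
        if best_sim >= eff:
            out.loc[site] = best_cluster
            log.append({"site": site, "merged_into": best_cluster,
                        "similarity": best_sim, "threshold": eff})
            logger.info("singleton %s merged into cluster %s (similarity %.3f)",
                        site, best_cluster, best_sim)
        else:
            out = out.drop(site)
            log.append({"site": site, "merged_into": None,
                        "similarity": best_sim, "threshold": eff})
            logger.info("singleton %s excluded (best similarity %.3f < %.3f)",
                        site, best_sim, eff)
    out = relabel_contiguous(out)
    return ClusteringResult(labels=out, k=int(out.nunique()), singleton_log=log)


def cluster_sites(
    matrix: pd.DataFrame,
    n_randomizations: int = 1000,
    seed: int | None = None,
    k: int | None = None,
    k_range: tuple[int, int] | None = None,
    similarity_threshold: float = 0.5,
    n_comparisons_correction: bool = True,
    resolve: bool = True,
) -> ClusteringResult:
    """Full bioregionalization: dissimilarity, UPGMA search, k choice, singletons.

    ``k=None`` selects the cluster count by the pc_distance elbow; a fixed
    ``k`` skips the elbow.  ``resolve=False`` keeps singleton clusters as is.
    """
    D = bray_turnover(matrix)
    tree = upgma_best_tree(D, n_randomizations=n_randomizations, seed=seed)
    pc_curve = None
    if k is None:
        k, pc_curve = select_k_elbow(tree, D, k_range=k_range)
    labels = tree.cut(k)
    if resolve:
        counts = labels.value_counts()
        if (counts == 1).any() and (counts >= 2).any():
            result = resolve_singletons(
                labels, matrix,
                similarity_threshold=similarity_threshold,
                n_comparisons_correction=n_comparisons_correction,
            )
            result.pc_curve, result.tree = pc_curve, tree
            return result
    labels = relabel_contiguous(labels)
    return ClusteringResult(labels=labels, k=int(labels.nunique()),
                            pc_curve=pc_curve, tree=tree)
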