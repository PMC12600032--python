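"""Species contribution test values and the cluster-interaction (lambda) network.

The test value rho_ij standardizes the difference between the mean
abundance of species i inside cluster j and its global mean, against the
standard deviation that mean would have if the cluster's n_j sites were a
simple random sample (without replacement) of the n sites:

    rho_ij = (mu_ij - mu) / sqrt( (n - n_j)/(n - 1) * sigma^2 / n_j ),

with sigma^2 the population variance of the species' abundances over all
sites.  Values at or above delta = 1.96 (one-tailed 2.5% under a Gaussian)
flag species significantly over-represented in a cluster; those species
form the contributive set A_j.

Positive contributions are row-normalized per species (rho-hat-plus) and
the cluster-interaction matrix averages them over each contributive set:

    lambda_{j j'} = (1/|A_j|) * sum_{i in A_j} rho_hat_plus_{i j'}.

Rows of lambda sum to 1; the diagonal is the specificity of a cluster and
off-diagonal entries measure how much its characteristic species also
contribute elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: default significance threshold on test values (one-tailed 2.5%, Gaussian)
DELTA = 1.96


def significance_threshold(alpha: float = 0.025) -> float:
    """Standard-normal upper quantile for a one-tailed level ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(norm.isf(alpha))


@dataclass
class TestValueMatrix:
    """Species x cluster test values with the per-species global context."""

    rho: pd.DataFrame          # species x cluster
    mu: pd.Series              # global mean abundance per species
    sigma2: pd.Series          # population variance per species
    n: int                     # total sites
    n_j: pd.Series             # sites per cluster
    mu_ij: pd.DataFrame        # species x cluster mean abundance

    @property
    def species(self):
        return self.rho.index

    @property
    def clusters(self):
        return self.rho.columns


@dataclass
class ContributiveSets:
    delta: float
    sets: dict                     # cluster -> list of species with rho >= delta
    clusters_per_species: pd.Series  # species -> number of clusters contributed to


@dataclass
class InteractionMatrix:
    lam: pd.DataFrame          # cluster x cluster, rows sum to 1
    rho_hat: pd.DataFrame      # species x cluster normalized positive contributions
    dropped_clusters: list = field(default_factory=list)

    @property
    def specificity(self) -> pd.Series:
        return pd.Series(np.diag(self.lam), index=self.lam.index, name="specificity")


def test_values(matrix: pd.DataFrame, labels) -> TestValueMatrix:
    """Standardized over/under-representation of every species in every cluster."""
    labels = pd.Series(labels).reindex(matrix.index)
    if labels.isna().any():
        raise KeyError("labels do not cover all sites in the matrix")
    n = len(matrix)
    if n < 2:
        raise DataError("test values require at least 2 sites")

    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sigma2 = X.var(axis=0)  # population variance (divisor n)

    clusters = pd.unique(labels)
    n_j = labels.value_counts().reindex(clusters)
    if (n_j == n).any():
        raise ConfigError(
            "a cluster contains every site; the test-value denominator is degenerate"
        )

    mu_ij = np.column_stack([X[(labels == c).to_numpy()].mean(axis=0) for c in clusters])
    nj = n_j.to_numpy(dtype=float)
    denom = np.sqrt(((n - nj) / (n - 1.0)) * sigma2[:, None] / nj)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (mu_ij - mu[:, None]) / np.where(denom > 0, denom, 1.0), 0.0)

    species = matrix.columns
    return TestValueMatrix(
        rho=pd.DataFrame(rho, index=species, columns=clusters),
        mu=pd.Series(mu, index=species),
        sigma2=pd.Series(sigma2, index=species),
        n=n,
        n_j=n_j,
        mu_ij=pd.DataFrame(mu_ij, index=species, columns=clusters),
    )


def contributive_species(tv: TestValueMatrix, delta: float = DELTA) -> ContributiveSets:
    """Per-cluster sets A_j of species with rho >= delta (boundary inclusive)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    significant = tv.rho >= delta
    sets = {c: list(tv.rho.index[significant[c]]) for c in tv.rho.columns}
    counts = significant.sum(axis=1).astype(int)
    return ContributiveSets(delta=delta, sets=sets, clusters_per_species=counts)


def normalize_contributions(
    tv: TestValueMatrix,
    mode: str = "positive",
    delta: float = DELTA,
) -> pd.DataFrame:
    """Row-normalized positive contributions (rho-hat-plus).

    ``mode="positive"`` (default) takes the positive part of rho;
    ``mode="significant"`` zeroes entries below delta before normalizing.
    Species with no positive entry anywhere are dropped with a log entry.
    """
    if mode == "positive":
        rho_plus = tv.rho.clip(lower=0.0)
    elif mode == "significant":
        rho_plus = tv.rho.where(tv.rho >= delta, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    row_sums = rho_plus.sum(axis=1)
    dropped = rho_plus.index[row_sums <= 0].tolist()
    if dropped:
        logger.info("dropped %d species with no positive contribution", len(dropped))
    kept = rho_plus.loc[row_sums > 0]
    return kept.div(row_sums[row_sums > 0], axis=0)


def interaction_matrix(rho_hat: pd.DataFrame, sets: ContributiveSets) -> InteractionMatrix:
    """Cluster x cluster lambda matrix: row j averages rho-hat-plus over A_j."""
    rows = {}
    dropped = []
    for c in rho_hat.columns:
        members = [s for s in sets.sets.get(c, []) if s in rho_hat.index]
        if not members:
            dropped.append(c)
            logger.warning("cluster %s has no contributive species; dropped from network", c)
            continue
        rows[c] = rho_hat.loc[members].mean(axis=0)
    if not rows:
        raise DataError("no cluster has a non-empty contributive set")
    lam = pd.DataFrame(rows).T
    lam = lam.loc[:, lam.index]  # square: destination clusters = retained sources
    lam = lam.div(lam.sum(axis=1), axis=0)  # renormalize if columns were dropped
    return InteractionMatrix(lam=lam, rho_hat=rho_hat, dropped_clusters=dropped)


def network_edges(im: InteractionMatrix, min_edge: float = 0.05):
    """Directed off-diagonal edges with weight strictly above ``min_edge``.

    Returns ``(edges, specificity)``: an edge-list frame with columns
    ``source, target, weight`` and the diagonal specificity series.
    """
    lam = im.lam
    records = []
    for j in lam.index:
        for jp in lam.columns:
            if j == jp:
                continue
            w = float(lam.loc[j, jp])
            if w > min_edge:
                records.append({"source": j, "target": jp, "weight": w})
    edges = pd.DataFrame(records, columns=["source", "target", "weight"])
    return edges, im.specificity


def to_graph(im: InteractionMatrix, min_edge: float = 0.05):
    """networkx DiGraph of the interaction network (specificity as node attr)."""
    import networkx as nx

    edges, spec = network_edges(im, min_edge=min_edge)
    g = nx.DiGraph()
    for c in im.lam.index:
        g.add_node(str(c), specificity=float(spec.loc[c]))
    for row in edges.itertuples():
        g.add_edge(str(row.source), str(row.target), weight=float(row.weight))
    return g


def project_network(
    im: InteractionMatrix,
    plot_env: pd.DataFrame,
    labels,
    x_var: str,
    y_var: str,
) -> pd.DataFrame:
    """Node coordinates: per-cluster medians of two environmental variables."""
    for v in (x_var, y_var):
        if v not in plot_env.columns:
            raise ConfigError(f"environmental variable {v!r} not in the plot table")
    labels = pd.Series(labels)
    env = plot_env.reindex(labels.index)
    if env[[x_var, y_var]].isna().any().any():
        raise ConfigError("environmental table does not cover all labeled sites")
    coords = env.groupby(labels.to_numpy())[[x_var, y_var]].median()
    coords = coords.reindex(im.lam.index)
    coords.columns = ["x", "y"]
    coords.index.name = "cluster"
    return coords
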