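"""Synthetic forest-inventory, segment and landscape generators with known truth.

The generator emulates the structure of a national forest inventory used
for ecosystem delineation: K planted site clusters, each with its own
disjoint pool of potential dominant species plus a background pool shared
by every cluster; heavy-tailed (Dirichlet-multinomial) per-plot species
abundances so that a few species dominate each plot; lognormal stem
diameters truncated at the 10 cm inventory cutoff; random subplot
membership; cluster-correlated environmental covariates; per-segment
feature tables summarized as q25/q50/q75 of simulated pixel values (with
pure-noise distractor variables); and a pixel landscape whose old-growth /
secondary forest mix is cluster-dependent.

Every generator is deterministic under the configured seed; the three
generators draw from independent streams spawned from that seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import ConfigError, ConsistencyError

#: default environmental variables: per-cluster means chosen to span the
#: elevation / precipitation gradients typical of a wet-tropical country
DEFAULT_ENV_MEANS = {
    "elevation": (150.0, 400.0, 1200.0, 2300.0),
    "annual_precip": (3500.0, 2300.0, 3600.0, 3800.0),
}
DEFAULT_ENV_SD = {"elevation": 150.0, "annual_precip": 300.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic inventory.

    Defaults are desk-scale analogues of a national inventory: a few
    imbalanced clusters, ~160 stems per plot, oligarchic abundances
    (small ``abundance_dispersion``), and two informative environmental
    gradients plus pure-noise distractors.
    """

    n_clusters: int = 4
    sites_per_cluster: tuple = (25, 15, 10, 6)
    species_per_cluster_pool: int = 30
    n_shared_species: int = 20
    trees_per_plot_mean: float = 160.0
    abundance_dispersion: float = 0.3
    dominant_weight: float = 3.0       # concentration multiplier for cluster-pool species
    plot_concentration: float = 50.0   # plot-level Dirichlet wobble around the cluster profile
    dbh_lognormal_params: tuple = (3.0, 0.5)   # (mu, sigma) of log DBH in cm
    n_subplots: int = 4
    env_cluster_means: Mapping = field(default_factory=lambda: dict(DEFAULT_ENV_MEANS))
    env_sd: Mapping = field(default_factory=lambda: dict(DEFAULT_ENV_SD))
    n_feature_variables: int = 10
    sf_probability_per_cluster: tuple = (0.7, 0.3, 0.5, 0.1)
    pixels_per_segment: int = 50
    n_segments: int = 120
    landscape_pixels_per_cluster: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ConfigError("n_clusters must be >= 2")
        for name in ("sites_per_cluster", "sf_probability_per_cluster"):
            if len(getattr(self, name)) != self.n_clusters:
                raise ConfigError(f"{name} must have one entry per cluster")
        if any(s < 1 for s in self.sites_per_cluster):
            raise ConfigError("sites_per_cluster entries must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.sf_probability_per_cluster):
            raise ConfigError("sf_probability_per_cluster entries must be in [0, 1]")
        for name in ("species_per_cluster_pool", "n_subplots", "pixels_per_segment",
                     "n_segments", "landscape_pixels_per_cluster"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_shared_species < 0:
            raise ConfigError("n_shared_species must be non-negative")
        for name in ("trees_per_plot_mean", "abundance_dispersion", "dominant_weight",
                     "plot_concentration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for var, means in self.env_cluster_means.items():
            if len(means) != self.n_clusters:
                raise ConfigError(f"env_cluster_means[{var!r}] must have one mean per cluster")
            if var not in self.env_sd:
                raise ConfigError(f"env_sd is missing variable {var!r}")
        if self.n_feature_variables < len(self.env_cluster_means):
            raise ConfigError(
                "n_feature_variables must be >= the number of environmental variables"
            )
        n_plots = sum(self.sites_per_cluster)
        if self.n_segments < n_plots:
            raise ConfigError("n_segments must be >= the total number of plots")

    @property
    def n_plots(self) -> int:
        return int(sum(self.sites_per_cluster))

    @property
    def env_variables(self) -> list:
        return list(self.env_cluster_means)

    @property
    def distractor_variables(self) -> list:
        n_noise = self.n_feature_variables - len(self.env_cluster_means)
        return [f"noise_{i + 1}" for i in range(n_noise)]

    def with_shared_fraction(self, fraction: float) -> "SyntheticConfig":
        """Adjust ``dominant_weight`` so shared species hold the given
        expected share of stems (fraction of total abundance)."""
        if not 0.0 < fraction < 1.0:
            raise ConfigError("shared fraction must be in (0, 1)")
        if self.n_shared_species == 0:
            raise ConfigError("no shared species to carry the shared fraction")
        w = self.n_shared_species * (1.0 - fraction) / (
            fraction * self.species_per_cluster_pool
        )
        return replace(self, dominant_weight=w)


def zero_noise_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Separable study condition: disjoint species pools, no shared species,
    widely separated environmental gradients.  Downstream recovery of the
    planted structure is exact by construction."""
    defaults = dict(
        n_clusters=4,
        sites_per_cluster=(8, 7, 6, 5),
        n_shared_species=0,
        trees_per_plot_mean=120.0,
        env_cluster_means={
            "elevation": (150.0, 600.0, 1300.0, 2300.0),
            "annual_precip": (3500.0, 2300.0, 3600.0, 4100.0),
        },
        env_sd={"elevation": 100.0, "annual_precip": 150.0},
        n_segments=60,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def moderate_noise_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Moderate-noise study condition: shared background species carry an
    expected 30% of stems in every plot."""
    defaults = dict(
        n_clusters=4,
        sites_per_cluster=(8, 7, 6, 5),
        trees_per_plot_mean=120.0,
        n_segments=60,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults).with_shared_fraction(0.3)


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside the generated tables."""

    plot_cluster: dict            # plot_id -> cluster id (1-based)
    planted_dominants: dict       # cluster id -> set of species names
    segment_cluster: dict         # segment_id -> cluster id
    segment_plot: dict            # segment_id -> plot_id or None
    informative_variables: set    # variable names that truly separate clusters
    seed: int = 0
    n_clusters: int = 0


def _streams(config: SyntheticConfig):
    children = np.random.SeedSequence(config.seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _truncated_lognormal_dbh(rng, size, mu, sigma, lower=10.0):
    """Sample DBH ~ lognormal(mu, sigma) conditioned on DBH >= lower, by inverse CDF."""
    lo = ndtr((np.log(lower) - mu) / sigma)
    u = rng.uniform(lo, 1.0, size=size)
    return np.exp(mu + sigma * ndtri(u))


def generate_inventory(config: SyntheticConfig):
    """Generate tree records, plot metadata and the planted truth.

    Returns ``(trees, plots, truth)``.  ``trees`` has columns
    ``plot_id, subplot_id, species, dbh_cm``; ``plots`` carries area,
    forest type (OGF/SF), coordinates and the environmental covariates.
    """
    rng = _streams(config)[0]
    K = config.n_clusters
    mu, sigma = config.dbh_lognormal_params

    pools = {
        c: [f"sp_c{c}_{m + 1}" for m in range(config.species_per_cluster_pool)]
        for c in range(1, K + 1)
    }
    shared = [f"sp_shared_{m + 1}" for m in range(config.n_shared_species)]

    plot_ids, plot_clusters = [], []
    for c, n_sites in zip(range(1, K + 1), config.sites_per_cluster):
        for _ in range(n_sites):
            plot_ids.append(f"P{len(plot_ids) + 1:03d}")
            plot_clusters.append(c)

    # One heavy-tailed abundance profile per cluster (the planted oligarchy)
    # plus one global profile for the shared background pool; plots wobble
    # around their cluster's combined profile.  The expected shared-species
    # stem share is n_shared / (n_pool * dominant_weight + n_shared).
    n_pool = config.species_per_cluster_pool
    shared_mass = len(shared) / (n_pool * config.dominant_weight + len(shared)) \
        if shared else 0.0
    shared_profile = rng.dirichlet(np.full(len(shared), config.abundance_dispersion)) \
        if shared else np.empty(0)
    cluster_profiles = {}
    for c in range(1, K + 1):
        pool_profile = rng.dirichlet(np.full(n_pool, config.abundance_dispersion))
        cluster_profiles[c] = np.concatenate([
            pool_profile * (1.0 - shared_mass),
            shared_profile * shared_mass,
        ])

    tree_rows = []
    plot_rows = []
    env_vars = config.env_variables
    for pid, c in zip(plot_ids, plot_clusters):
        species = pools[c] + shared
        base = cluster_profiles[c]
        p = rng.dirichlet(np.maximum(config.plot_concentration * base, 1e-9))
        n_trees = max(1, int(rng.poisson(config.trees_per_plot_mean)))
        counts = rng.multinomial(n_trees, p)
        for sp, cnt in zip(species, counts):
            if cnt == 0:
                continue
            dbh = _truncated_lognormal_dbh(rng, cnt, mu, sigma)
            subplots = rng.integers(1, config.n_subplots + 1, size=cnt)
            for d, sub in zip(dbh, subplots):
                tree_rows.append((pid, int(sub), sp, float(d)))

        env_values = {
            v: float(rng.normal(config.env_cluster_means[v][c - 1], config.env_sd[v]))
            for v in env_vars
        }
        plot_rows.append({
            "plot_id": pid,
            "area_ha": 1.0,
            "forest_type": "SF" if rng.random() < config.sf_probability_per_cluster[c - 1] else "OGF",
            "x": float(c * 10.0 + rng.normal(0, 1.0)),
            "y": float(rng.normal(0, 1.0)),
            **env_values,
        })

    trees = pd.DataFrame(tree_rows, columns=["plot_id", "subplot_id", "species", "dbh_cm"])
    plots = pd.DataFrame(plot_rows)

    segment_ids = [f"S{i + 1:04d}" for i in range(config.n_segments)]
    segment_cluster, segment_plot = {}, {}
    for i, sid in enumerate(segment_ids):
        if i < len(plot_ids):
            segment_cluster[sid] = plot_clusters[i]
            segment_plot[sid] = plot_ids[i]
        else:
            weights = np.asarray(config.sites_per_cluster, dtype=float)
            segment_cluster[sid] = int(rng.choice(np.arange(1, K + 1), p=weights / weights.sum()))
            segment_plot[sid] = None

    truth = SyntheticTruth(
        plot_cluster=dict(zip(plot_ids, plot_clusters)),
        planted_dominants={c: set(pools[c]) for c in pools},
        segment_cluster=segment_cluster,
        segment_plot=segment_plot,
        informative_variables=set(env_vars),
        seed=config.seed,
        n_clusters=K,
    )
    return trees, plots, truth


def _check_truth(config: SyntheticConfig, truth: SyntheticTruth):
    if truth.seed != config.seed or truth.n_clusters != config.n_clusters:
        raise ConsistencyError("truth was not generated under this configuration")
    if len(truth.segment_cluster) != config.n_segments:
        raise ConsistencyError("segment count in truth does not match the configuration")


def generate_segments(config: SyntheticConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-segment q25/q50/q75 feature table from simulated pixel values.

    Informative variables are drawn from the segment's cluster distribution;
    distractor variables are standard normal, independent of cluster.
    """
    _check_truth(config, truth)
    rng = _streams(config)[1]
    env_vars = config.env_variables
    noise_vars = config.distractor_variables

    rows = []
    for sid in sorted(truth.segment_cluster):
        c = truth.segment_cluster[sid]
        row = {"segment_id": sid, "plot_id": truth.segment_plot[sid]}
        for v in env_vars + noise_vars:
            if v in config.env_cluster_means:
                mean = config.env_cluster_means[v][c - 1]
                sd = config.env_sd[v]
            else:
                mean, sd = 0.0, 1.0
            pixels = rng.normal(mean, sd, size=config.pixels_per_segment) if sd > 0 \
                else np.full(config.pixels_per_segment, mean)
            q25, q50, q75 = np.percentile(pixels, [25, 50, 75])
            row[f"{v}_q25"], row[f"{v}_q50"], row[f"{v}_q75"] = q25, q50, q75
        rows.append(row)
    return pd.DataFrame(rows)


def generate_landscape(config: SyntheticConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Pixel table with ecosystem (cluster) label and OGF/SF forest type.

    Forest type is Bernoulli(sf_probability of the pixel's cluster).
    """
    _check_truth(config, truth)
    rng = _streams(config)[2]
    frames = []
    for c in range(1, config.n_clusters + 1):
        n = config.landscape_pixels_per_cluster
        sf = rng.random(n) < config.sf_probability_per_cluster[c - 1]
        frames.append(pd.DataFrame({
            "ecosystem": c,
            "forest_type": np.where(sf, "SF", "OGF"),
        }))
    out = pd.concat(frames, ignore_index=True)
    out.index.name = "pixel_id"
    return out.reset_index()
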