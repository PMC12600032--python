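"""End-to-end orchestration: simulate -> ivi -> cluster -> network -> model -> composition.

A single global seed is fanned out to per-stage seeds through numpy's
``SeedSequence`` so stages are individually reproducible; every artifact is
written under a run directory together with a JSON manifest recording the
parameters, stage seeds and SHA-256 digest of each output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, composition, dominance, ecosystem, network, synthetic
from .errors import ForecoError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ivi", "cluster", "contributions", "network", "model", "composition")


class PipelineError(ForecoError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All stage parameters, with the study's defaults."""

    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    ivi_threshold: float = 5.0
    n_randomizations: int = 1000
    k: int | None = None               # None -> elbow selection
    k_range: tuple | None = None
    singleton_threshold: float = 0.5
    delta: float = 1.96
    contribution_mode: str = "positive"
    min_edge: float = 0.05
    x_var: str = "annual_precip"
    y_var: str = "elevation"
    min_cluster_size: int = 15
    folds: int = 10
    rfe_sizes: tuple = (5, 30)
    rfe_folds: int = 5
    r_threshold: float = 0.7
    n_permutations: int = 100
    n_estimators: int = 500
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["env_cluster_means"] = {
            k: list(v) for k, v in d["synthetic"]["env_cluster_means"].items()
        }
        return d


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds (each below 2**31) from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES), dtype=np.uint64)
    return {name: int(s % (2**31)) for name, s in zip(STAGES, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, writing artifacts and a provenance manifest.

    Returns the manifest dict.  A stage failure raises ``PipelineError``
    naming the stage; artifacts from completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {"config": config.to_dict(), "stage_seeds": seeds, "outputs": {}}

    def write(name: str, df: pd.DataFrame, **kwargs):
        path = outdir / name
        df.to_csv(path, index=kwargs.pop("index", False), **kwargs)
        manifest["outputs"][name] = _sha256(path)
        return path

    def write_text(name: str, text: str):
        path = outdir / name
        path.write_text(text)
        manifest["outputs"][name] = _sha256(path)

    stage = "simulate"
    try:
        sim_config = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
        trees, plots, truth = synthetic.generate_inventory(sim_config)
        segments = synthetic.generate_segments(sim_config, truth)
        pixels = synthetic.generate_landscape(sim_config, truth)
        write("trees.csv", trees)
        write("plots.csv", plots)
        write("segments.csv", segments)
        write("pixels.csv", pixels)
        write("truth_plot_clusters.csv",
              pd.DataFrame({"plot_id": list(truth.plot_cluster),
                            "cluster": list(truth.plot_cluster.values())}))

        stage = "ivi"
        ivi = dominance.compute_ivi(trees)
        matrix = dominance.select_dominant(ivi, threshold_pct=config.ivi_threshold)
        write("ivi.csv", ivi)
        write("abundance_matrix.csv", matrix, index=True)

        stage = "cluster"
        D = clustering.bray_turnover(matrix)
        write("dissimilarity.csv", D, index=True)
        result = clustering.cluster_sites(
            matrix,
            n_randomizations=config.n_randomizations,
            seed=seeds["cluster"],
            k=config.k,
            k_range=config.k_range,
            similarity_threshold=config.singleton_threshold,
        )
        write("clusters.csv", result.to_frame())
        if result.tree is not None:
            write_text("dendrogram.nwk", result.tree.to_newick())
            manifest["cophenetic_corr"] = result.tree.cophenetic_corr
        if result.pc_curve is not None:
            write("pc_curve.csv", result.pc_curve.rename_axis("k").reset_index())
        labels = result.labels

        stage = "contributions"
        tv = network.test_values(matrix.loc[labels.index], labels)
        sets = network.contributive_species(tv, delta=config.delta)
        rho_hat = network.normalize_contributions(
            tv, mode=config.contribution_mode, delta=config.delta)
        write("test_values.csv", tv.rho, index=True)
        write("contributive_species.csv", pd.DataFrame(
            [{"cluster": c, "species": s, "rho": float(tv.rho.loc[s, c])}
             for c, members in sets.sets.items() for s in members]))

        stage = "network"
        im = network.interaction_matrix(rho_hat, sets)
        write("lambda.csv", im.lam, index=True)
        edges, spec = network.network_edges(im, min_edge=config.min_edge)
        write("network_edges.csv", edges)
        write("specificity.csv", spec.rename_axis("cluster").reset_index())
        env_cols = [config.x_var, config.y_var]
        if set(env_cols) <= set(plots.columns):
            coords = network.project_network(
                im, plots.set_index("plot_id"), labels, config.x_var, config.y_var)
            write("network_coords.csv", coords, index=True)
        try:
            import networkx as nx
            nx.write_graphml(network.to_graph(im, min_edge=config.min_edge),
                             outdir / "network.graphml")
            manifest["outputs"]["network.graphml"] = _sha256(outdir / "network.graphml")
        except ImportError:  # pragma: no cover - networkx is a hard dependency
            pass

        stage = "model"
        train, predict_set = ecosystem.label_segments(
            segments, labels, min_cluster_size=config.min_cluster_size)
        feats = ecosystem.feature_columns(train)
        rfe_sizes = range(config.rfe_sizes[0], config.rfe_sizes[1] + 1)
        selection = ecosystem.select_features_rfe(
            train, subset_sizes=rfe_sizes, folds=config.rfe_folds,
            seed=seeds["model"], n_estimators=min(config.n_estimators, 200),
            features=feats)
        kept, dropped = ecosystem.prune_collinear(
            train, selection.selected, r_threshold=config.r_threshold)
        fit, model = ecosystem.fit_evaluate(
            train, kept, folds=config.folds, seed=seeds["model"],
            n_estimators=config.n_estimators)
        write_text("fit_result.json", json.dumps(fit.to_dict(), indent=2))
        importance = ecosystem.permutation_importance_scores(
            model, train, kept, n_permutations=config.n_permutations,
            seed=seeds["model"])
        write("importance_overall.csv", importance.overall, index=True)
        write("importance_per_class.csv", importance.per_class, index=True)
        top = importance.overall["importance"].idxmax()
        pdp = ecosystem.partial_dependence(model, train, top, kept)
        write("partial_dependence.csv",
              pdp.log_odds.rename_axis(pdp.variable), index=True)
        predictions = ecosystem.predict_segments(model, predict_set, kept)
        write("predicted_segments.csv", predictions)
        manifest["model"] = {"selected_features": kept,
                             "dropped_collinear": [list(d) for d in dropped],
                             "f1": fit.f1, "macro_f1": fit.macro_f1}

        stage = "composition"
        by_cluster = composition.composition_by_cluster(plots, labels)
        by_eco = composition.composition_by_ecosystem(pixels)
        write("composition_clusters.csv",
              composition.composition_long(by_cluster, source="clustering"))
        write("composition_ecosystems.csv",
              composition.composition_long(by_eco, source="model"))
        per_row, summary = composition.compare_compositions(by_cluster, by_eco)
        write("composition_comparison.csv", per_row, index=True)
        manifest["composition_summary"] = summary
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete; %d artifacts in %s", len(manifest["outputs"]), outdir)
    return manifest
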