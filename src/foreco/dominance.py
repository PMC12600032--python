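"""Dominant-species selection by the Importance Value Index (IVI).

The IVI of a species in a plot combines three relative components, after
Curtis & McIntosh: relative density (share of stems), relative dominance
(share of basal area) and relative frequency (share of subplot presences).
Each component sums to 100% over the species of a plot; the composite is
the mean of the three, so per-plot IVI totals are also 100%.  Species at or
above a percentage threshold (default 5%) are retained as the plot's
dominant species, and the site x species stem-count matrix over the union
of dominant species is the input to bioregion clustering.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import DataError

logger = logging.getLogger(__name__)

TREE_COLUMNS = ("plot_id", "subplot_id", "species", "dbh_cm")

#: minimum diameter at breast height retained in inventories, in cm
MIN_DBH_CM = 10.0


def basal_area_m2(dbh_cm):
    """Basal area of a stem, pi*(DBH/2)^2, with DBH in cm and area in m^2."""
    return np.pi * (np.asarray(dbh_cm, dtype=float) / 200.0) ** 2


def load_tree_records(path) -> pd.DataFrame:
    """Read a tree-record CSV, rejecting stems below the 10 cm DBH cutoff."""
    records = pd.read_csv(path)
    missing = [c for c in TREE_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"tree record table is missing columns {missing}")
    return validate_tree_records(records)


def validate_tree_records(records: pd.DataFrame) -> pd.DataFrame:
    if records.empty:
        raise DataError("tree record table is empty")
    if records["species"].isna().any() or (records["species"].astype(str) == "").any():
        raise DataError("tree record table contains empty species names")
    small = records["dbh_cm"] < MIN_DBH_CM
    if small.any():
        logger.warning("rejected %d records with DBH < %g cm", int(small.sum()), MIN_DBH_CM)
        records = records.loc[~small]
    if records.empty:
        raise DataError("no records remain after the DBH cutoff")
    return records.reset_index(drop=True)


def compute_ivi(records: pd.DataFrame) -> pd.DataFrame:
    """Per-plot, per-species IVI table.

    Returns a long-format frame with columns ``plot_id, species, stems,
    basal_area_m2, rel_density, rel_dominance, rel_frequency, ivi``.
    ``rel_frequency`` uses the classical Curtis–McIntosh denominator: the
    sum over species of subplot-presence counts, which guarantees the
    component sums to 100 within each plot.
    """
    records = validate_tree_records(records)
    records = records.assign(ba=basal_area_m2(records["dbh_cm"]))

    grouped = records.groupby(["plot_id", "species"], sort=True)
    per = grouped.agg(
        stems=("species", "size"),
        basal_area_m2=("ba", "sum"),
        presences=("subplot_id", "nunique"),
    ).reset_index()

    plot_totals = per.groupby("plot_id").agg(
        tot_stems=("stems", "sum"),
        tot_ba=("basal_area_m2", "sum"),
        tot_presences=("presences", "sum"),
    )
    if (plot_totals["tot_ba"] <= 0).any():
        bad = plot_totals.index[plot_totals["tot_ba"] <= 0].tolist()
        raise DataError(f"plots with zero basal area: {bad}")

    per = per.join(plot_totals, on="plot_id")
    per["rel_density"] = 100.0 * per["stems"] / per["tot_stems"]
    per["rel_dominance"] = 100.0 * per["basal_area_m2"] / per["tot_ba"]
    per["rel_frequency"] = 100.0 * per["presences"] / per["tot_presences"]
    per["ivi"] = (per["rel_density"] + per["rel_dominance"] + per["rel_frequency"]) / 3.0
    return per[
        ["plot_id", "species", "stems", "basal_area_m2",
         "rel_density", "rel_dominance", "rel_frequency", "ivi"]
    ]


def select_dominant(ivi: pd.DataFrame, threshold_pct: float = 5.0) -> pd.DataFrame:
    """Site x species stem-count matrix of dominant species (IVI >= threshold).

    Plots where no species reaches the threshold are dropped with a warning.
    Columns are the union of species kept in any plot; absent species get 0.
    """
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError(f"threshold_pct must be in [0, 100], got {threshold_pct}")
    kept = ivi.loc[ivi["ivi"] >= threshold_pct]
    dropped = set(ivi["plot_id"]) - set(kept["plot_id"])
    if dropped:
        logger.warning(
            "dropped %d plot(s) with no species at IVI >= %g%%: %s",
            len(dropped), threshold_pct, sorted(dropped),
        )
    if kept.empty:
        raise DataError(f"no plot retains any species at IVI >= {threshold_pct}%")
    matrix = kept.pivot_table(
        index="plot_id", columns="species", values="stems", fill_value=0, aggfunc="sum"
    )
    matrix.columns.name = None
    return matrix.astype(int)


def ivi_retention(ivi: pd.DataFrame, thresholds: Sequence[float]) -> pd.DataFrame:
    """Mean (over plots) cumulative IVI retained by each threshold.

    Returns a frame with columns ``threshold, mean_retained_pct``; retained
    percentage is non-increasing in the threshold.
    """
    rows = []
    for t in thresholds:
        per_plot = (
            ivi.assign(kept=np.where(ivi["ivi"] >= t, ivi["ivi"], 0.0))
            .groupby("plot_id")["kept"].sum()
        )
        rows.append({"threshold": float(t), "mean_retained_pct": float(per_plot.mean())})
    return pd.DataFrame(rows)


def _align_labels(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise KeyError("partitions are over different site sets")
    b = b.reindex(a.index)
    return a.to_numpy(), b.to_numpy()


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two site partitions (ARI).

    Accepts mappings/Series keyed by site id (aligned by key) or plain
    sequences (aligned by position).
    """
    if isinstance(labels_a, (pd.Series, Mapping)) or isinstance(labels_b, (pd.Series, Mapping)):
        a, b = _align_labels(labels_a, labels_b)
    else:
        a, b = np.asarray(labels_a), np.asarray(labels_b)
        if a.shape != b.shape:
            raise KeyError("partitions have different lengths")
    if a.size < 2:
        raise ValueError("ARI requires at least 2 sites")
    return float(adjusted_rand_score(a, b))


def threshold_sensitivity(
    records: pd.DataFrame,
    thresholds: Sequence[float],
    clustering_params: Mapping | None = None,
) -> pd.DataFrame:
    """Pairwise ARI matrix between clusterings run at different IVI thresholds.

    Each threshold defines its own dominant-species matrix; the full
    clustering pipeline (turnover dissimilarity, order-randomized UPGMA,
    elbow or fixed k, singleton resolution) is run per threshold and the
    resulting partitions are compared on their common plots.
    """
    from .clustering import cluster_sites  # deferred: avoids import cycle at CLI level

    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds to compare")
    params = dict(clustering_params or {})
    ivi = compute_ivi(records)
    partitions = {}
    for t in thresholds:
        matrix = select_dominant(ivi, threshold_pct=t)
        partitions[t] = cluster_sites(matrix, **params).labels

    n = len(thresholds)
    out = pd.DataFrame(np.eye(n), index=list(thresholds), columns=list(thresholds))
    for i, ti in enumerate(thresholds):
        for j, tj in enumerate(thresholds):
            if j <= i:
                continue
            common = partitions[ti].index.intersection(partitions[tj].index)
            ari = adjusted_rand_index(partitions[ti].loc[common], partitions[tj].loc[common])
            out.iloc[i, j] = out.iloc[j, i] = ari
    return out
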