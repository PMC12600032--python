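"""Old-growth (OGF) vs secondary (SF) forest composition per cluster/ecosystem.

Proportions are computed over classified plots (in situ clusters) or pixels
(predicted ecosystems); units lacking a forest type are excluded from the
denominators.  ``compare_compositions`` contrasts the two views of the same
ecosystems: per-row absolute difference in OGF share, its mean and SD, and
a flag for rows where the dominant forest type inverts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

FOREST_TYPES = ("OGF", "SF")


def _proportions(types: pd.Series, group: pd.Series, unit: str) -> pd.DataFrame:
    valid = types.isin(FOREST_TYPES)
    if (~valid).any():
        logger.info("excluding %d %s(s) without a valid forest type", int((~valid).sum()), unit)
    types, group = types[valid], group[valid]
    counts = pd.crosstab(group, types).reindex(columns=FOREST_TYPES, fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals.index[totals == 0].tolist()
    if empty:
        logger.warning("omitting group(s) with no typed %ss: %s", unit, empty)
        counts = counts.loc[totals > 0]
        totals = totals[totals > 0]
    out = pd.DataFrame({
        "proportion_OGF": counts["OGF"] / totals,
        "proportion_SF": counts["SF"] / totals,
        "n_OGF": counts["OGF"],
        "n_SF": counts["SF"],
    })
    out.index.name = "ecosystem"
    return out


def composition_by_cluster(plot_metadata: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster OGF/SF plot shares from in situ plot metadata."""
    labels = pd.Series(labels)
    meta = plot_metadata.set_index("plot_id") if "plot_id" in plot_metadata.columns \
        else plot_metadata
    types = meta["forest_type"].reindex(labels.index)
    return _proportions(types, labels, unit="plot")


def composition_by_ecosystem(pixel_table: pd.DataFrame) -> pd.DataFrame:
    """Per-ecosystem OGF/SF pixel shares from a labeled pixel table."""
    if not {"ecosystem", "forest_type"} <= set(pixel_table.columns):
        raise DataError("pixel table must have ecosystem and forest_type columns")
    return _proportions(pixel_table["forest_type"], pixel_table["ecosystem"], unit="pixel")


def compare_compositions(a: pd.DataFrame, b: pd.DataFrame):
    """Per-ecosystem |ΔOGF| between two composition tables, with summary.

    Returns ``(per_row, summary)``: ``per_row`` has columns
    ``ogf_a, ogf_b, abs_diff, inversion`` over the shared ecosystems
    (inversion = the dominant forest type flips between the tables);
    ``summary`` is a dict with ``mean_abs_diff`` and ``sd_abs_diff``
    (sample SD).  Symmetric in its arguments.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise DataError("the two composition tables share no ecosystem ids")
    ogf_a = a.loc[shared, "proportion_OGF"]
    ogf_b = b.loc[shared, "proportion_OGF"]
    diff = (ogf_a - ogf_b).abs()
    inversion = (ogf_a - 0.5) * (ogf_b - 0.5) < 0
    per_row = pd.DataFrame({
        "ogf_a": ogf_a, "ogf_b": ogf_b,
        "abs_diff": diff, "inversion": inversion,
    })
    summary = {
        "mean_abs_diff": float(diff.mean()),
        "sd_abs_diff": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
        "n_inversions": int(inversion.sum()),
    }
    return per_row, summary


def composition_long(table: pd.DataFrame, source: str) -> pd.DataFrame:
    """Long-format (ecosystem, forest_type, proportion, source) export."""
    rows = []
    for eco, row in table.iterrows():
        for ft in FOREST_TYPES:
            rows.append({"ecosystem": eco, "forest_type": ft,
                         "proportion": row[f"proportion_{ft}"], "source": source})
    return pd.DataFrame(rows)
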