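"""Mitotic-age ("stopwatch") views of barcode methylation.

Barcodes start methylated in the progenitor and demethylate with divisions,
then freeze when a cell stops dividing and differentiates.  A cell type's
barcode methylation distribution therefore records when its cells exited
the division tree: early-exiting types (brainstem inhibitory neurons) stay
highly methylated, late-exiting types (outer cortical excitatory neurons,
glia) end up closer to the stationary level.  Descending barcode
methylation serves as the proxy time axis; no calibration to calendar age
is attempted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fcpg.barcode import MISSING, BarcodeMatrix

__all__ = ["type_methylation", "site_spectrum", "emergence_curves"]


def type_methylation(matrix: BarcodeMatrix, group_by: str = "subtype") -> pd.DataFrame:
    """Per-type barcode methylation summaries, ordered by mean (descending).

    Returns one row per type with n_cells, mean, std, min, median, max of
    per-cell mean methylation; row order ranks types from earliest-exiting
    (most methylated) to latest.
    """
    if group_by not in matrix.cells.columns:
        raise ValueError(f"unknown grouping column {group_by!r}")
    df = pd.DataFrame(
        {
            "type": matrix.cells[group_by].to_numpy(),
            "methylation": matrix.mean_methylation,
        }
    )
    out = (
        df.groupby("type")["methylation"]
        .agg(n_cells="count", mean="mean", std="std", min="min", median="median", max="max")
        .sort_values("mean", ascending=False)
    )
    return out


def site_spectrum(
    matrix: BarcodeMatrix,
    cell_ids: list[str] | None = None,
    bins: int = 20,
    methylated_cutoff: float = 0.8,
) -> dict:
    """Site-level methylation spectrum for a cell group.

    Computes each site's mean methylation over the group's non-missing
    entries, a histogram of those means, and the fraction of (covered)
    sites predominantly methylated (mean > ``methylated_cutoff``).
    """
    sub = matrix if cell_ids is None else matrix.subset_cells(cell_ids)
    if sub.n_cells == 0:
        raise ValueError("empty cell group")
    covered = sub.values != MISSING
    n = covered.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, (sub.values == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    defined = means[n > 0]
    hist, edges = np.histogram(defined, bins=bins, range=(0.0, 1.0))
    return {
        "site_means": pd.Series(means, index=sub.sites, name="mean_methylation"),
        "histogram": pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "n_sites": hist}),
        "fraction_predominantly_methylated": float((defined > methylated_cutoff).mean()) if len(defined) else float("nan"),
    }


def emergence_curves(matrix: BarcodeMatrix, group_by: str = "subtype") -> pd.DataFrame:
    """Cumulative emergence of each cell type along descending methylation.

    Cells are sorted by barcode methylation, descending (ties broken by cell
    id for reproducibility).  Walking down this proxy time axis, each type's
    curve gives the cumulative fraction of that type's cells seen so far: 0
    before the type appears, 1 once its adult content is reached.

    Returns a long table (type, methylation, cumulative_fraction), one row
    per cell, with rows of each type sorted by decreasing methylation.
    """
    df = pd.DataFrame(
        {
            "cell_id": matrix.cells.index,
            "type": matrix.cells[group_by].to_numpy(),
            "methylation": matrix.mean_methylation,
        }
    ).sort_values(["methylation", "cell_id"], ascending=[False, True], kind="mergesort")
    totals = df["type"].value_counts()
    df["rank_within_type"] = df.groupby("type").cumcount() + 1
    df["cumulative_fraction"] = df["rank_within_type"] / df["type"].map(totals)
    return df[["type", "methylation", "cumulative_fraction"]].reset_index(drop=True)
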