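"""Three-stage filter cascade selecting fluctuating CpG (fCpG) sites.

A site is "fluctuating" when its methylation is intermediate at every level
of aggregation: stage 1 keeps X-chromosome sites with bulk neuronal WGBS
mean in [0.25, 0.75]; stage 2 drops sites whose single-cell mean is <0.2 or
>0.8 in any of three groups (all cells, inhibitory neurons, excitatory
neurons) of one reference individual; stage 3 keeps sites with mean in
[0.3, 0.7] across all cells of a second individual.  All retention bounds
are inclusive: the discard conditions are strict inequalities, so boundary
values survive.

Sites whose group mean is undefined (fewer covered cells than ``min_cells``)
are discarded at that stage — a mean over a handful of sparse binary
observations cannot certify "fluctuating".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fcpg.barcode import MISSING, BarcodeMatrix

__all__ = ["SiteSet", "filter_bulk", "group_means", "filter_stage2", "filter_stage3", "select_sites"]

STAGE2_GROUPS = ("all", "inhibitory", "excitatory")


@dataclass
class SiteSet:
    """Ordered candidate sites with per-stage provenance flags.

    ``table`` has one row per stage-1 candidate site, sorted by (chrom, pos),
    with boolean columns passed_bulk / passed_stage2 / passed_stage3 and the
    group means used at each stage (NaN where undefined or not yet computed).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("passed_stage2", "passed_stage3"):
            if col not in t.columns:
                t[col] = False
        key = list(zip(t["chrom"], t["pos"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicate sites in SiteSet")
        if key != sorted(key):
            self.table = t.sort_values(["chrom", "pos"]).reset_index(drop=True)

    @property
    def keys(self) -> list[str]:
        """All stage-1 candidate site keys, 'chrom:pos'."""
        return [f"{c}:{p}" for c, p in zip(self.table["chrom"], self.table["pos"])]

    @property
    def final(self) -> list[str]:
        """Site keys passing all three stages."""
        t = self.table
        ok = t["passed_bulk"] & t["passed_stage2"] & t["passed_stage3"]
        return [f"{c}:{p}" for c, p in zip(t.loc[ok, "chrom"], t.loc[ok, "pos"])]

    def stage_counts(self) -> dict[str, int]:
        t = self.table
        s1 = t["passed_bulk"]
        s2 = s1 & t["passed_stage2"]
        s3 = s2 & t["passed_stage3"]
        return {"stage1": int(s1.sum()), "stage2": int(s2.sum()), "stage3": int(s3.sum())}

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path: str | Path) -> "SiteSet":
        t = pd.read_csv(path, sep="\t", na_values=["NA"])
        for col in ("passed_bulk", "passed_stage2", "passed_stage3"):
            if col in t.columns:
                t[col] = t[col].astype(bool)
        return cls(t)


def filter_bulk(bulk: pd.DataFrame, lo: float = 0.25, hi: float = 0.75) -> SiteSet:
    """Stage 1: retain sites with bulk mean methylation in [lo, hi].

    ``bulk`` is a table with columns chrom, pos, mean_methylation (one row
    per X-chromosome CpG site, from male bulk neuronal WGBS).
    """
    if len(bulk) == 0:
        raise ValueError("empty bulk table")
    t = bulk[["chrom", "pos", "mean_methylation"]].copy()
    t = t.rename(columns={"mean_methylation": "bulk_mean"})
    t["passed_bulk"] = (t["bulk_mean"] >= lo) & (t["bulk_mean"] <= hi)
    t = t[t["passed_bulk"]].reset_index(drop=True)
    return SiteSet(t)


def group_means(
    matrix: BarcodeMatrix,
    groups: Mapping[str, Sequence[str]],
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-site mean binary methylation for each named cell group.

    Returns a DataFrame indexed by site key with one column per group; the
    mean is over non-missing entries, NaN where fewer than ``min_cells``
    cells cover the site.
    """
    out = {}
    idx = matrix.cells.index
    for name, cell_ids in groups.items():
        rows = idx.get_indexer(list(cell_ids))
        if len(rows) == 0 or (rows < 0).any():
            raise ValueError(f"group {name!r} is empty or names unknown cells")
        vals = matrix.values[rows]
        covered = vals != MISSING
        n = covered.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = (vals == 1).sum(axis=0) / np.maximum(n, 1)
        mean = np.where(n >= min_cells, mean, np.nan)
        out[name] = mean
    return pd.DataFrame(out, index=pd.Index(matrix.sites, name="site"))


def _apply_stage(siteset: SiteSet, means: pd.DataFrame, flag: str, lo: float, hi: float) -> SiteSet:
    t = siteset.table.copy()
    keys = pd.Index([f"{c}:{p}" for c, p in zip(t["chrom"], t["pos"])])
    aligned = means.reindex(keys)
    # retain only when every group mean is defined and inside [lo, hi]
    inside = (aligned >= lo) & (aligned <= hi)
    ok = inside.all(axis=1) & aligned.notna().all(axis=1)
    prior = t["passed_bulk"].to_numpy()
    if flag == "passed_stage3":
        prior = prior & t["passed_stage2"].to_numpy()
    t[flag] = ok.to_numpy() & prior
    for col in aligned.columns:
        t[f"{flag.removeprefix('passed_')}_{col}_mean"] = aligned[col].to_numpy()
    return SiteSet(t)


def filter_stage2(siteset: SiteSet, ref_means: pd.DataFrame, lo: float = 0.2, hi: float = 0.8) -> SiteSet:
    """Stage 2: discard sites with mean <lo or >hi in ANY reference group.

    ``ref_means`` must carry columns 'all', 'inhibitory', 'excitatory'
    (single-cell group means in the stage-2 reference individual).  Sites
    undefined in any group are discarded.
    """
    missing = [g for g in STAGE2_GROUPS if g not in ref_means.columns]
    if missing:
        raise ValueError(f"stage-2 means missing group(s): {missing}")
    return _apply_stage(siteset, ref_means[list(STAGE2_GROUPS)], "passed_stage2", lo, hi)


def filter_stage3(siteset: SiteSet, ref_means: pd.DataFrame, lo: float = 0.3, hi: float = 0.7) -> SiteSet:
    """Stage 3: retain sites with all-cell mean in [lo, hi] in a second individual."""
    if "all" not in ref_means.columns:
        raise ValueError("stage-3 means must carry an 'all' column")
    return _apply_stage(siteset, ref_means[["all"]], "passed_stage3", lo, hi)


def select_sites(
    bulk: pd.DataFrame,
    stage2_matrix: BarcodeMatrix,
    stage3_matrix: BarcodeMatrix,
    bulk_bounds: tuple[float, float] = (0.25, 0.75),
    stage2_bounds: tuple[float, float] = (0.2, 0.8),
    stage3_bounds: tuple[float, float] = (0.3, 0.7),
    min_cells: int = 10,
) -> SiteSet:
    """Run the full cascade against two reference individuals' cell matrices.

    The stage-2 matrix supplies the three group means (all cells, inhibitory,
    excitatory); the stage-3 matrix supplies the all-cell mean of the second
    individual.
    """
    ss = filter_bulk(bulk, *bulk_bounds)
    cls = stage2_matrix.cells["major_class"]
    groups = {
        "all": list(stage2_matrix.cells.index),
        "inhibitory": list(cls[cls == "inhibitory"].index),
        "excitatory": list(cls[cls == "excitatory"].index),
    }
    m2 = group_means(stage2_matrix, groups, min_cells=min_cells)
    ss = filter_stage2(ss, m2, *stage2_bounds)
    m3 = group_means(stage3_matrix, {"all": list(stage3_matrix.cells.index)}, min_cells=min_cells)
    ss = filter_stage3(ss, m3, *stage3_bounds)
    return ss
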