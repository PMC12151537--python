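"""Ternary barcode matrix: binary methylation states with first-class missingness.

On a male X chromosome every covered fCpG site carries a haploid binary
state, so one read is enough to call it.  The barcode matrix holds cells ×
sites with entries 0 (unmethylated), 1 (methylated), and -1 (missing / not
covered).  Missing data is never imputed; every downstream statistic is
computed over the observed entries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Tuple

import numpy as np
import pandas as pd

from fcpg.io import MethylationCall

__all__ = ["MISSING", "BarcodeMatrix", "binarize", "build_matrix", "cell_summary", "barcode_complexity"]

MISSING: int = -1

ANNOTATION_COLUMNS = ["brain_id", "major_class", "subtype", "region"]


def binarize(mc: int, cov: int) -> int:
    """Call a binary methylation state from read counts.

    Returns 1 when the methylated fraction exceeds 0.5, 0 when below, and
    ``MISSING`` on an exact tie (discordant reads on a haploid chromosome
    signal technical error, so no majority call is forced).
    """
    if cov < 1:
        raise ValueError("coverage must be >= 1")
    if not 0 <= mc <= cov:
        raise ValueError(f"mc={mc} outside [0, cov={cov}]")
    if 2 * mc > cov:
        return 1
    if 2 * mc < cov:
        return 0
    return MISSING


@dataclass
class BarcodeMatrix:
    """Cells × fCpG-sites ternary matrix with cell annotations.

    Attributes
    ----------
    values
        int8 array of shape (n_cells, n_sites) with entries in {0, 1, -1}.
    cells
        DataFrame indexed by cell_id with columns brain_id, major_class,
        subtype, region (rows aligned with ``values``).
    sites
        Ordered site keys, ``"chrom:pos"`` strings aligned with columns.
    """

    values: np.ndarray
    cells: pd.DataFrame
    sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x sites)")
        if self.values.shape != (len(self.cells), len(self.sites)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.cells)} cells x {len(self.sites)} sites"
            )
        if not np.isin(self.values, (MISSING, 0, 1)).all():
            raise ValueError("barcode values must be in {0, 1, -1}")
        if self.cells.index.has_duplicates:
            raise ValueError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def n_covered(self) -> np.ndarray:
        """Per-cell count of non-missing entries."""
        return (self.values != MISSING).sum(axis=1)

    @property
    def mean_methylation(self) -> np.ndarray:
        """Per-cell mean of non-missing entries (NaN for zero-coverage cells)."""
        cov = self.n_covered
        meth = (self.values == 1).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)

    def subset_cells(self, cell_ids: Iterable[str]) -> "BarcodeMatrix":
        idx = self.cells.index.get_indexer(list(cell_ids))
        if (idx < 0).any():
            raise KeyError("unknown cell id(s) in subset")
        return BarcodeMatrix(self.values[idx], self.cells.iloc[idx].copy(), list(self.sites))

    def subset_sites(self, sites: Iterable[str]) -> "BarcodeMatrix":
        keep = list(sites)
        pos = {s: j for j, s in enumerate(self.sites)}
        cols = [pos[s] for s in keep]
        return BarcodeMatrix(self.values[:, cols], self.cells.copy(), keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BarcodeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.cells.index.tolist() == other.cells.index.tolist()
            and np.array_equal(self.values, other.values)
        )


def build_matrix(
    calls_per_cell: Mapping[str, Iterable[MethylationCall]],
    sites: Iterable[str],
    annotations: pd.DataFrame,
    min_sites_per_cell: int = 500,
    on_unannotated: str = "raise",
) -> Tuple[BarcodeMatrix, pd.DataFrame]:
    """Assemble the ternary barcode matrix from per-cell call streams.

    Parameters
    ----------
    calls_per_cell
        cell_id -> iterable of calls (e.g. from :func:`fcpg.io.read_allc`).
    sites
        Ordered fCpG site keys ("chrom:pos"); calls at other sites are ignored.
    annotations
        Cell annotation table indexed by cell_id.
    min_sites_per_cell
        Cells covering fewer fCpG sites are excluded (QC rule; the reference
        analyses require at least 500 covered sites per cell).
    on_unannotated
        "raise" (default) or "drop" for cells with calls but no annotation.

    Returns
    -------
    (matrix, qc)
        The matrix restricted to retained cells, and a QC table for *all*
        input cells (n_covered, mean_methylation, retained flag).
    """
    site_list = list(sites)
    site_index = {s: j for j, s in enumerate(site_list)}
    rows: list[np.ndarray] = []
    ids: list[str] = []
    qc_records = []
    for cell_id, calls in calls_per_cell.items():
        if cell_id not in annotations.index:
            if on_unannotated == "drop":
                continue
            raise KeyError(f"cell {cell_id!r} has calls but no annotation")
        row = np.full(len(site_list), MISSING, dtype=np.int8)
        for call in calls:
            j = site_index.get(f"{call.chrom}:{call.pos}")
            if j is not None:
                row[j] = binarize(call.mc, call.cov)
        covered = int((row != MISSING).sum())
        mean_m = float((row == 1).sum() / covered) if covered else float("nan")
        retained = covered >= min_sites_per_cell
        qc_records.append((cell_id, covered, mean_m, retained))
        if retained:
            rows.append(row)
            ids.append(cell_id)
    qc = pd.DataFrame(qc_records, columns=["cell_id", "n_covered", "mean_methylation", "retained"]).set_index(
        "cell_id"
    )
    values = np.vstack(rows) if rows else np.empty((0, len(site_list)), dtype=np.int8)
    cells = annotations.loc[ids, ANNOTATION_COLUMNS].copy()
    return BarcodeMatrix(values, cells, site_list), qc


def cell_summary(matrix: BarcodeMatrix) -> pd.DataFrame:
    """Per-cell coverage and methylation summary, one row per retained cell."""
    out = matrix.cells.copy()
    out["n_covered"] = matrix.n_covered
    out["mean_methylation"] = matrix.mean_methylation
    return out


def barcode_complexity(n_sites: int) -> float:
    """Number of distinct states of an n-site binary barcode (2**n as float).

    A 100-site barcode has ~1.27e30 states — ample to distinguish the
    billions of cells in a human brain.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    return float(2**n_sites)
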