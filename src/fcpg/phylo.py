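"""Tree building and binary-alignment export for barcode phylogenies.

Barcodes are exported as binary alignments (symbols 0/1/-, '-' = missing)
in relaxed PHYLIP and FASTA for external maximum-likelihood inference — the
intended engine is IQ-TREE with the two-state GTR2+FO+G4 model, which
accommodates back-mutation and missing data; a ready-to-run command line is
written next to the alignment.  The in-repo tree method is neighbor joining
on the PWD matrix, optionally rooted by an artificial fully methylated
progenitor taxon (the inferred barcode start state).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from fcpg.barcode import MISSING, BarcodeMatrix
from fcpg.distance import pwd_matrix

__all__ = [
    "BinaryAlignment",
    "TreeResult",
    "export_alignment",
    "read_alignment",
    "nj_tree",
    "read_tree",
    "write_tree",
    "rf_distance",
]

PROGENITOR = "PROGENITOR"
SYMBOLS = {0: "0", 1: "1", MISSING: "-"}


@dataclass
class BinaryAlignment:
    """Cells x sites binary characters with '-' for missing."""

    taxa: list[str]
    rows: list[str]
    sites: list[str]
    name_map: dict[str, str]  # sanitized -> original cell id

    def to_matrix(self) -> np.ndarray:
        inv = {"0": 0, "1": 1, "-": MISSING}
        return np.array([[inv[c] for c in row] for row in self.rows], dtype=np.int8)


@dataclass
class TreeResult:
    newick: str
    name_map: dict[str, str]  # leaf label -> cell id

    @property
    def tree(self) -> TreeNode:
        # convert_underscores off: cell ids routinely contain underscores
        return TreeNode.read([self.newick], convert_underscores=False)


def _sanitize(cell_ids: list[str]) -> dict[str, str]:
    name_map: dict[str, str] = {}
    for cid in cell_ids:
        clean = re.sub(r"[^0-9A-Za-z_]", "_", cid)
        if clean in name_map:
            raise ValueError(f"duplicate sanitized taxon id {clean!r}")
        name_map[clean] = cid
    return name_map


def export_alignment(
    matrix: BarcodeMatrix,
    out_prefix: str | Path,
    subsample: Optional[int] = None,
    seed: int = 0,
    bootstraps: int = 1000,
) -> BinaryAlignment:
    """Write relaxed PHYLIP + FASTA binary alignments (and the ML command).

    ``subsample`` draws that many cells, stratified by subtype
    (proportional allocation, seeded) so exported trees stay
    phenotype-diverse.  Files written: ``<prefix>.phy``, ``<prefix>.fasta``,
    ``<prefix>.names.tsv`` (sanitized-id map) and ``<prefix>.iqtree.sh``
    recording the external GTR2+FO+G4 model invocation.
    """
    if matrix.n_cells < 4:
        raise ValueError("need at least 4 cells to export an alignment worth a tree")
    cells = matrix.cells
    if subsample is not None:
        if subsample > matrix.n_cells:
            raise ValueError("subsample exceeds number of cells")
        rng = np.random.default_rng(seed)
        chosen: list[str] = []
        frac = subsample / matrix.n_cells
        for _, group in cells.groupby("subtype", sort=True):
            k = int(round(len(group) * frac))
            k = min(len(group), max(1, k))
            idx = rng.choice(len(group), size=k, replace=False)
            chosen.extend(group.index[sorted(idx)])
        matrix = matrix.subset_cells(chosen[:subsample] if len(chosen) > subsample else chosen)
    name_map = _sanitize(list(matrix.cells.index))
    taxa = list(name_map)
    rows = ["".join(SYMBOLS[v] for v in matrix.values[i]) for i in range(matrix.n_cells)]
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    width = max(len(t) for t in taxa) + 2
    with open(f"{out_prefix}.phy", "wt") as fh:
        fh.write(f"{len(taxa)} {matrix.n_sites}\n")
        for t, row in zip(taxa, rows):
            fh.write(f"{t:<{width}}{row}\n")
    with open(f"{out_prefix}.fasta", "wt") as fh:
        for t, row in zip(taxa, rows):
            fh.write(f">{t}\n{row}\n")
    pd.Series(name_map, name="cell_id").rename_axis("taxon").to_csv(f"{out_prefix}.names.tsv", sep="\t")
    with open(f"{out_prefix}.iqtree.sh", "wt") as fh:
        fh.write(
            f"iqtree2 -s {out_prefix.name}.phy -st BIN -m GTR2+FO+G4 -b {bootstraps} "
            f"-seed {seed} -pre {out_prefix.name}\n"
        )
    return BinaryAlignment(taxa, rows, list(matrix.sites), name_map)


def read_alignment(path: str | Path) -> BinaryAlignment:
    """Read a relaxed-PHYLIP binary alignment written by :func:`export_alignment`."""
    lines = Path(path).read_text().splitlines()
    n, s = (int(x) for x in lines[0].split())
    taxa, rows = [], []
    for line in lines[1 : n + 1]:
        name, row = line.split(None, 1)
        taxa.append(name)
        rows.append(row.strip())
        if len(rows[-1]) != s:
            raise ValueError(f"{path}: row for {name} has {len(rows[-1])} characters, expected {s}")
    return BinaryAlignment(taxa, rows, sites=[], name_map={t: t for t in taxa})


def nj_tree(
    distances: pd.DataFrame,
    matrix: Optional[BarcodeMatrix] = None,
    min_shared: int = 30,
    root_at_progenitor: bool = False,
    min_partners: int = 3,
) -> TreeResult:
    """Neighbor-joining tree from a (possibly incomplete) PWD matrix.

    Parameters
    ----------
    distances
        Square DataFrame from :func:`fcpg.distance.pwd_matrix` (NaN where a
        pair lacked qualifying overlap), or None to compute it from
        ``matrix``.
    matrix
        Needed when ``distances`` is None or for progenitor rooting.
    root_at_progenitor
        Adds an artificial fully methylated progenitor taxon whose distance
        to each cell is that cell's unmethylated fraction, then roots there —
        the barcode's inferred start state.
    min_partners
        Cells with fewer finite off-diagonal distances are dropped (and the
        remaining NaNs imputed as the mean of the two cells' observed
        distances).
    """
    if distances is None:
        if matrix is None:
            raise ValueError("need distances or a barcode matrix")
        distances, _ = pwd_matrix(matrix, min_shared=min_shared)
    D = distances.to_numpy(dtype=float, copy=True)
    ids = list(distances.index)
    off = D.copy()
    np.fill_diagonal(off, np.nan)
    usable = np.array([(np.isfinite(off[i])).sum() >= min_partners for i in range(len(ids))])
    if usable.sum() < 4:
        raise ValueError("fewer than 4 cells with enough qualifying distances")
    D = D[np.ix_(usable, usable)]
    ids = [i for i, u in zip(ids, usable) if u]
    row_mean = np.nanmean(np.where(np.eye(len(ids), dtype=bool), np.nan, D), axis=1)
    nan_i, nan_j = np.where(~np.isfinite(D))
    D[nan_i, nan_j] = (row_mean[nan_i] + row_mean[nan_j]) / 2.0
    name_map = _sanitize(ids)
    taxa = list(name_map)
    if root_at_progenitor:
        if matrix is None:
            raise ValueError("progenitor rooting needs the barcode matrix")
        sub = matrix.subset_cells(ids)
        prog_d = 1.0 - sub.mean_methylation  # mismatch fraction vs the all-methylated barcode
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = prog_d
        D[:-1, -1] = prog_d
        taxa = taxa + [PROGENITOR]
        name_map[PROGENITOR] = PROGENITOR
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    tree = nj(DistanceMatrix(D, ids=taxa), neg_as_zero=True)
    if root_at_progenitor:
        prog = tree.find(PROGENITOR)
        tree = tree.root_at(prog.parent if prog.parent is not None else prog)
    return TreeResult(newick=str(tree).strip(), name_map=name_map)


def read_tree(path: str | Path) -> TreeResult:
    """Read a newick file (e.g. an external ML .treefile)."""
    tree = TreeNode.read(str(path), convert_underscores=False)
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        raise ValueError(f"{path}: duplicate leaf labels")
    return TreeResult(newick=str(tree).strip(), name_map={t: t for t in labels})


def write_tree(result: TreeResult, path: str | Path) -> None:
    Path(path).write_text(result.newick + "\n")


def rf_distance(a: TreeResult | TreeNode, b: TreeResult | TreeNode) -> float:
    """Normalized Robinson-Foulds distance in [0, 1].

    The symmetric bipartition difference divided by its maximum 2(n-3); 0
    for identical topologies, 1 for fully incompatible binary resolutions.
    """
    ta = a.tree if isinstance(a, TreeResult) else a
    tb = b.tree if isinstance(b, TreeResult) else b
    taxa_a = {t.name for t in ta.tips()}
    taxa_b = {t.name for t in tb.tips()}
    if taxa_a != taxa_b:
        raise ValueError("trees are over different taxon sets")
    n = len(taxa_a)
    if n < 4:
        return 0.0
    raw = ta.compare_rfd(tb, rooted=False)
    return float(min(1.0, raw / (2 * (n - 3))))
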