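"""Lineage simulator: fCpG barcode dynamics on cell-division trees.

Model
-----
Each individual is one division tree rooted at a progenitor whose barcode is
fully methylated.  At every division each site flips independently:
methylated -> unmethylated with probability ``p_demeth``, unmethylated ->
methylated with probability ``p_remeth``.  Writing lambda = 1 - p_demeth -
p_remeth and pi = p_remeth / (p_demeth + p_remeth), the expected methylated
fraction after k divisions from a methylated start is the closed form

    m_k = pi + (1 - pi) * lambda**k

Cell types exit the tree at scheduled depths and their barcodes freeze;
sequencing sparsity is emulated by masking each site independently with
probability 1 - coverage_rate (single-read semantics).  Regions are placed
either by inheritance from the lineage (radial migration: related cells
share a region) or at random on exit (tangential migration).

Closed-form and matrix-power oracles (``expected_methylation``,
``expected_pwd``) are exact under this model and back every downstream
validation; ``fit_flip_rates`` inverts m_k by least squares to recover the
generating rates from per-type mean methylation at known exit depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from fcpg.barcode import MISSING, BarcodeMatrix
from fcpg.io import MethylationCall, write_allc

__all__ = [
    "TypeSpec",
    "SimParams",
    "LineageTruth",
    "SimResult",
    "simulate",
    "expected_methylation",
    "expected_pwd",
    "fit_flip_rates",
    "make_fixture",
    "paper_like_params",
    "tiny_params",
]

CORTICAL_REGIONS = ("FC", "TC", "OC", "PC")


@dataclass(frozen=True)
class TypeSpec:
    """One cell type's exit schedule.

    Cells of this type leave the division tree at a depth drawn uniformly
    from ``depth_range`` (inclusive).  ``placement`` controls the region
    label: "inherit_region" derives it from the lineage path (radial
    migration), "random_region" draws it uniformly on exit (tangential).
    """

    label: str
    major_class: str
    depth_range: tuple[int, int]
    n_cells: int
    regions: tuple[str, ...] = CORTICAL_REGIONS
    placement: Literal["inherit_region", "random_region"] = "random_region"


@dataclass(frozen=True)
class SimParams:
    n_sites: int = 5000
    p_demeth: float = 0.05
    p_remeth: float = 0.05
    type_schedule: tuple[TypeSpec, ...] = ()
    coverage_rate: float = 0.1
    read_error_rate: float = 0.0
    n_individuals: int = 1
    chrom: str = "chrX"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_demeth <= 1 and 0 <= self.p_remeth <= 1):
            raise ValueError("flip probabilities must be in [0, 1]")
        if not 0 < self.coverage_rate <= 1:
            raise ValueError("coverage_rate must be in (0, 1]")
        if self.n_sites < 1 or self.n_individuals < 1:
            raise ValueError("n_sites and n_individuals must be positive")
        for spec in self.type_schedule:
            lo, hi = spec.depth_range
            if lo < 0 or hi < lo:
                raise ValueError(f"bad depth range for {spec.label}: {spec.depth_range}")
            if spec.n_cells < 1:
                raise ValueError(f"n_cells must be positive for {spec.label}")


@dataclass
class LineageTruth:
    """Ground truth for one simulation: lineages, exit depths, true barcodes.

    ``cells`` is indexed by cell id with columns individual, subtype,
    major_class, region, exit_depth; ``paths`` maps cell id to its division
    path from the root (tuple of 0/1 branch choices, length = exit depth);
    ``true_barcodes`` are the pre-masking binary states aligned with
    ``cells`` rows.
    """

    cells: pd.DataFrame
    paths: dict[str, tuple[int, ...]]
    true_barcodes: np.ndarray
    params: SimParams

    def divergence_depth(self, cell_a: str, cell_b: str) -> Optional[int]:
        """Depth of the most recent common ancestor (None across individuals)."""
        if self.cells.loc[cell_a, "individual"] != self.cells.loc[cell_b, "individual"]:
            return None
        pa, pb = self.paths[cell_a], self.paths[cell_b]
        k = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            k += 1
        return k

    def newick(self, individual: str) -> str:
        """True lineage tree of one individual's sampled cells (branch lengths in divisions)."""
        cells = self.cells[self.cells["individual"] == individual]
        if len(cells) == 0:
            raise ValueError(f"no cells for individual {individual!r}")
        by_path: dict[tuple[int, ...], list[str]] = {}
        children: dict[tuple[int, ...], set[tuple[int, ...]]] = {}
        for cid in cells.index:
            p = self.paths[cid]
            by_path.setdefault(p, []).append(cid)
            for i in range(len(p)):
                children.setdefault(p[:i], set()).add(p[: i + 1])

        def render(prefix: tuple[int, ...], edge_len: int) -> str:
            kids = sorted(children.get(prefix, ()))
            cells_here = by_path.get(prefix, [])
            # collapse pass-through nodes (one child, no sampled cell)
            while len(kids) == 1 and not cells_here:
                prefix = kids[0]
                edge_len += 1
                kids = sorted(children.get(prefix, ()))
                cells_here = by_path.get(prefix, [])
            if not kids:  # trie leaf always holds exactly one cell
                return f"{cells_here[0]}:{edge_len}"
            parts = [render(k, 1) for k in kids]
            if cells_here:  # cell that exited at an internal node: zero-length pendant
                parts.append(f"{cells_here[0]}:0")
            return f"({','.join(parts)}):{edge_len}"

        return render((), 0) + ";"


@dataclass
class SimResult:
    matrix: BarcodeMatrix
    truth: LineageTruth

    def write_allc_bundle(self, out_dir: str | Path) -> Path:
        """Write per-cell allc files, the annotation TSV and truth newicks."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        m = self.matrix
        positions = [int(s.split(":")[1]) for s in m.sites]
        chroms = [s.split(":")[0] for s in m.sites]
        allc_dir = out / "allc"
        allc_dir.mkdir(exist_ok=True)
        for i, cid in enumerate(m.cells.index):
            row = m.values[i]
            calls = [
                MethylationCall(chroms[j], positions[j], "+", "CGN", int(row[j]), 1)
                for j in np.flatnonzero(row != MISSING)
            ]
            write_allc(allc_dir / f"{cid}.allc.tsv", calls)
        ann = m.cells.copy()
        ann.index.name = "cell_id"
        ann.reset_index().to_csv(out / "annotations.tsv", sep="\t", index=False)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        t = self.truth.cells.copy()
        t["path"] = [("".join(map(str, self.truth.paths[c]))) for c in t.index]
        t.to_csv(truth_dir / "cells.tsv", sep="\t")
        for ind in sorted(set(t["individual"])):
            (truth_dir / f"{ind}.nwk").write_text(self.truth.newick(ind) + "\n")
        return out


def _transition_matrix(p_demeth: float, p_remeth: float) -> np.ndarray:
    # state order (0 = unmethylated, 1 = methylated)
    return np.array([[1 - p_remeth, p_remeth], [p_demeth, 1 - p_demeth]])


def expected_methylation(k: int, params: SimParams) -> float:
    """Closed-form methylated fraction after k divisions from a methylated start."""
    if k < 0:
        raise ValueError("k must be >= 0")
    total = params.p_demeth + params.p_remeth
    if total == 0:
        return 1.0
    pi = params.p_remeth / total
    lam = 1.0 - total
    return pi + (1.0 - pi) * lam**k


def expected_pwd(depth_a: int, depth_b: int, split_depth: int, params: SimParams) -> float:
    """Expected per-site mismatch probability between two cells.

    The cells share ancestry down to ``split_depth`` divisions from the
    (fully methylated) root, then evolve independently to depths ``depth_a``
    and ``depth_b``.  Computed by brute-force two-state transition-matrix
    powers, with no closed-form shortcut, so it serves as an independent
    oracle for simulated PWDs.
    """
    if split_depth > min(depth_a, depth_b) or split_depth < 0:
        raise ValueError("split_depth must be in [0, min(depth_a, depth_b)]")
    T = _transition_matrix(params.p_demeth, params.p_remeth)
    at_split = np.array([0.0, 1.0]) @ np.linalg.matrix_power(T, split_depth)
    Ta = np.linalg.matrix_power(T, depth_a - split_depth)
    Tb = np.linalg.matrix_power(T, depth_b - split_depth)
    mismatch = 0.0
    for s in (0, 1):
        mismatch += at_split[s] * (Ta[s, 0] * Tb[s, 1] + Ta[s, 1] * Tb[s, 0])
    return float(mismatch)


def _flip(states: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(states.shape)
    demeth = (states == 1) & (u < params.p_demeth)
    remeth = (states == 0) & (u < params.p_remeth)
    out = states.copy()
    out[demeth] = 0
    out[remeth] = 1
    return out


def _sample_paths(spec: TypeSpec, rng: np.random.Generator, used: set[tuple[int, ...]]) -> list[tuple[int, ...]]:
    lo, hi = spec.depth_range
    if spec.n_cells > sum(2**d for d in range(lo, hi + 1)):
        raise ValueError(
            f"type {spec.label}: {spec.n_cells} cells demanded in depth range {spec.depth_range} "
            f"but the tree has only {sum(2**d for d in range(lo, hi + 1))} lineages there"
        )
    depths = rng.integers(lo, hi + 1, size=spec.n_cells)
    # depths are drawn uniformly; excess cells beyond a depth's leaf count are
    # pushed to the nearest deeper (or shallower) depth with spare capacity
    counts = pd.Series(depths).value_counts().to_dict()
    for d in sorted(counts):
        while counts[d] > 2**d:
            candidates = [e for e in range(lo, hi + 1) if counts.get(e, 0) < 2**e]
            target = min(candidates, key=lambda e: (abs(e - d), e))
            moved = np.flatnonzero(depths == d)[-1]
            depths[moved] = target
            counts[d] -= 1
            counts[target] = counts.get(target, 0) + 1
    paths = []
    for d in depths:
        for _ in range(10000):
            p = tuple(int(b) for b in rng.integers(0, 2, size=int(d)))
            if p not in used:
                used.add(p)
                paths.append(p)
                break
        else:
            raise ValueError(f"type {spec.label}: could not place a cell at depth {d} (tree exhausted)")
    return paths


def _region_for(spec: TypeSpec, path: tuple[int, ...], rng: np.random.Generator) -> str:
    if spec.placement == "random_region":
        return spec.regions[int(rng.integers(0, len(spec.regions)))]
    # inherit_region: the region is a deterministic function of the earliest
    # lineage branches, so cells with a recent common ancestor co-locate
    n_bits = max(1, int(np.ceil(np.log2(max(len(spec.regions), 2)))))
    bits = path[:n_bits]
    idx = 0
    for b in bits:
        idx = (idx << 1) | b
    return spec.regions[idx % len(spec.regions)]


def simulate(params: SimParams) -> SimResult:
    """Run the simulator; deterministic for a fixed ``params.seed``.

    Returns the observed (coverage-masked) barcode matrix over all sampled
    cells of all individuals, plus the ground truth.
    """
    if not params.type_schedule:
        raise ValueError("type_schedule is empty")
    rng = np.random.default_rng(params.seed)
    all_rows, ann_rows, truth_rows = [], [], []
    paths_by_cell: dict[str, tuple[int, ...]] = {}
    true_rows = []
    for ind_i in range(params.n_individuals):
        ind = f"sim{ind_i:02d}"
        used: set[tuple[int, ...]] = set()
        cells: list[tuple[str, TypeSpec, tuple[int, ...]]] = []
        for spec in params.type_schedule:
            for j, p in enumerate(_sample_paths(spec, rng, used)):
                cells.append((f"{ind}_{spec.label}_{j:04d}", spec, p))
        # DFS over the trie of sampled paths, evolving one barcode per edge
        children: dict[tuple[int, ...], set[tuple[int, ...]]] = {}
        at_node: dict[tuple[int, ...], list[int]] = {}
        for idx, (_, _, p) in enumerate(cells):
            at_node.setdefault(p, []).append(idx)
            for i in range(len(p)):
                children.setdefault(p[:i], set()).add(p[: i + 1])
        barcodes = np.empty((len(cells), params.n_sites), dtype=np.int8)
        stack: list[tuple[tuple[int, ...], np.ndarray]] = [((), np.ones(params.n_sites, dtype=np.int8))]
        while stack:
            prefix, state = stack.pop()
            for idx in at_node.get(prefix, ()):
                barcodes[idx] = state
            for child in sorted(children.get(prefix, ())):
                stack.append((child, _flip(state, params, rng)))
        # observe: mask coverage, optionally flip read errors
        mask = rng.random(barcodes.shape) < params.coverage_rate
        observed = np.where(mask, barcodes, MISSING).astype(np.int8)
        if params.read_error_rate > 0:
            err = mask & (rng.random(barcodes.shape) < params.read_error_rate)
            observed[err] = 1 - observed[err]
        for idx, (cid, spec, p) in enumerate(cells):
            region = _region_for(spec, p, rng)
            ann_rows.append((cid, ind, spec.major_class, spec.label, region))
            truth_rows.append((cid, ind, spec.label, spec.major_class, region, len(p)))
            paths_by_cell[cid] = p
        all_rows.append(observed)
        true_rows.append(barcodes)
    positions = 10_000 + 2 * np.arange(params.n_sites)
    sites = [f"{params.chrom}:{p}" for p in positions]
    ann = pd.DataFrame(ann_rows, columns=["cell_id", "brain_id", "major_class", "subtype", "region"]).set_index(
        "cell_id"
    )
    matrix = BarcodeMatrix(np.vstack(all_rows), ann, sites)
    truth_cells = pd.DataFrame(
        truth_rows, columns=["cell_id", "individual", "subtype", "major_class", "region", "exit_depth"]
    ).set_index("cell_id")
    truth = LineageTruth(truth_cells, paths_by_cell, np.vstack(true_rows), params)
    return SimResult(matrix, truth)


def fit_flip_rates(depths: Sequence[float], mean_methylation: Sequence[float]) -> tuple[float, float]:
    """Recover (p_demeth, p_remeth) from mean methylation at known depths.

    Least-squares fit of m_k = pi + (1 - pi) * lambda**k; needs observations
    at >= 2 distinct depths spanning the transient.
    """
    k = np.asarray(depths, dtype=float)
    m = np.asarray(mean_methylation, dtype=float)
    if len(k) < 2 or len(set(k.tolist())) < 2:
        raise ValueError("need mean methylation at >= 2 distinct depths")

    def resid(theta: np.ndarray) -> np.ndarray:
        pd_, pm_ = theta
        pi = pm_ / (pd_ + pm_)
        lam = 1.0 - pd_ - pm_
        return pi + (1.0 - pi) * np.sign(lam) * np.abs(lam) ** k - m

    fit = least_squares(resid, x0=np.array([0.05, 0.05]), bounds=([1e-6, 1e-6], [0.999, 0.999]))
    return float(fit.x[0]), float(fit.x[1])


def tiny_params(seed: int = 0) -> SimParams:
    """8 cells x 60 sites, full-ish coverage: hand-checkable smoke fixture."""
    return SimParams(
        n_sites=60,
        p_demeth=0.05,
        p_remeth=0.05,
        coverage_rate=0.9,
        n_individuals=1,
        seed=seed,
        type_schedule=(
            TypeSpec("PN", "inhibitory", (2, 3), 4, ("SC",), "inherit_region"),
            TypeSpec("L2_3", "excitatory", (4, 5), 4, CORTICAL_REGIONS, "inherit_region"),
        ),
    )


def paper_like_params(seed: int = 0, scale: float = 1.0) -> SimParams:
    """Three independent individuals with a caudal-to-rostral exit schedule.

    Defaults: 5,000 sites, symmetric flip rates 0.05/division (stationary
    methylation 0.5), coverage 0.1 (~500 covered sites per cell, ~50 shared
    sites per pair), ~2,000 cells per individual spanning exit depths 2-20:
    brainstem/thalamic inhibitory neurons exit shallow, cortical
    interneurons intermediate (regions randomized: tangential migration),
    cortical excitatory neurons deep (regions inherited: radial migration),
    glia deepest.  ``scale`` multiplies per-type cell counts only.
    """

    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    return SimParams(
        n_sites=5000,
        p_demeth=0.05,
        p_remeth=0.05,
        coverage_rate=0.1,
        n_individuals=3,
        seed=seed,
        type_schedule=(
            TypeSpec("PN_early", "inhibitory", (2, 4), n(12), ("SC",), "inherit_region"),
            TypeSpec("PN", "inhibitory", (6, 9), n(150), ("SC",), "inherit_region"),
            TypeSpec("THM", "inhibitory", (7, 10), n(150), ("SC",), "inherit_region"),
            TypeSpec("MSN", "inhibitory", (8, 11), n(120), ("SC",), "inherit_region"),
            TypeSpec("Pvalb", "inhibitory", (9, 13), n(240), CORTICAL_REGIONS, "random_region"),
            TypeSpec("Sst", "inhibitory", (9, 13), n(240), CORTICAL_REGIONS, "random_region"),
            TypeSpec("L4_6", "excitatory", (11, 15), n(360), CORTICAL_REGIONS, "inherit_region"),
            TypeSpec("L2_3", "excitatory", (14, 18), n(420), CORTICAL_REGIONS, "inherit_region"),
            TypeSpec("ASC", "non-neuronal", (16, 20), n(150), CORTICAL_REGIONS, "random_region"),
            TypeSpec("ODC", "non-neuronal", (16, 20), n(150), CORTICAL_REGIONS, "random_region"),
        ),
    )


def make_fixture(preset: str, seed: int = 0, out_dir: str | Path | None = None) -> SimResult:
    """Build a named fixture ("tiny" or "paper_like"); optionally write it to disk."""
    if preset == "tiny":
        params = tiny_params(seed)
    elif preset == "paper_like":
        params = paper_like_params(seed)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    result = simulate(params)
    if out_dir is not None:
        result.write_allc_bundle(out_dir)
    return result
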