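"""Pairwise differences (PWD) between cell barcodes.

The PWD of a cell pair is the Hamming mismatch fraction over the sites
covered in both cells.  A pair is comparable only when it shares at least
``min_shared`` covered sites (default 30); pairs below the gate are excluded,
not errored.  PWD 0 means identical barcodes; independent Bernoulli(0.5)
barcodes give PWD 0.5, the randomization limit.

The production kernel bit-packs each cell's (state, coverage-mask) into
uint64 words and counts mismatches with hardware popcount
(``numpy.bitwise_count``); its correctness is certified in the test suite
against the naive double loop implemented here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from fcpg.barcode import MISSING, BarcodeMatrix

__all__ = ["PairDistance", "PairResult", "pwd", "all_pairs", "cross_brain_pairs", "pwd_matrix", "pairs_naive"]


class PairDistance(NamedTuple):
    cell_a: str
    cell_b: str
    n_shared: int
    n_mismatch: int
    pwd: float
    same_brain: bool


@dataclass
class PairResult:
    """Pair table plus streaming summary of one all-pairs computation.

    ``pairs`` holds the stored pairs (all qualifying pairs, or only those
    under a PWD cutoff when ``store`` was restricted); the summary always
    reflects every pair examined.
    """

    pairs: pd.DataFrame
    n_pairs_total: int
    n_qualifying: int
    mean_pwd: float
    mean_n_shared: float
    store: str = "all"

    @property
    def summary(self) -> dict:
        return {
            "n_pairs_total": self.n_pairs_total,
            "n_qualifying": self.n_qualifying,
            "mean_pwd": self.mean_pwd,
            "mean_n_shared": self.mean_n_shared,
        }


def pwd(
    barcode_a: np.ndarray,
    barcode_b: np.ndarray,
    min_shared: int = 30,
) -> Optional[Tuple[int, int, float]]:
    """PWD between two ternary site vectors over the same site set.

    Returns ``(n_shared, n_mismatch, pwd)`` or ``None`` when fewer than
    ``min_shared`` sites are covered in both cells.
    """
    a = np.asarray(barcode_a)
    b = np.asarray(barcode_b)
    if a.shape != b.shape:
        raise ValueError("barcodes are over different site sets")
    shared = (a != MISSING) & (b != MISSING)
    n_shared = int(shared.sum())
    if n_shared < min_shared:
        return None
    n_mismatch = int((a[shared] != b[shared]).sum())
    return n_shared, n_mismatch, n_mismatch / n_shared


def _pack(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bit-pack states and coverage masks into (n_cells, n_words) uint64."""
    n, s = values.shape
    width = -(-s // 64) * 64
    pad = width - s
    state = np.pad((values == 1), ((0, 0), (0, pad)))
    mask = np.pad((values != MISSING), ((0, 0), (0, pad)))
    S = np.ascontiguousarray(np.packbits(state, axis=1, bitorder="little")).view(np.uint64)
    K = np.ascontiguousarray(np.packbits(mask, axis=1, bitorder="little")).view(np.uint64)
    return S, K


class _Accumulator:
    """Streams pair blocks into summary totals and a (possibly filtered) store."""

    def __init__(self, min_shared: int, store: str, close_threshold: float):
        self.min_shared = min_shared
        self.store = store
        self.close_threshold = close_threshold
        self.n_total = 0
        self.n_qual = 0
        self.sum_pwd = 0.0
        self.sum_shared = 0
        self.blocks: list[pd.DataFrame] = []

    def add(self, ids_a, ids_b, shared, mism, same_brain) -> None:
        self.n_total += len(shared)
        qual = shared >= self.min_shared
        self.n_qual += int(qual.sum())
        d = mism[qual] / shared[qual]
        self.sum_pwd += float(d.sum())
        self.sum_shared += int(shared[qual].sum())
        if self.store == "all":
            keep = qual
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                keep = qual & (mism / np.maximum(shared, 1) < self.close_threshold)
        if keep.any():
            self.blocks.append(
                pd.DataFrame(
                    {
                        "cell_a": np.asarray(ids_a)[keep],
                        "cell_b": np.asarray(ids_b)[keep],
                        "n_shared": shared[keep],
                        "n_mismatch": mism[keep],
                        "pwd": mism[keep] / shared[keep],
                        "same_brain": np.asarray(same_brain)[keep],
                    }
                )
            )

    def result(self) -> PairResult:
        pairs = (
            pd.concat(self.blocks, ignore_index=True)
            if self.blocks
            else pd.DataFrame(columns=["cell_a", "cell_b", "n_shared", "n_mismatch", "pwd", "same_brain"])
        )
        return PairResult(
            pairs=pairs,
            n_pairs_total=self.n_total,
            n_qualifying=self.n_qual,
            mean_pwd=self.sum_pwd / self.n_qual if self.n_qual else float("nan"),
            mean_n_shared=self.sum_shared / self.n_qual if self.n_qual else float("nan"),
            store=self.store,
        )


def all_pairs(
    matrix: BarcodeMatrix,
    min_shared: int = 30,
    store: str = "all",
    close_threshold: float = 0.05,
) -> PairResult:
    """PWD over every unordered cell pair of one matrix.

    Parameters
    ----------
    matrix
        Barcode matrix (>= 2 cells for a non-empty result).
    min_shared
        Minimum mutually covered sites for a pair to qualify.
    store
        "all" stores every qualifying pair; "close" stores only pairs with
        pwd < ``close_threshold`` (summaries still cover all pairs) — use
        this for large matrices where the full pair table is not needed.
    """
    if store not in ("all", "close"):
        raise ValueError("store must be 'all' or 'close'")
    S, K = _pack(matrix.values)
    ids = np.asarray(matrix.cells.index)
    brains = np.asarray(matrix.cells["brain_id"])
    acc = _Accumulator(min_shared, store, close_threshold)
    n = matrix.n_cells
    for i in range(n - 1):
        m = K[i] & K[i + 1 :]
        shared = np.bitwise_count(m).sum(axis=1).astype(np.int64)
        mism = np.bitwise_count((S[i] ^ S[i + 1 :]) & m).sum(axis=1).astype(np.int64)
        acc.add(
            np.repeat(ids[i], n - 1 - i),
            ids[i + 1 :],
            shared,
            mism,
            brains[i + 1 :] == brains[i],
        )
    return acc.result()


def cross_brain_pairs(
    matrix_a: BarcodeMatrix,
    matrix_b: BarcodeMatrix,
    min_shared: int = 30,
    store: str = "all",
    close_threshold: float = 0.05,
) -> PairResult:
    """PWD over pairs with one cell from each of two individuals' matrices."""
    if matrix_a.sites != matrix_b.sites:
        raise ValueError("matrices are over different site sets")
    brains_a = set(matrix_a.cells["brain_id"])
    brains_b = set(matrix_b.cells["brain_id"])
    if brains_a & brains_b:
        raise ValueError(f"matrices share brain id(s) {sorted(brains_a & brains_b)}; use all_pairs within an individual")
    Sa, Ka = _pack(matrix_a.values)
    Sb, Kb = _pack(matrix_b.values)
    ids_a = np.asarray(matrix_a.cells.index)
    ids_b = np.asarray(matrix_b.cells.index)
    acc = _Accumulator(min_shared, store, close_threshold)
    nb = matrix_b.n_cells
    for i in range(matrix_a.n_cells):
        m = Ka[i] & Kb
        shared = np.bitwise_count(m).sum(axis=1).astype(np.int64)
        mism = np.bitwise_count((Sa[i] ^ Sb) & m).sum(axis=1).astype(np.int64)
        acc.add(np.repeat(ids_a[i], nb), ids_b, shared, mism, np.zeros(nb, dtype=bool))
    return acc.result()


def pwd_matrix(matrix: BarcodeMatrix, min_shared: int = 30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dense symmetric PWD matrix (NaN where a pair does not qualify).

    Returns (distances, n_shared) DataFrames indexed by cell id — the export
    used by tree building.
    """
    S, K = _pack(matrix.values)
    n = matrix.n_cells
    D = np.full((n, n), np.nan)
    Ns = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(D, 0.0)
    for i in range(n - 1):
        m = K[i] & K[i + 1 :]
        shared = np.bitwise_count(m).sum(axis=1).astype(np.int64)
        mism = np.bitwise_count((S[i] ^ S[i + 1 :]) & m).sum(axis=1).astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(shared >= min_shared, mism / np.maximum(shared, 1), np.nan)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
        Ns[i, i + 1 :] = shared
        Ns[i + 1 :, i] = shared
    ids = matrix.cells.index
    return pd.DataFrame(D, index=ids, columns=ids), pd.DataFrame(Ns, index=ids, columns=ids)


def pairs_naive(matrix: BarcodeMatrix, min_shared: int = 30) -> list[PairDistance]:
    """Reference double-loop PWD over all unordered pairs (small inputs only).

    Independent of the bit-packed kernel; used to certify it.
    """
    out = []
    ids = list(matrix.cells.index)
    brains = list(matrix.cells["brain_id"])
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            n_shared = n_mismatch = 0
            for k in range(matrix.n_sites):
                a, b = matrix.values[i, k], matrix.values[j, k]
                if a != MISSING and b != MISSING:
                    n_shared += 1
                    if a != b:
                        n_mismatch += 1
            if n_shared >= min_shared:
                out.append(
                    PairDistance(ids[i], ids[j], n_shared, n_mismatch, n_mismatch / n_shared, brains[i] == brains[j])
                )
    return out
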