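"""Closely related cell pairs: enrichment, lineage fidelity, and migration.

Cell pairs with PWD below a cutoff (default 0.05) are interpreted as sharing
recent ancestry ("nearest neighbor pairs").  Because barcodes can also match
by chance, the within- versus between-individual close-pair rate is the
calibration: true kinship exists only within an individual, so an excess of
within-individual close pairs over the between-individual chance rate is
the ancestry signal.

Fidelity statistics ask whether the two cells of a close pair share a
phenotype (major class, subtype) or an anatomic region.  The percent-same
denominator for a label counts close pairs with at least one cell of that
label.  A permutation null (labels shuffled across cells) gives the
chance-level fidelity implied by label frequencies alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RelatedPairReport",
    "close_pairs",
    "nearest_neighbor_pairs",
    "within_between_enrichment",
    "fidelity_matrix",
    "location_fidelity",
    "permutation_fidelity_null",
]

from fcpg.distance import PairResult

CORTICAL_REGIONS = ("FC", "TC", "OC", "PC")


@dataclass
class RelatedPairReport:
    threshold: float
    n_close: int
    n_total: int  # qualifying pairs (>= min_shared sites)
    n_total_all: int  # every examined pair, qualifying or not
    mean_n_shared_close: float

    @property
    def rate_per_million(self) -> float:
        """Close pairs per million qualifying pairs."""
        return 1e6 * self.n_close / self.n_total if self.n_total else 0.0

    @property
    def rate_per_million_all(self) -> float:
        """Close pairs per million examined pairs (all-pair denominator)."""
        return 1e6 * self.n_close / self.n_total_all if self.n_total_all else 0.0


def close_pairs(result: PairResult, threshold: float = 0.05) -> tuple[RelatedPairReport, pd.DataFrame]:
    """Pairs with pwd strictly below ``threshold``, plus the rate report."""
    if result.n_pairs_total == 0:
        raise ValueError("empty pair table")
    if result.store == "close":
        # stored pairs are already pwd < close_threshold; re-filter for safety
        pass
    close = result.pairs[result.pairs["pwd"] < threshold].copy()
    report = RelatedPairReport(
        threshold=threshold,
        n_close=len(close),
        n_total=result.n_qualifying,
        n_total_all=result.n_pairs_total,
        mean_n_shared_close=float(close["n_shared"].mean()) if len(close) else float("nan"),
    )
    return report, close


def nearest_neighbor_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Optional per-cell mode: each cell's single minimum-PWD partner.

    Returns the unique set of (cell, best partner) pairs; a pair appears
    once even when the relation is mutual.
    """
    long = pd.concat(
        [
            pairs.rename(columns={"cell_a": "cell", "cell_b": "partner"}),
            pairs.rename(columns={"cell_b": "cell", "cell_a": "partner"}),
        ],
        ignore_index=True,
    )
    best = long.sort_values(["cell", "pwd", "partner"]).groupby("cell", sort=True).head(1)
    key = best.apply(lambda r: tuple(sorted((r["cell"], r["partner"]))), axis=1)
    best = best.assign(_key=key).drop_duplicates("_key").drop(columns="_key")
    return best.rename(columns={"cell": "cell_a", "partner": "cell_b"}).reset_index(drop=True)


def within_between_enrichment(
    within_rates: Sequence[float], between_rates: Sequence[float]
) -> tuple[float, float, float]:
    """Enrichment of close pairs within vs between individuals.

    Both inputs are per-report close-pair rates (per million); the ratio is
    the unweighted mean of within rates over the unweighted mean of between
    rates (``inf`` when the between mean is zero).

    Returns (ratio, mean_within, mean_between).
    """
    if not len(within_rates) or not len(between_rates):
        raise ValueError("need at least one within and one between report")
    mean_w = float(np.mean(within_rates))
    mean_b = float(np.mean(between_rates))
    ratio = mean_w / mean_b if mean_b > 0 else math.inf
    return ratio, mean_w, mean_b


def _annotate_pairs(pairs: pd.DataFrame, annotations: pd.DataFrame, column: str) -> pd.DataFrame:
    out = pairs.copy()
    for side in ("a", "b"):
        cells = out[f"cell_{side}"]
        unknown = set(cells) - set(annotations.index)
        if unknown:
            raise KeyError(f"close pairs contain unannotated cell(s): {sorted(unknown)[:5]}")
        out[f"label_{side}"] = annotations.loc[cells, column].to_numpy()
    return out


def fidelity_matrix(
    pairs: pd.DataFrame, annotations: pd.DataFrame, label: str = "major_class"
) -> tuple[pd.DataFrame, pd.Series]:
    """Symmetric close-pair count matrix by label, plus percent-same per label.

    ``label`` is one of the annotation columns (major_class, subtype,
    region).  percent-same for label L = 100 * (pairs with both cells L) /
    (pairs with at least one cell L).
    """
    ann = _annotate_pairs(pairs, annotations, label)
    labels = sorted(set(ann["label_a"]) | set(ann["label_b"]))
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for la, lb in zip(ann["label_a"], ann["label_b"]):
        counts.loc[la, lb] += 1
        if la != lb:
            counts.loc[lb, la] += 1
    pct = {}
    for lab in labels:
        both = int(counts.loc[lab, lab])
        any_ = int(((ann["label_a"] == lab) | (ann["label_b"] == lab)).sum())
        pct[lab] = 100.0 * both / any_ if any_ else float("nan")
    return counts, pd.Series(pct, name="percent_same")


def location_fidelity(
    pairs: pd.DataFrame,
    annotations: pd.DataFrame,
    cortical_regions: Iterable[str] = CORTICAL_REGIONS,
) -> pd.Series:
    """Per-major-class percent of close same-class cortical pairs in the same region.

    Only pairs whose two cells share a major class and both lie in the
    cortical scope are counted; a high percent indicates radial (localized)
    migration, a chance-level percent indicates tangential migration.
    """
    scope = set(cortical_regions)
    cls = _annotate_pairs(pairs, annotations, "major_class")
    reg = _annotate_pairs(pairs, annotations, "region")
    same_class = cls["label_a"] == cls["label_b"]
    in_scope = reg["label_a"].isin(scope) & reg["label_b"].isin(scope)
    sub_cls = cls[same_class & in_scope]
    sub_reg = reg[same_class & in_scope]
    out = {}
    for major in sorted(set(sub_cls["label_a"])):
        m = sub_cls["label_a"] == major
        n = int(m.sum())
        same_region = int((sub_reg.loc[m, "label_a"] == sub_reg.loc[m, "label_b"]).sum())
        out[major] = 100.0 * same_region / n if n else float("nan")
    return pd.Series(out, name="percent_same_region")


def permutation_fidelity_null(
    pairs: pd.DataFrame,
    annotations: pd.DataFrame,
    label: str = "major_class",
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Chance-level fidelity: percent-same under label shuffling across cells.

    Returns one row per permutation with percent-same per label; the column
    means estimate the fidelity expected from label frequencies alone.
    """
    rng = np.random.default_rng(seed)
    perm_ann = annotations.copy()
    rows = []
    values = annotations[label].to_numpy()
    for _ in range(n_permutations):
        perm_ann[label] = rng.permutation(values)
        _, pct = fidelity_matrix(pairs, perm_ann, label)
        rows.append(pct)
    return pd.DataFrame(rows).reset_index(drop=True)
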