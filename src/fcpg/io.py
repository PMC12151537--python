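"""Readers and writers for allc methylation calls and pipeline artifacts.

The allc format is the tab-separated per-site call table produced by
methylpy-style pipelines: chromosome, 1-based position, strand, trinucleotide
context, methylated read count, total read count, and an optional flag
column.  Files may be gzip-compressed; compression is autodetected from the
magic bytes so ``.tsv`` and ``.tsv.gz`` are handled uniformly.

Barcode matrices, bulk methylation tables, and cell annotation tables are
plain TSV so every artifact round-trips through pandas.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "MethylationCall",
    "DEFAULT_SUBTYPE_CLASS",
    "read_allc",
    "write_allc",
    "read_annotations",
    "read_bulk_table",
    "write_bulk_table",
    "read_barcode_table",
    "write_barcode_table",
]


class MethylationCall(NamedTuple):
    """One CpG site's methylation evidence in one cell."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    mc: int
    cov: int


#: Default fine-subtype -> major-class lookup for adult brain cell types.
#: Subtypes follow the snmC-seq brain-atlas nomenclature: PN (pons), THM
#: (thalamus), MSN (medium spiny neurons) and the cortical interneuron
#: families are inhibitory; cortical layer neurons and hippocampal neurons
#: are excitatory; glia are non-neuronal.
DEFAULT_SUBTYPE_CLASS: dict[str, str] = {
    "PN": "inhibitory",
    "PN_early": "inhibitory",
    "THM": "inhibitory",
    "MSN": "inhibitory",
    "Pvalb": "inhibitory",
    "Sst": "inhibitory",
    "Vip": "inhibitory",
    "Lamp5": "inhibitory",
    "Sncg": "inhibitory",
    "Foxp2": "inhibitory",
    "Chd7": "inhibitory",
    "AMY": "inhibitory",
    "L2_3": "excitatory",
    "L4_6": "excitatory",
    "CA": "excitatory",
    "DG": "excitatory",
    "Hip-mc": "excitatory",
    "ASC": "non-neuronal",
    "ODC": "non-neuronal",
    "OPC": "non-neuronal",
    "NN": "non-neuronal",
}


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_allc(path: str | Path, chrom_filter: str | None = None) -> Iterator[MethylationCall]:
    """Stream methylation calls from an allc file.

    Parameters
    ----------
    path
        allc TSV, optionally gzip-compressed (autodetected by magic bytes).
    chrom_filter
        If given, only calls on this chromosome are yielded.

    Yields
    ------
    MethylationCall
        Calls in file order.  Trailing extra columns are tolerated;
        malformed lines raise ``ValueError`` with the 1-based line number.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >=6 tab-separated fields, got {len(fields)}")
            chrom, pos_s, strand, context, mc_s, cov_s = fields[:6]
            if chrom_filter is not None and chrom != chrom_filter:
                continue
            try:
                pos, mc, cov = int(pos_s), int(mc_s), int(cov_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer pos/mc/cov: {exc}") from None
            if pos < 1:
                raise ValueError(f"{path}: line {lineno}: position {pos} is not 1-based")
            if cov < 1:
                raise ValueError(f"{path}: line {lineno}: coverage {cov} < 1")
            if mc > cov:
                raise ValueError(f"{path}: line {lineno}: mc={mc} exceeds cov={cov}")
            yield MethylationCall(chrom, pos, strand, context, mc, cov)


def write_allc(path: str | Path, calls: Iterable[MethylationCall]) -> None:
    """Write calls as allc TSV (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.context}\t{c.mc}\t{c.cov}\t1\n")


def read_annotations(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    subtype_class: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a per-cell annotation table.

    Parameters
    ----------
    path
        TSV/CSV with a header.  Required logical columns: ``cell_id``,
        ``brain_id``, ``subtype``, ``region``; ``major_class`` is derived
        from subtype via *subtype_class* when absent.
    columns
        Optional mapping from logical names to the file's column names.
    subtype_class
        Subtype -> major class lookup; defaults to ``DEFAULT_SUBTYPE_CLASS``.

    Returns
    -------
    DataFrame indexed by cell_id with columns brain_id, major_class,
    subtype, region.  Duplicate cell ids raise ``ValueError``.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep)
    colmap = {k: k for k in ("cell_id", "brain_id", "major_class", "subtype", "region")}
    if columns:
        colmap.update(columns)
    required = ["cell_id", "brain_id", "subtype", "region"]
    missing = [colmap[k] for k in required if colmap[k] not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df = pd.DataFrame({k: raw[colmap[k]] for k in required})
    if colmap["major_class"] in raw.columns:
        df["major_class"] = raw[colmap["major_class"]]
    else:
        lookup = dict(subtype_class or DEFAULT_SUBTYPE_CLASS)
        unknown = sorted(set(df["subtype"]) - set(lookup))
        if unknown:
            raise ValueError(f"{path}: subtypes with no major-class mapping: {unknown}")
        df["major_class"] = df["subtype"].map(lookup)
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate cell ids: {sorted(set(dup))[:5]}")
    df = df.set_index("cell_id")[["brain_id", "major_class", "subtype", "region"]]
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)


def read_bulk_table(path: str | Path) -> pd.DataFrame:
    """Read a bulk WGBS per-site mean-methylation table (chrom, pos, mean_methylation)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "mean_methylation"):
        if col not in df.columns:
            raise ValueError(f"{path}: bulk table missing column {col!r}")
    bad = df[(df["mean_methylation"] < 0) | (df["mean_methylation"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: mean_methylation outside [0,1] at {len(bad)} site(s)")
    return df


def write_bulk_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_barcode_table(matrix: "BarcodeMatrix", path: str | Path) -> None:  # noqa: F821
    """Serialize a barcode matrix as TSV: cell_id rows, "chrom:pos" columns, values 0/1/NA."""
    vals = matrix.values
    if not np.isin(vals, (-1, 0, 1)).all():
        raise ValueError("barcode matrix contains values outside {0, 1, missing}")
    body = pd.DataFrame(vals.astype(float), index=matrix.cells.index, columns=matrix.sites)
    body[vals == -1] = np.nan
    out = pd.concat([matrix.cells, body], axis=1)
    out.index.name = "cell_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_barcode_table(path: str | Path) -> "BarcodeMatrix":  # noqa: F821
    """Inverse of :func:`write_barcode_table` (round-trip identity, missing included)."""
    from fcpg.barcode import BarcodeMatrix

    df = pd.read_csv(path, sep="\t", index_col="cell_id", na_values=["NA"])
    ann_cols = ["brain_id", "major_class", "subtype", "region"]
    sites = [c for c in df.columns if c not in ann_cols]
    body = df[sites].to_numpy(dtype=float)
    values = np.where(np.isnan(body), -1, body).astype(np.int8)
    return BarcodeMatrix(values=values, cells=df[ann_cols].copy(), sites=list(sites))
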