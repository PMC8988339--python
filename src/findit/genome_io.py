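"""Readers and writers for the genomic formats the toolkit consumes.

Everything is normalized into plain pandas containers with a single internal
coordinate convention: 0-based, half-open intervals (BED-native). Conversion
to and from 1-based inclusive coordinates (GFF3/GTF) happens only here, at the
I/O boundary.

Containers
----------
genes : DataFrame with columns ``gene_id, chrom, start, end, strand, tss``
    ``tss`` is the strand-aware transcription start: ``start`` on '+',
    ``end - 1`` on '-'.
peaks : DataFrame with columns ``peak_id, chrom, start, end, summit_offset, score``
    ``summit_offset`` is the offset of the summit from ``start`` (pandas NA
    when unknown).
signal matrix : DataFrame, rows = feature ids, columns = sample ids.
DGE table : DataFrame with columns ``gene_id, log2fc, padj, category``.
TF hits : dict mapping ``tf_id`` to a set of ``peak_id``.
TF-target pairs : DataFrame with columns ``tf_id, target_gene_id, confidence``.
"""

from __future__ import annotations

import io
import logging
import os
import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

__all__ = [
    "load_peak_file",
    "write_peak_file",
    "load_gene_annotation",
    "write_gene_annotation",
    "load_signal_matrix",
    "write_signal_matrix",
    "load_bedgraph",
    "load_tf_hits",
    "load_dge",
    "categorize_dge",
    "load_tt_pairs",
    "write_table",
]

logger = logging.getLogger("findit")

PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "summit_offset", "score"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]

_BED_NCOLS = {"bed6": 6, "narrowPeak": 10, "broadPeak": 9}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def load_peak_file(path: str | os.PathLike, format: str = "bed6") -> pd.DataFrame:
    """Read a BED6 / narrowPeak / broadPeak file into a peak table.

    Coordinates are kept 0-based half-open as in BED. narrowPeak column 10 is
    mapped to ``summit_offset`` (-1 meaning "absent"). Peaks whose name column
    is ``.`` receive auto-generated ids ``peak_000001`` ... in file order;
    explicit names are kept verbatim. The result is sorted by (chrom, start).
    """
    if format not in _BED_NCOLS:
        raise ValueError(f"unknown peak format {format!r}")
    ncols = _BED_NCOLS[format]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {ncols} columns for "
                    f"{format}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: require 0 <= start < end, "
                    f"got [{start}, {end})"
                )
            name = fields[3]
            score = None
            try:
                score = float(fields[4])
            except (ValueError, IndexError):
                score = None
            summit = None
            if format == "narrowPeak":
                try:
                    summit = int(fields[9])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: bad summit column") from exc
                if summit == -1:
                    summit = None
                elif start + summit >= end:
                    raise FormatError(
                        f"{path}: line {lineno}: summit offset {summit} outside peak"
                    )
            rows.append((name, fields[0], start, end, summit, score))
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    auto = peaks["peak_id"] == "."
    peaks.loc[auto, "peak_id"] = [f"peak_{i + 1:06d}" for i in np.flatnonzero(auto.to_numpy())]
    dup = peaks["peak_id"].duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate peak_id {peaks.loc[dup, 'peak_id'].iloc[0]!r}")
    peaks["summit_offset"] = peaks["summit_offset"].astype("Int64")
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return peaks


def write_peak_file(peaks: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a peak table as BED6 (summit/score information beyond BED6 is dropped)."""
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            score = 0 if row.score is None or pd.isna(row.score) else row.score
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_id}\t{score:g}\t.\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

_GENE_ID_ATTRS = ("ID", "gene_id", "Name", "gene_name")


def _feature_gene_id(feature) -> str | None:
    for key in _GENE_ID_ATTRS:
        if key in feature.attributes:
            val = feature.attributes[key]
            if val:
                return val[0]
    return None


def load_gene_annotation(
    path: str | os.PathLike, format: str = "gff3", feature: str = "gene"
) -> pd.DataFrame:
    """Read gene models from GFF3/GTF.

    1-based inclusive coordinates are converted to 0-based half-open. The TSS
    is the 5' end of the feature span: ``start`` on '+', ``end - 1`` on '-'.
    Records with strand '.' or without a recognizable gene identifier are
    skipped with a warning.
    """
    if format not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation format {format!r}")
    rows = []
    n_skipped = 0
    for feat in DataIterator(str(path)):
        if feat.featuretype != feature:
            continue
        gene_id = _feature_gene_id(feat)
        if gene_id is None:
            n_skipped += 1
            continue
        if feat.strand not in ("+", "-"):
            n_skipped += 1
            continue
        start0 = feat.start - 1  # GFF 1-based inclusive -> 0-based half-open
        end0 = feat.end
        tss = start0 if feat.strand == "+" else end0 - 1
        rows.append((gene_id, feat.seqid, start0, end0, feat.strand, tss))
    if n_skipped:
        logger.warning("%s: skipped %d %s records (no id or unknown strand)", path, n_skipped, feature)
    if not rows:
        raise FormatError(f"{path}: no usable {feature!r} records")
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if genes["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id in annotation")
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gene_annotation(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (inverse of :func:`load_gene_annotation`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tfindit\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------

def load_signal_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a features x samples TSV (first column = feature id, header = samples)."""
    mat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if mat.index.duplicated().any() or mat.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate row or column ids")
    if mat.isna().any().any():
        raise FormatError(f"{path}: missing values in signal matrix")
    if (mat.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative signal values")
    return mat.astype(float)


def write_signal_matrix(mat: pd.DataFrame, path: str | os.PathLike, **params) -> None:
    write_table(mat.reset_index(names="feature_id"), path, **params)


def load_bedgraph(path: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read a bedGraph coverage track into per-chromosome interval tables.

    Returns a dict chrom -> DataFrame(start, end, value), sorted by start.
    """
    cov = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    if (cov["value"] < 0).any():
        raise FormatError(f"{path}: negative coverage values")
    if (cov["start"] >= cov["end"]).any():
        raise FormatError(f"{path}: empty or inverted bedGraph interval")
    return {
        chrom: sub.sort_values("start").reset_index(drop=True)[["start", "end", "value"]]
        for chrom, sub in cov.groupby("chrom")
    }


def load_tf_hits(
    path: str | os.PathLike, peaks: pd.DataFrame | None = None
) -> dict[str, set[str]]:
    """Read TF binding hits as a mapping tf_id -> set of peak_id.

    Two dialects are accepted. A two-column TSV (tf_id, peak_id) is taken as
    direct hits; peak ids not present in the supplied peak universe are
    dropped with a warning. A BED file whose name column carries the TF name
    is resolved against the peak universe by >= 1 bp overlap (an interval
    overlapping two peaks yields hits on both).
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    fields = first.split("\t")
    is_bed = len(fields) >= 4 and fields[1].isdigit() and fields[2].isdigit()
    hits: dict[str, set[str]] = {}
    n_dropped = 0
    if is_bed:
        if peaks is None:
            raise ValueError("BED-format TF hits require a peak universe")
        sites = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "tf_id"], usecols=[0, 1, 2, 3],
            dtype={"chrom": str, "start": int, "end": int, "tf_id": str},
        )
        by_chrom = {c: sub.reset_index(drop=True) for c, sub in peaks.groupby("chrom")}
        for row in sites.itertuples(index=False):
            sub = by_chrom.get(row.chrom)
            matched = False
            if sub is not None:
                ov = (sub["start"] < row.end) & (sub["end"] > row.start)
                for pid in sub.loc[ov, "peak_id"]:
                    hits.setdefault(row.tf_id, set()).add(pid)
                    matched = True
            if not matched:
                n_dropped += 1
    else:
        tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if tab.shape[1] < 2:
            raise FormatError(f"{path}: expected columns tf_id, peak_id")
        tab = tab.iloc[:, :2]
        tab.columns = ["tf_id", "peak_id"]
        universe = None if peaks is None else set(peaks["peak_id"])
        for row in tab.itertuples(index=False):
            if universe is not None and row.peak_id not in universe:
                n_dropped += 1
                continue
            hits.setdefault(row.tf_id, set()).add(row.peak_id)
    if n_dropped:
        logger.warning("%s: dropped %d TF-hit rows outside the peak universe", path, n_dropped)
    return hits


def categorize_dge(
    dge: pd.DataFrame, lfc_min: float = 1.0, padj_max: float = 0.05
) -> pd.DataFrame:
    """Assign up/down/static categories from fold-change and padj thresholds.

    A gene is 'static' iff it fails either threshold; otherwise the sign of
    log2fc decides 'up' or 'down'.
    """
    out = dge.copy()
    passed = (out["padj"] < padj_max) & (out["log2fc"].abs() >= lfc_min)
    out["category"] = np.where(
        passed, np.where(out["log2fc"] > 0, "up", "down"), "static"
    )
    return out


def load_dge(
    path: str | os.PathLike,
    genes: pd.DataFrame | None = None,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Read a differential-expression TSV (gene_id, log2fc, padj[, category]).

    When the category column is absent it is derived from the thresholds.
    Rows referencing genes outside the supplied universe are dropped with a
    logged count.
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in tab.columns}
    ren = {}
    for want, aliases in {
        "gene_id": ("gene_id", "gene"),
        "log2fc": ("log2fc", "log2foldchange"),
        "padj": ("padj", "p_adj", "fdr"),
    }.items():
        for a in aliases:
            if a in cols:
                ren[cols[a]] = want
                break
        else:
            raise FormatError(f"{path}: missing column {want}")
    tab = tab.rename(columns=ren)
    if ((tab["padj"] < 0) | (tab["padj"] > 1)).any():
        raise FormatError(f"{path}: padj outside [0, 1]")
    if "category" not in tab.columns:
        tab = categorize_dge(tab, lfc_min=lfc_min, padj_max=padj_max)
    if genes is not None:
        keep = tab["gene_id"].isin(set(genes["gene_id"]))
        if (~keep).any():
            logger.warning("%s: dropped %d DGE rows outside gene universe", path, int((~keep).sum()))
        tab = tab[keep]
    return tab[["gene_id", "log2fc", "padj", "category"]].reset_index(drop=True)


def load_tt_pairs(
    path: str | os.PathLike, genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a TF -> target-gene pair table (tf_id, target_gene_id[, confidence])."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    tab = tab.rename(columns={tab.columns[0]: "tf_id", tab.columns[1]: "target_gene_id"})
    if "confidence" not in tab.columns:
        tab["confidence"] = np.nan
    if tab.duplicated(["tf_id", "target_gene_id"]).any():
        raise FormatError(f"{path}: duplicate (tf_id, target_gene_id) pairs")
    if genes is not None:
        keep = tab["target_gene_id"].isin(set(genes["gene_id"]))
        if (~keep).any():
            logger.warning("%s: dropped %d TF-target rows outside gene universe", path, int((~keep).sum()))
        tab = tab[keep]
    return tab[["tf_id", "target_gene_id", "confidence"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | os.PathLike, **params) -> None:
    """Write a TSV with '#'-commented header lines naming tool version and parameters."""
    from findit import __version__

    buf = io.StringIO()
    buf.write(f"# findit {__version__}\n")
    for key, value in params.items():
        buf.write(f"# {key}={value}\n")
    table.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
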