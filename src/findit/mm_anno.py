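"""Peak-to-gene annotation under three strategies.

``mm_nearest_gene``: one-to-one, every peak to the gene whose TSS is closest
to the peak anchor.  ``mm_gene_scan``: many-to-many, every peak to every gene
whose scan window (TSS +/- scan_length) contains the peak anchor, falling back
to the nearest gene for orphan peaks.  ``mm_gene_bound``: gene-centric, every
query gene guaranteed at least one associated peak.

The peak anchor is the summit when present, otherwise the interval midpoint.
Distances are signed: negative when the anchor lies 5' of the TSS in the
gene's orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnnoConfig",
    "anchor_positions",
    "mm_nearest_gene",
    "mm_gene_scan",
    "mm_gene_bound",
    "summarize_anno",
    "distance_distribution",
]

logger = logging.getLogger("findit")

LINK_COLUMNS = ["peak_id", "gene_id", "distance", "mode"]


@dataclass
class AnnoConfig:
    """Annotation parameters.

    scan_length is the per-side radius of the gene scan window in bp (the
    window is TSS - scan_length .. TSS + scan_length). anchor selects the
    measured point of a peak: 'summit' uses the summit where recorded and
    falls back to the midpoint, 'midpoint' always uses the midpoint.
    """

    scan_length: int = 20_000
    anchor: str = "summit"

    def __post_init__(self):
        if self.scan_length <= 0:
            raise ValueError("scan_length must be > 0")
        if self.anchor not in ("summit", "midpoint"):
            raise ValueError("anchor must be 'summit' or 'midpoint'")


def anchor_positions(peaks: pd.DataFrame, anchor: str = "summit") -> np.ndarray:
    """Return the anchor coordinate of every peak (summit if available, else midpoint)."""
    mid = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    if anchor == "midpoint" or "summit_offset" not in peaks.columns:
        return mid
    summit = peaks["summit_offset"]
    pos = peaks["start"].to_numpy() + summit.fillna(0).to_numpy(dtype=np.int64)
    return np.where(summit.isna().to_numpy(), mid, pos)


def _signed_distance(anchor: np.ndarray, tss: np.ndarray, strand: np.ndarray) -> np.ndarray:
    # negative = anchor upstream (5') of TSS in gene orientation
    raw = anchor - tss
    return np.where(strand == "+", raw, -raw).astype(np.int64)


def _gene_lookup(genes: pd.DataFrame):
    """Per-chromosome sorted TSS arrays with deduplicated representatives.

    When several genes share a TSS the lexicographically smallest gene_id
    represents the position, implementing the documented tie-break.
    """
    out = {}
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values(["tss", "gene_id"], kind="stable")
        rep = sub.drop_duplicates("tss", keep="first")
        out[chrom] = rep.reset_index(drop=True)
    return out


def mm_nearest_gene(peaks: pd.DataFrame, genes: pd.DataFrame, config: AnnoConfig | None = None) -> pd.DataFrame:
    """Annotate every peak with its single nearest gene by |anchor - TSS|.

    Ties (equal |distance|) resolve to the lexicographically smaller gene_id.
    Peaks on chromosomes without genes are omitted with a warning.
    """
    if peaks.empty or genes.empty:
        raise ValueError("peaks and genes must be non-empty")
    config = config or AnnoConfig()
    lookup = _gene_lookup(genes)
    anchors = anchor_positions(peaks, config.anchor)
    rows = []
    n_orphan = 0
    for i, peak in enumerate(peaks.itertuples(index=False)):
        sub = lookup.get(peak.chrom)
        if sub is None:
            n_orphan += 1
            continue
        tss = sub["tss"].to_numpy()
        a = anchors[i]
        j = np.searchsorted(tss, a)
        candidates = [k for k in (j - 1, j) if 0 <= k < len(tss)]
        best = min(
            candidates,
            key=lambda k: (abs(int(a) - int(tss[k])), sub["gene_id"].iloc[k]),
        )
        gene = sub.iloc[best]
        d = _signed_distance(np.array([a]), np.array([gene["tss"]]), np.array([gene["strand"]]))[0]
        rows.append((peak.peak_id, gene["gene_id"], int(d), "nearest"))
    if n_orphan:
        logger.warning("mm_nearest_gene: %d peaks on chromosomes without genes were omitted", n_orphan)
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def mm_gene_scan(
    peaks: pd.DataFrame, genes: pd.DataFrame, config: AnnoConfig | None = None
) -> pd.DataFrame:
    """Annotate peaks against every gene scan window they fall in.

    A peak whose anchor lies within TSS +/- scan_length of k genes yields k
    links with mode 'scan'; a peak inside no window falls back to its nearest
    gene (mode 'nearest_fallback').
    """
    if peaks.empty or genes.empty:
        raise ValueError("peaks and genes must be non-empty")
    config = config or AnnoConfig()
    anchors = anchor_positions(peaks, config.anchor)
    peak_ids = peaks["peak_id"].to_numpy()
    chroms = peaks["chrom"].to_numpy()
    rows = []
    linked = np.zeros(len(peaks), dtype=bool)
    for chrom, gsub in genes.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        p_idx = np.flatnonzero(mask)
        order = np.argsort(anchors[p_idx], kind="stable")
        p_idx = p_idx[order]
        a_sorted = anchors[p_idx]
        for gene in gsub.itertuples(index=False):
            lo = np.searchsorted(a_sorted, gene.tss - config.scan_length, side="left")
            hi = np.searchsorted(a_sorted, gene.tss + config.scan_length, side="right")
            if hi <= lo:
                continue
            sel = p_idx[lo:hi]
            linked[sel] = True
            d = _signed_distance(
                anchors[sel],
                np.full(len(sel), gene.tss),
                np.full(len(sel), gene.strand),
            )
            rows.extend(
                (peak_ids[k], gene.gene_id, int(dd), "scan") for k, dd in zip(sel, d)
            )
    out = pd.DataFrame(rows, columns=LINK_COLUMNS)
    if not linked.all():
        orphans = peaks.loc[~linked]
        fallback = mm_nearest_gene(orphans, genes, config)
        fallback = fallback.assign(mode="nearest_fallback")
        out = pd.concat([out, fallback], ignore_index=True)
    return out.sort_values(["peak_id", "gene_id"], kind="stable").reset_index(drop=True)


def mm_gene_bound(
    query_genes: list[str],
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    config: AnnoConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Find associated peaks for a list of genes of interest.

    Nearest-gene annotation is run first; query genes it already covers keep
    those links (mode 'nearest'). Each remaining query gene is linked to its
    nearest peak (mode 'gene_bound'). Genes on chromosomes without any peak
    are returned in the second element as unresolvable.
    """
    config = config or AnnoConfig()
    missing = set(query_genes) - set(genes["gene_id"])
    if missing:
        raise ValueError(f"query genes absent from annotation: {sorted(missing)}")
    nearest = mm_nearest_gene(peaks, genes, config)
    nearest = nearest[nearest["gene_id"].isin(set(query_genes))]
    covered = set(nearest["gene_id"])
    anchors = anchor_positions(peaks, config.anchor)
    order = np.lexsort((peaks["peak_id"].to_numpy(), anchors))
    by_chrom: dict[str, tuple[np.ndarray, pd.DataFrame]] = {}
    sorted_peaks = peaks.iloc[order].reset_index(drop=True)
    sorted_anchors = anchors[order]
    for chrom, sub in sorted_peaks.groupby("chrom"):
        by_chrom[chrom] = (sorted_anchors[sub.index.to_numpy()], sub.reset_index(drop=True))
    extra = []
    unresolvable = []
    gtab = genes.set_index("gene_id")
    for gid in query_genes:
        if gid in covered:
            continue
        gene = gtab.loc[gid]
        entry = by_chrom.get(gene["chrom"])
        if entry is None:
            unresolvable.append(gid)
            continue
        a_sorted, psub = entry
        j = np.searchsorted(a_sorted, gene["tss"])
        candidates = [k for k in (j - 1, j) if 0 <= k < len(a_sorted)]
        best = min(
            candidates,
            key=lambda k: (abs(int(a_sorted[k]) - int(gene["tss"])), psub["peak_id"].iloc[k]),
        )
        d = _signed_distance(
            np.array([a_sorted[best]]), np.array([gene["tss"]]), np.array([gene["strand"]])
        )[0]
        extra.append((psub["peak_id"].iloc[best], gid, int(d), "gene_bound"))
    if unresolvable:
        logger.warning("mm_gene_bound: %d query genes unresolvable (no peaks on chromosome)", len(unresolvable))
    out = pd.concat([nearest, pd.DataFrame(extra, columns=LINK_COLUMNS)], ignore_index=True)
    return out.reset_index(drop=True), unresolvable


def summarize_anno(links: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count peaks per gene and genes per peak for a link table."""
    if links.empty:
        raise ValueError("links must be non-empty")
    per_gene = (
        links.groupby("gene_id").size().rename("n_peaks").reset_index().sort_values("gene_id")
    )
    per_peak = (
        links.groupby("peak_id").size().rename("n_genes").reset_index().sort_values("peak_id")
    )
    return per_gene.reset_index(drop=True), per_peak.reset_index(drop=True)


def distance_distribution(links: pd.DataFrame, bin_width: int = 1000) -> pd.DataFrame:
    """Histogram of signed peak-TSS distances with half-open bins of bin_width bp."""
    d = links["distance"].to_numpy()
    lo = int(np.floor(d.min() / bin_width) * bin_width)
    hi = int(np.ceil((d.max() + 1) / bin_width) * bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int), "count": counts}
    )
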