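"""Correlate peak accessibility with gene expression across samples.

Two linking strategies are scored. ``peak_gene_cor`` takes existing
peak-gene links and correlates each peak's accessibility row against its
gene's expression row. ``enhancer_promoter_cor`` needs accessibility only:
per gene the nearest peak is declared the promoter and every other peak
within the scan window a distal candidate, and distal rows are correlated
against the promoter row. Links passing r > r_min and p < p_max form the
filtered, high-confidence set (defaults r_min=0.8, p_max=0.01).

p-values are the two-sided test of the correlation via the t transform with
n - 2 degrees of freedom; for Spearman the same transform is applied to the
rank correlation. Rows with zero variance give an undefined r (NaN) and are
excluded from filtering rather than treated as r = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from findit.mm_anno import AnnoConfig, anchor_positions

__all__ = ["CorConfig", "peak_gene_cor", "enhancer_promoter_cor", "assoc_pair_counts"]

logger = logging.getLogger("findit")


@dataclass
class CorConfig:
    method: str = "pearson"
    r_min: float = 0.8
    p_max: float = 0.01

    def __post_init__(self):
        if self.method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must be in (0, 1]")
        if not (-1 <= self.r_min <= 1):
            raise ValueError("r_min must be in [-1, 1]")


def _check_samples(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    if list(a.columns) != list(b.columns):
        raise ValueError(
            "sample sets differ between matrices: "
            f"{sorted(set(a.columns) ^ set(b.columns))[:10]}"
        )
    if a.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {a.shape[1]}")
    return list(a.columns)


def _cor_rows(x: np.ndarray, y: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise correlation of paired 2-D arrays with two-sided t-test p-values."""
    n = x.shape[1]
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y, axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc).sum(axis=1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = np.where(np.isnan(r), np.nan, 2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), df))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return r, np.clip(p, 0.0, 1.0)


def peak_gene_cor(
    links: pd.DataFrame,
    peak_signal: pd.DataFrame,
    gene_expr: pd.DataFrame,
    config: CorConfig | None = None,
) -> pd.DataFrame:
    """Score each peak-gene link by accessibility-expression correlation.

    Returns one row per input link: source_id (peak), anchor_id (gene), r, p,
    n, pass_filter. Undefined correlations (zero-variance rows) carry NaN and
    never pass the filter.
    """
    config = config or CorConfig()
    samples = _check_samples(peak_signal, gene_expr)
    missing_p = set(links["peak_id"]) - set(peak_signal.index)
    missing_g = set(links["gene_id"]) - set(gene_expr.index)
    if missing_p or missing_g:
        raise ValueError(
            f"links reference features without signal rows: peaks {sorted(missing_p)[:5]}, "
            f"genes {sorted(missing_g)[:5]}"
        )
    x = peak_signal.loc[links["peak_id"], samples].to_numpy(dtype=float)
    y = gene_expr.loc[links["gene_id"], samples].to_numpy(dtype=float)
    r, p = _cor_rows(x, y, config.method)
    out = pd.DataFrame(
        {
            "source_id": links["peak_id"].to_numpy(),
            "anchor_id": links["gene_id"].to_numpy(),
            "r": r,
            "p": p,
            "n": len(samples),
        }
    )
    out["pass_filter"] = (out["r"] > config.r_min) & (out["p"] < config.p_max)
    out.loc[out["r"].isna(), "pass_filter"] = False
    return out


def enhancer_promoter_cor(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    peak_signal: pd.DataFrame,
    config: CorConfig | None = None,
    anno_config: AnnoConfig | None = None,
) -> pd.DataFrame:
    """Correlate distal peaks with per-gene promoter peaks using accessibility only.

    Per gene: the promoter is the peak whose anchor is nearest the TSS (ties
    to the lexicographically smaller peak_id); distal candidates are all other
    peaks whose anchor lies within TSS +/- scan_length. Output rows carry
    source_id (distal peak), anchor_id (promoter peak), gene_id, r, p, n,
    pass_filter. Genes with no peak in their window are skipped with a count.
    """
    config = config or CorConfig()
    anno_config = anno_config or AnnoConfig()
    if peak_signal.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {peak_signal.shape[1]}")
    anchors = anchor_positions(peaks, anno_config.anchor)
    peak_ids = peaks["peak_id"].to_numpy()
    rows = []
    n_skipped = 0
    for chrom, gsub in genes.groupby("chrom"):
        mask = peaks["chrom"].to_numpy() == chrom
        if not mask.any():
            n_skipped += len(gsub)
            continue
        idx = np.flatnonzero(mask)
        order = np.lexsort((peak_ids[idx], anchors[idx]))
        idx = idx[order]
        a_sorted = anchors[idx]
        for gene in gsub.itertuples(index=False):
            lo = np.searchsorted(a_sorted, gene.tss - anno_config.scan_length, "left")
            hi = np.searchsorted(a_sorted, gene.tss + anno_config.scan_length, "right")
            window = idx[lo:hi]
            if len(window) == 0:
                n_skipped += 1
                continue
            dists = np.abs(anchors[window] - gene.tss)
            prom_pos = min(
                range(len(window)), key=lambda k: (dists[k], peak_ids[window[k]])
            )
            prom = peak_ids[window[prom_pos]]
            for k, pidx in enumerate(window):
                if k == prom_pos:
                    continue
                rows.append((peak_ids[pidx], prom, gene.gene_id))
    if n_skipped:
        logger.warning("enhancer_promoter_cor: %d genes with no peak in window skipped", n_skipped)
    if not rows:
        return pd.DataFrame(
            columns=["source_id", "anchor_id", "gene_id", "r", "p", "n", "pass_filter"]
        )
    link = pd.DataFrame(rows, columns=["source_id", "anchor_id", "gene_id"])
    link = link.drop_duplicates(["source_id", "gene_id"]).reset_index(drop=True)
    x = peak_signal.loc[link["source_id"]].to_numpy(dtype=float)
    y = peak_signal.loc[link["anchor_id"]].to_numpy(dtype=float)
    r, p = _cor_rows(x, y, config.method)
    link["r"] = r
    link["p"] = p
    link["n"] = peak_signal.shape[1]
    link["pass_filter"] = (link["r"] > config.r_min) & (link["p"] < config.p_max)
    link.loc[link["r"].isna(), "pass_filter"] = False
    return link


def assoc_pair_counts(links: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count-of-counts summaries: how many genes have k peaks, and vice versa.

    Accepts either an annotation link table (peak_id/gene_id) or a correlation
    link table (source_id/anchor_id/gene_id).
    """
    peak_col = "peak_id" if "peak_id" in links.columns else "source_id"
    per_gene = links.groupby("gene_id")[peak_col].nunique()
    per_peak = links.groupby(peak_col)["gene_id"].nunique()
    gene_coc = (
        per_gene.value_counts().sort_index().rename("n_genes")
        .rename_axis("n_peaks").reset_index()
    )
    peak_coc = (
        per_peak.value_counts().sort_index().rename("n_peaks")
        .rename_axis("n_genes").reset_index()
    )
    return gene_coc, peak_coc
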