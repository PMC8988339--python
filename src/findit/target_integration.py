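"""Call direct TF targets by combining ChIP RP ranks with differential expression.

The rank product of a gene is rp_rank * diff_rank, where rp_rank orders genes
by regulatory potential from the TF's ChIP peaks (larger RP = rank 1) and
diff_rank orders the differential-expression table by ascending adjusted
p-value within the selected direction. Genes standing high on both axes get
small products and are the high-confidence direct targets. Only ranks enter,
so the product is invariant under monotone transforms of either input. Ties
receive average (mid) ranks, which is why fractional products occur.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rank_with_ties", "rank_product", "integrate_chip_rna", "top_targets"]

logger = logging.getLogger("findit")

TARGET_COLUMNS = [
    "gene_id", "with_peak_n", "sum_rp", "rp_rank", "log2fc", "padj",
    "diff_rank", "rank_product", "rank_of_rank_product", "gene_category",
]


def rank_with_ties(values, direction: str = "ascending") -> np.ndarray:
    """Mid-ranks (average over tied positions); ranks sum to n(n+1)/2."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if np.isnan(values).any():
        raise ValueError("values must not contain missing entries")
    if direction == "ascending":
        return stats.rankdata(values, method="average")
    if direction == "descending":
        return stats.rankdata(-values, method="average")
    raise ValueError("direction must be 'ascending' or 'descending'")


def rank_product(rp_rank, diff_rank) -> pd.DataFrame:
    """The product step: rank_product = rp_rank * diff_rank and its own rank.

    Accepts the two rank vectors (fractional mid-ranks allowed) and returns
    a table with rank_product and rank_of_rank_product (ascending mid-rank).
    """
    rp_rank = np.asarray(rp_rank, dtype=float)
    diff_rank = np.asarray(diff_rank, dtype=float)
    if rp_rank.shape != diff_rank.shape:
        raise ValueError("rank vectors must have equal length")
    prod = rp_rank * diff_rank
    return pd.DataFrame(
        {
            "rp_rank": rp_rank,
            "diff_rank": diff_rank,
            "rank_product": prod,
            "rank_of_rank_product": rank_with_ties(prod, "ascending"),
        }
    )


def integrate_chip_rna(
    rp_table: pd.DataFrame,
    dge: pd.DataFrame,
    category: str = "up",
    recompute_rp_rank: bool = True,
) -> pd.DataFrame:
    """Rank-product integration of a calc_rp_tfhit table with a DGE table.

    Parameters
    ----------
    rp_table : output of calc_rp_tfhit (gene_id, with_peak_n, sum_rp, rp_rank).
    dge : table with gene_id, log2fc, padj, category.
    category : which expression direction to rank ('up', 'down' or 'both').
    recompute_rp_rank : re-rank sum_rp within the intersected gene universe
        (default) instead of keeping ranks from the full ChIP universe.

    Returns the target table sorted by rank_of_rank_product ascending, with
    lexicographic gene_id as the final tie-break.
    """
    if category not in ("up", "down", "both"):
        raise ValueError("category must be 'up', 'down' or 'both'")
    sel = dge if category == "both" else dge[dge["category"] == category]
    if category == "both":
        sel = sel[sel["category"].isin(["up", "down"])]
    merged = rp_table.merge(sel, on="gene_id", how="inner")
    n_rp_only = len(rp_table) - len(merged)
    n_dge_only = len(sel) - len(merged)
    if merged.empty:
        raise ValueError("no genes shared between the ChIP and DGE universes")
    if n_rp_only or n_dge_only:
        logger.info(
            "integrate_chip_rna: dropped %d ChIP-only and %d DGE-only genes",
            n_rp_only, n_dge_only,
        )
    if recompute_rp_rank:
        merged["rp_rank"] = rank_with_ties(merged["sum_rp"], "descending")
    merged["diff_rank"] = rank_with_ties(merged["padj"], "ascending")
    prod = rank_product(merged["rp_rank"], merged["diff_rank"])
    merged["rank_product"] = prod["rank_product"].to_numpy()
    merged["rank_of_rank_product"] = prod["rank_of_rank_product"].to_numpy()
    merged = merged.rename(columns={"category": "gene_category"})
    merged = merged.sort_values(
        ["rank_of_rank_product", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    return merged[TARGET_COLUMNS]


def top_targets(table: pd.DataFrame, k: int) -> list[str]:
    """First k gene ids by ascending rank_of_rank_product (ties by gene_id)."""
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    ordered = table.sort_values(["rank_of_rank_product", "gene_id"], kind="stable")
    return ordered["gene_id"].head(k).tolist()
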