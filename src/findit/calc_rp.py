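"""Regulatory-potential (RP) profiles.

The RP of a gene sums nearby regulatory signal weighted by an exponentially
decaying function of distance to the TSS:

    w(d) = 2 ** (-d / half_decay)

so a peak at the TSS contributes its full signal, one at the half-decay
distance contributes half, and so on. Three input modes are supported:

* ``calc_rp_region``  — peak count matrix + gene-scan links, per-sample
  profile (broad accessibility; default half-decay 10 kb),
* ``calc_rp_coverage`` — per-base coverage (bedGraph), one value per gene,
* ``calc_rp_tfhit``   — one TF's ChIP peaks with unit weight per peak
  (sharp binding; default half-decay 1 kb), ranked so larger RP means a
  better (smaller) rank, ties mid-ranked.

RP does no normalization of its own; normalize the signal matrix upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from findit.mm_anno import AnnoConfig, anchor_positions

__all__ = [
    "RPConfig",
    "RPProfile",
    "decay_weight",
    "calc_rp_region",
    "calc_rp_coverage",
    "calc_rp_tfhit",
]

logger = logging.getLogger("findit")

HALF_DECAY_TFCHIP = 1_000
HALF_DECAY_ACCESSIBILITY = 10_000


@dataclass
class RPConfig:
    """half_decay: bp at which the decay weight reaches 0.5; window: max |distance|."""

    half_decay: int = HALF_DECAY_ACCESSIBILITY
    window: int = 20_000

    def __post_init__(self):
        if self.half_decay <= 0 or self.window <= 0:
            raise ValueError("half_decay and window must be > 0")


@dataclass
class RPProfile:
    """Gene x sample RP matrix plus the per-link decay weights behind it."""

    rp: pd.DataFrame
    weights: pd.DataFrame  # columns gene_id, peak_id, w
    with_peak_n: pd.Series  # gene_id -> number of contributing peaks


def decay_weight(d, half_decay: int):
    """Exponential decay weight 2^(-d/half_decay); w(0) = 1, w(half_decay) = 0.5."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    return np.exp2(-d / half_decay)


def calc_rp_region(
    scan_links: pd.DataFrame,
    peak_signal: pd.DataFrame,
    config: RPConfig | None = None,
    genes: pd.DataFrame | None = None,
) -> RPProfile:
    """Per-sample RP from a peak count matrix and gene-scan links.

    rp(g, s) = sum over scan-linked peaks p of w(|d_pg|) * signal(p, s).
    Fallback-mode links are excluded. When a gene table is supplied, genes
    without any scan link get an all-zero row and with_peak_n = 0.
    """
    config = config or RPConfig()
    links = scan_links[scan_links["mode"] == "scan"]
    links = links[links["distance"].abs() <= config.window]
    missing = set(links["peak_id"]) - set(peak_signal.index)
    if missing:
        raise ValueError(f"linked peaks missing from signal matrix: {sorted(missing)[:5]}")
    w = decay_weight(links["distance"].abs().to_numpy(), config.half_decay)
    weights = pd.DataFrame(
        {"gene_id": links["gene_id"].to_numpy(), "peak_id": links["peak_id"].to_numpy(), "w": w}
    )
    x = peak_signal.loc[weights["peak_id"]].to_numpy(dtype=float)
    contrib = pd.DataFrame(
        x * weights["w"].to_numpy()[:, None],
        columns=peak_signal.columns,
    )
    contrib["gene_id"] = weights["gene_id"].to_numpy()
    rp = contrib.groupby("gene_id").sum()
    n = weights.groupby("gene_id").size()
    if genes is not None:
        all_ids = pd.Index(genes["gene_id"].sort_values())
        rp = rp.reindex(all_ids, fill_value=0.0)
        n = n.reindex(all_ids, fill_value=0)
    rp.index.name = "gene_id"
    return RPProfile(rp=rp, weights=weights.reset_index(drop=True), with_peak_n=n.astype(int))


def _weight_run_sum(d1: int, d2: int, half_decay: int) -> float:
    """Sum of 2^(-d/half_decay) for integer d from d1 to d2 inclusive (geometric)."""
    if d2 < d1:
        return 0.0
    q = 2.0 ** (-1.0 / half_decay)
    # q^d1 + ... + q^d2 = (q^d1 - q^(d2+1)) / (1 - q)
    return (q**d1 - q ** (d2 + 1)) / (1.0 - q)


def calc_rp_coverage(
    coverage: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    config: RPConfig | None = None,
) -> pd.Series:
    """Per-gene RP integrated base-by-base from a bedGraph coverage track.

    rp(g) = sum over bases b in [tss - window, tss + window] of
    w(|b - tss|) * coverage(b). Bases outside covered intervals contribute
    zero; genes on chromosomes absent from the track get rp = 0 with a
    warning.
    """
    config = config or RPConfig()
    if genes.empty:
        raise ValueError("genes must be non-empty")
    out = {}
    missing_chroms = set()
    for gene in genes.itertuples(index=False):
        track = coverage.get(gene.chrom)
        if track is None:
            missing_chroms.add(gene.chrom)
            out[gene.gene_id] = 0.0
            continue
        lo = gene.tss - config.window
        hi = gene.tss + config.window  # inclusive endpoints of the window
        total = 0.0
        starts = track["start"].to_numpy()
        ends = track["end"].to_numpy()
        vals = track["value"].to_numpy()
        first = np.searchsorted(ends, lo, side="right")
        for i in range(first, len(starts)):
            s = max(int(starts[i]), lo)
            e = min(int(ends[i]) - 1, hi)  # inclusive base range [s, e]
            if starts[i] > hi:
                break
            if e < s:
                continue
            if e < gene.tss:  # fully upstream: distances tss-e .. tss-s
                total += vals[i] * _weight_run_sum(gene.tss - e, gene.tss - s, config.half_decay)
            elif s > gene.tss:  # fully downstream
                total += vals[i] * _weight_run_sum(s - gene.tss, e - gene.tss, config.half_decay)
            else:  # spans the TSS: split into upstream run, d=0, downstream run
                total += vals[i] * (
                    _weight_run_sum(1, gene.tss - s, config.half_decay)
                    + 1.0
                    + _weight_run_sum(1, e - gene.tss, config.half_decay)
                )
        out[gene.gene_id] = total
    if missing_chroms:
        logger.warning(
            "calc_rp_coverage: chromosomes absent from coverage, rp=0 assigned: %s",
            sorted(missing_chroms),
        )
    rp = pd.Series(out, name="rp")
    rp.index.name = "gene_id"
    return rp


def calc_rp_tfhit(
    tf_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    config: RPConfig | None = None,
    anno_config: AnnoConfig | None = None,
) -> pd.DataFrame:
    """Per-gene RP from one TF's ChIP peaks, each contributing unit signal.

    Returns a table (gene_id, with_peak_n, sum_rp, rp_rank) where
    sum_rp(g) = sum of w(|anchor - tss|) over peaks within the window and
    rp_rank ranks sum_rp descending with ties assigned the average (mid)
    rank, so the strongest regulatory environment has rank 1.
    """
    if tf_peaks.empty:
        raise ValueError("tf_peaks must be non-empty")
    config = config or RPConfig(half_decay=HALF_DECAY_TFCHIP)
    anno_config = anno_config or AnnoConfig()
    anchors = anchor_positions(tf_peaks, anno_config.anchor)
    chroms = tf_peaks["chrom"].to_numpy()
    sum_rp = np.zeros(len(genes))
    n_peaks = np.zeros(len(genes), dtype=int)
    for chrom in np.unique(chroms):
        a = np.sort(anchors[chroms == chrom])
        gmask = genes["chrom"].to_numpy() == chrom
        for gi in np.flatnonzero(gmask):
            tss = genes["tss"].iat[gi]
            lo = np.searchsorted(a, tss - config.window, "left")
            hi = np.searchsorted(a, tss + config.window, "right")
            if hi > lo:
                d = np.abs(a[lo:hi] - tss)
                sum_rp[gi] = decay_weight(d, config.half_decay).sum()
                n_peaks[gi] = hi - lo
    out = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "with_peak_n": n_peaks,
            "sum_rp": sum_rp,
        }
    )
    out["rp_rank"] = stats.rankdata(-out["sum_rp"].to_numpy(), method="average")
    return out.sort_values("rp_rank", kind="stable").reset_index(drop=True)
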