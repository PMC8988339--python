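"""Rank transcription factors by influence over a query peak or gene set.

Six complementary statistics share one output contract (tf_id, statistic, p,
p_adj, z, rank):

* ``findit_enrich_fisher``  — one-sided Fisher exact test of TF binding
  enrichment in a query peak set against the rest of the peak universe.
* ``findit_enrich_wilcox``  — one-sided Wilcoxon rank-sum on per-peak TF
  scores (hit indicators or supplied signal), query vs background.
* ``findit_tt_pair``        — hypergeometric over-representation of a TF's
  known target genes in a query gene set (GO-enrichment style).
* ``findit_tfhit``          — Wilcoxon on per-gene TF binding-site counts
  within gene scan windows, query genes vs background genes.
* ``findit_region_rp``      — per-sample Wilcoxon on the TF-attributable
  share of each gene's regulatory potential (an epigenetic-landscape
  reduction of in-silico deletion).
* ``findit_mara``           — motif activity response analysis: ridge
  regression of the (log, double-centered) peak signal on motif site counts,
  giving per-sample motif activities; variable motifs are the influential
  ones.

All hypothesis tests are one-sided "greater" (enrichment), adjusted by
Benjamini-Hochberg across TFs within a call. The z column is the inverse
normal transform of the TF's rank, z = Phi^-1((n - rank + 0.5) / n), so the
top TF carries the largest z.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from statsmodels.stats.multitest import multipletests

from findit.calc_rp import RPProfile, decay_weight

__all__ = [
    "MARAResult",
    "inverse_normal_z",
    "wilcox_greater",
    "findit_enrich_fisher",
    "findit_enrich_wilcox",
    "findit_tt_pair",
    "findit_tfhit",
    "findit_region_rp",
    "findit_mara",
    "integrate_replicates",
    "jaccard_tf",
]

logger = logging.getLogger("findit")

RANKING_COLUMNS = ["tf_id", "statistic", "p", "p_adj", "z", "rank"]

# exact Wilcoxon enumeration is attempted only below this many arrangements
_EXACT_ENUM_CAP = 200_000


def inverse_normal_z(ranks, n: int | None = None) -> np.ndarray:
    """Inverse normal transform of ranks: z = Phi^-1((n - r + 0.5) / n).

    Rank 1 (best) maps to the largest z; the 0.5/n offset keeps the extremes
    finite. Mid-ranks are accepted.
    """
    ranks = np.asarray(ranks, dtype=float)
    n = len(ranks) if n is None else n
    return ndtri((n - ranks + 0.5) / n)


def _finalize_ranking(df: pd.DataFrame) -> pd.DataFrame:
    """Attach p_adj (BH), rank (p asc, statistic desc, tf_id) and z columns."""
    if df.empty:
        return df.reindex(columns=RANKING_COLUMNS)
    df = df.sort_values(
        ["p", "statistic", "tf_id"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["rank"] = np.arange(1, len(df) + 1)
    df["z"] = inverse_normal_z(df["rank"].to_numpy())
    front = RANKING_COLUMNS
    rest = [c for c in df.columns if c not in front]
    return df[front + rest]


# ---------------------------------------------------------------------------
# core tests
# ---------------------------------------------------------------------------

def hypergeom_sf_geq(k: int, total: int, marked: int, drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeom(total, marked, drawn)."""
    return float(stats.hypergeom.sf(k - 1, total, marked, drawn))


def wilcox_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test of x stochastically greater than y.

    Returns (z, p). The exact permutation null is enumerated when the
    smaller group has at most 8 observations and the arrangement count is
    tractable (ties are handled by enumerating mid-rank subsets); otherwise
    the normal approximation with tie and continuity corrections is used.
    With all observations tied there is no evidence either way and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    ntot = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (ntot * (ntot - 1))
    var = n1 * n2 / 12.0 * ((ntot + 1) - tie_term)
    if var <= 0:  # all observations identical
        return 0.0, 1.0
    z = (u1 - mu) / math.sqrt(var)
    k = min(n1, n2)
    if k <= 8 and math.comb(ntot, k) <= _EXACT_ENUM_CAP:
        # enumerate rank subsets for the smaller group; R_x + R_y is fixed,
        # so P(R_x >= obs) == P(R_y <= obs)
        target_sum = r1 if n1 <= n2 else ranks[n1:].sum()
        eps = 1e-9
        count = total = 0
        for subset in itertools.combinations(ranks, k):
            s = sum(subset)
            total += 1
            if n1 <= n2:
                count += s >= target_sum - eps
            else:
                count += s <= target_sum + eps
        return z, count / total
    p = float(stats.norm.sf((u1 - mu - 0.5) / math.sqrt(var)))
    return z, min(1.0, p)


# ---------------------------------------------------------------------------
# peak-set statistics
# ---------------------------------------------------------------------------

def _check_query(query: set[str], universe: set[str]) -> set[str]:
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("query set is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if query == universe:
        raise ValueError("query equals the universe: no background to compare against")
    return universe - query


def findit_enrich_fisher(
    query_peaks: set[str], universe: set[str], hits: dict[str, set[str]]
) -> pd.DataFrame:
    """Fisher exact enrichment of TF binding in a query peak set.

    Per TF the 2x2 table (query-hit, query-miss, background-hit,
    background-miss) is tested one-sided for over-representation; the
    statistic is the sample odds ratio (Haldane 0.5 correction when a cell
    is zero).
    """
    query_peaks = set(query_peaks)
    background = _check_query(query_peaks, universe)
    nq, nb = len(query_peaks), len(background)
    rows = []
    for tf_id, tf_hits in hits.items():
        tf_hits = tf_hits & (query_peaks | background)
        a = len(tf_hits & query_peaks)
        c = len(tf_hits) - a
        b, d = nq - a, nb - c
        p = hypergeom_sf_geq(a, nq + nb, len(tf_hits), nq)
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append((tf_id, odds, p, a, len(tf_hits)))
    df = pd.DataFrame(rows, columns=["tf_id", "statistic", "p", "n_query_hit", "n_hit"])
    return _finalize_ranking(df)


def findit_enrich_wilcox(
    query_peaks: set[str],
    universe: set[str],
    hits: dict[str, set[str]] | None = None,
    peak_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum enrichment of per-peak TF scores in a query peak set.

    Scores default to binary hit indicators from ``hits``; alternatively a
    peak x TF score matrix can be supplied via ``peak_scores``.
    """
    query_peaks = set(query_peaks)
    background = _check_query(query_peaks, universe)
    q_ids = sorted(query_peaks)
    b_ids = sorted(background)
    rows = []
    if peak_scores is not None:
        for tf_id in peak_scores.columns:
            xs = peak_scores.loc[q_ids, tf_id].to_numpy(dtype=float)
            ys = peak_scores.loc[b_ids, tf_id].to_numpy(dtype=float)
            zval, p = wilcox_greater(xs, ys)
            rows.append((tf_id, zval, p))
    else:
        if hits is None:
            raise ValueError("either hits or peak_scores is required")
        for tf_id, tf_hits in hits.items():
            xs = np.fromiter((1.0 if pid in tf_hits else 0.0 for pid in q_ids), float)
            ys = np.fromiter((1.0 if pid in tf_hits else 0.0 for pid in b_ids), float)
            zval, p = wilcox_greater(xs, ys)
            rows.append((tf_id, zval, p))
    df = pd.DataFrame(rows, columns=["tf_id", "statistic", "p"])
    return _finalize_ranking(df)


# ---------------------------------------------------------------------------
# gene-set statistics
# ---------------------------------------------------------------------------

def findit_tt_pair(
    query_genes: set[str], universe_genes: set[str], pairs: pd.DataFrame
) -> pd.DataFrame:
    """Hypergeometric over-representation of known TF targets in a gene set."""
    query_genes = set(query_genes)
    universe_genes = set(universe_genes)
    if not query_genes <= universe_genes:
        raise ValueError("query must be a subset of the universe")
    if not query_genes:
        raise ValueError("query set is empty")
    total, drawn = len(universe_genes), len(query_genes)
    rows = []
    n_dropped = 0
    for tf_id, sub in pairs.groupby("tf_id"):
        targets = set(sub["target_gene_id"]) & universe_genes
        if not targets:
            n_dropped += 1
            continue
        overlap = sorted(targets & query_genes)
        k = len(overlap)
        p = hypergeom_sf_geq(k, total, len(targets), drawn)
        enrichment = (k * total) / (len(targets) * drawn)
        rows.append((tf_id, enrichment, p, k, len(targets), ",".join(overlap)))
    if n_dropped:
        logger.warning("findit_tt_pair: %d TFs with no targets in universe dropped", n_dropped)
    df = pd.DataFrame(
        rows, columns=["tf_id", "statistic", "p", "n_overlap", "n_targets", "overlap_genes"]
    )
    return _finalize_ranking(df)


def _gene_tf_hit_counts(
    universe_genes: list[str],
    hits: dict[str, set[str]],
    scan_links: pd.DataFrame,
    weighted: bool = False,
    half_decay: int = 1000,
) -> pd.DataFrame:
    """Gene x TF matrix of TF-bound peak counts (optionally decay-weighted)."""
    links = scan_links[scan_links["mode"] == "scan"]
    links = links[links["gene_id"].isin(set(universe_genes))]
    gene_index = {g: i for i, g in enumerate(universe_genes)}
    tf_ids = sorted(hits)
    counts = np.zeros((len(universe_genes), len(tf_ids)))
    gi = links["gene_id"].map(gene_index).to_numpy()
    link_peaks = links["peak_id"].to_numpy()
    w = (
        decay_weight(links["distance"].abs().to_numpy(), half_decay)
        if weighted
        else np.ones(len(links))
    )
    for j, tf_id in enumerate(tf_ids):
        mask = np.fromiter((pid in hits[tf_id] for pid in link_peaks), bool, len(link_peaks))
        if mask.any():
            np.add.at(counts[:, j], gi[mask], w[mask])
    return pd.DataFrame(counts, index=universe_genes, columns=tf_ids)


def findit_tfhit(
    query_genes: set[str],
    universe_genes: set[str],
    hits: dict[str, set[str]],
    scan_links: pd.DataFrame,
    weighted: bool = False,
    half_decay: int = 1000,
) -> pd.DataFrame:
    """Wilcoxon enrichment of TF binding-site counts around query-gene TSSs.

    Per gene and TF the count of TF-bound peaks linked to the gene (scan
    mode) is computed — optionally weighted by the RP decay weight — and per
    TF the counts of query genes are tested against background genes.
    """
    query_genes = set(query_genes)
    universe_sorted = sorted(set(universe_genes))
    background = _check_query(query_genes, set(universe_sorted))
    counts = _gene_tf_hit_counts(universe_sorted, hits, scan_links, weighted, half_decay)
    q_ids = sorted(query_genes)
    b_ids = sorted(background)
    rows = []
    for tf_id in counts.columns:
        zval, p = wilcox_greater(
            counts.loc[q_ids, tf_id].to_numpy(), counts.loc[b_ids, tf_id].to_numpy()
        )
        rows.append((tf_id, zval, p))
    df = pd.DataFrame(rows, columns=["tf_id", "statistic", "p"])
    return _finalize_ranking(df)


def findit_region_rp(
    query_genes: set[str],
    rp_profile: RPProfile,
    peak_signal: pd.DataFrame,
    hits: dict[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank TFs by the share of query genes' regulatory potential they can claim.

    For gene g, TF t and sample s the attributable RP is the decay-weighted
    signal summed over g's linked peaks bound by t; dividing by the gene's
    total RP gives the proportion attributable (0 where RP is 0). Per sample
    and TF a one-sided Wilcoxon compares proportions of query genes against
    background genes. The summary p per TF is the Bonferroni-corrected
    minimum across samples.

    Returns (summary ranking, per-sample long table, per-(gene, TF, sample)
    detail table restricted to query genes).
    """
    query_genes = set(query_genes)
    genes = list(rp_profile.rp.index)
    background = _check_query(query_genes, set(genes))
    samples = list(rp_profile.rp.columns)
    weights = rp_profile.weights
    known_peaks = set(weights["peak_id"])
    rp = rp_profile.rp.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}
    gi = weights["gene_id"].map(gene_index).to_numpy()
    x = peak_signal.loc[weights["peak_id"], samples].to_numpy(dtype=float)
    wx = x * weights["w"].to_numpy()[:, None]  # per-link weighted signal
    q_idx = np.fromiter((gene_index[g] for g in sorted(query_genes)), int)
    b_idx = np.fromiter((gene_index[g] for g in sorted(background)), int)
    n_ignored = 0
    sample_rows = []
    detail_rows = []
    summary_rows = []
    for tf_id in sorted(hits):
        tf_hits = hits[tf_id]
        extra = tf_hits - known_peaks
        n_ignored += len(extra)
        mask = weights["peak_id"].isin(tf_hits).to_numpy()
        attributable = np.zeros_like(rp)
        if mask.any():
            np.add.at(attributable, gi[mask], wx[mask])
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(rp > 0, attributable / rp, 0.0)
        per_sample_p = []
        per_sample_z = []
        for si, sample in enumerate(samples):
            zval, p = wilcox_greater(prop[q_idx, si], prop[b_idx, si])
            per_sample_p.append(p)
            per_sample_z.append(zval)
            sample_rows.append((tf_id, sample, zval, p))
        p_summary = min(1.0, min(per_sample_p) * len(samples))
        summary_rows.append((tf_id, float(np.mean(per_sample_z)), p_summary))
        for g in sorted(query_genes):
            i = gene_index[g]
            for si, sample in enumerate(samples):
                detail_rows.append(
                    (g, tf_id, sample, attributable[i, si], rp[i, si], prop[i, si])
                )
    if n_ignored:
        logger.warning(
            "findit_region_rp: %d TF-hit peaks absent from the RP profile ignored", n_ignored
        )
    summary = _finalize_ranking(pd.DataFrame(summary_rows, columns=["tf_id", "statistic", "p"]))
    per_sample = pd.DataFrame(sample_rows, columns=["tf_id", "sample", "z_stat", "p"])
    per_sample["p_adj"] = np.nan
    for sample in samples:
        m = per_sample["sample"] == sample
        per_sample.loc[m, "p_adj"] = multipletests(
            per_sample.loc[m, "p"].to_numpy(), method="fdr_bh"
        )[1]
    detail = pd.DataFrame(
        detail_rows,
        columns=["gene_id", "tf_id", "sample", "attributable_rp", "total_rp", "proportion"],
    )
    return summary, per_sample, detail


# ---------------------------------------------------------------------------
# MARA
# ---------------------------------------------------------------------------

@dataclass
class MARAResult:
    """Motif activities from ridge regression of signal on site counts."""

    activity: pd.DataFrame  # motif x sample
    site_counts: pd.DataFrame  # peak x motif (as supplied)
    lam: float
    variability: pd.Series  # motif -> stddev of activity across samples

    def top_variable(self, k: int = 40) -> pd.DataFrame:
        """Activity rows of the k most variable motifs, most variable first."""
        order = self.variability.sort_values(ascending=False).index[:k]
        return self.activity.loc[order]


def findit_mara(
    peak_signal: pd.DataFrame,
    site_counts: pd.DataFrame,
    lambda_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0),
) -> MARAResult:
    """Motif activity response analysis.

    The signal matrix is transformed by log2(x + 1), then centered per peak
    and per sample; site counts are centered per motif. Per-sample motif
    activities solve the ridge problem x_s ~ N a_s with one shared penalty
    chosen from lambda_grid by generalized cross-validation averaged over
    samples. Activity rows are centered across samples (the model only
    identifies activity differences) and the per-motif standard deviation
    across samples measures activity variability.
    """
    if peak_signal.shape[1] < 2:
        raise ValueError("MARA needs >= 2 samples")
    if list(site_counts.index) != list(peak_signal.index):
        site_counts = site_counts.loc[peak_signal.index]
    lam_grid = [float(l) for l in lambda_grid]
    x = np.log2(peak_signal.to_numpy(dtype=float) + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    x = x - x.mean(axis=0, keepdims=True)
    nmat = site_counts.to_numpy(dtype=float)
    nmat = nmat - nmat.mean(axis=0, keepdims=True)
    n_peaks, n_motifs = nmat.shape
    u, s, vt = np.linalg.svd(nmat, full_matrices=False)
    if min(lam_grid) <= 0 and np.min(s) < 1e-10 * np.max(s):
        raise ValueError("site-count matrix is rank-deficient; use lambda > 0")
    utx = u.T @ x  # (r, samples)
    best = None
    for lam in lam_grid:
        shrink = s**2 / (s**2 + lam)
        fitted = u @ (shrink[:, None] * utx)
        df_eff = shrink.sum()
        resid = ((x - fitted) ** 2).sum(axis=0)
        gcv = (resid / n_peaks) / (1.0 - df_eff / n_peaks) ** 2
        score = float(gcv.mean())
        if best is None or score < best[0]:
            best = (score, lam)
    lam = best[1]
    coef = vt.T @ ((s / (s**2 + lam))[:, None] * utx)  # motifs x samples
    coef = coef - coef.mean(axis=1, keepdims=True)
    activity = pd.DataFrame(coef, index=site_counts.columns, columns=peak_signal.columns)
    variability = activity.std(axis=1, ddof=1).rename("variability")
    return MARAResult(activity=activity, site_counts=site_counts, lam=lam, variability=variability)


# ---------------------------------------------------------------------------
# replicate integration and co-occurrence
# ---------------------------------------------------------------------------

def integrate_replicates(
    tables: list[pd.DataFrame], value: str = "p", method: str = "geometric_mean"
) -> pd.DataFrame:
    """Combine TF rankings from replicates or sources into one table.

    method 'geometric_mean' combines p-values multiplicatively, 'stouffer'
    sums the per-table z columns divided by sqrt(k), 'mean_rank' averages
    ranks. TFs absent from any table are dropped with a warning.
    """
    if not tables:
        raise ValueError("no tables to integrate")
    common = set(tables[0]["tf_id"])
    union = set()
    for t in tables:
        common &= set(t["tf_id"])
        union |= set(t["tf_id"])
    if union - common:
        logger.warning(
            "integrate_replicates: %d TFs missing from some table dropped", len(union - common)
        )
    if not common:
        raise ValueError("no TF shared by all tables")
    idx = sorted(common)
    aligned = [t.set_index("tf_id").loc[idx] for t in tables]
    k = len(aligned)
    if method == "geometric_mean":
        logp = np.mean([np.log(np.clip(a["p"].to_numpy(float), 1e-300, 1.0)) for a in aligned], axis=0)
        combined_p = np.exp(logp)
        stat = np.mean([a["statistic"].to_numpy(float) for a in aligned], axis=0)
        df = pd.DataFrame({"tf_id": idx, "statistic": stat, "p": combined_p})
        return _finalize_ranking(df)
    if method == "stouffer":
        zsum = np.sum([a["z"].to_numpy(float) for a in aligned], axis=0) / math.sqrt(k)
        p = stats.norm.sf(zsum)
        df = pd.DataFrame({"tf_id": idx, "statistic": zsum, "p": p})
        return _finalize_ranking(df)
    if method == "mean_rank":
        mean_rank = np.mean([a["rank"].to_numpy(float) for a in aligned], axis=0)
        df = pd.DataFrame({"tf_id": idx, "statistic": -mean_rank, "p": mean_rank / len(idx)})
        df["mean_rank"] = mean_rank
        out = _finalize_ranking(df)
        out["p"] = np.nan
        out["p_adj"] = np.nan
        return out
    raise ValueError("method must be 'geometric_mean', 'stouffer' or 'mean_rank'")


def jaccard_tf(sets: dict[str, set[str]], restrict_to: set[str] | None = None) -> pd.DataFrame:
    """Symmetric TF x TF Jaccard matrix of hit/target co-occurrence.

    Sets are optionally intersected with a query peak/gene set first.
    J(a, a) = 1 by convention; a pair of empty sets scores 0.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 TFs")
    tf_ids = sorted(sets)
    if restrict_to is not None:
        sets = {t: sets[t] & set(restrict_to) for t in tf_ids}
    mat = np.zeros((len(tf_ids), len(tf_ids)))
    for i, a in enumerate(tf_ids):
        for j, b in enumerate(tf_ids):
            if j < i:
                continue
            if i == j:
                val = 1.0
            else:
                union = sets[a] | sets[b]
                val = len(sets[a] & sets[b]) / len(union) if union else 0.0
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=tf_ids, columns=tf_ids)
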