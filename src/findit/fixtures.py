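"""Synthetic genomes, peak sets, matrices and TF worlds with planted structure.

Every generator is deterministic under its seed and emits objects (and files)
that pass the package's own readers unchanged. The default world mirrors a
compact-genome time-course study: seven ordered samples (time points), one
planted TF whose ChIP hits and perturbed-expression targets coincide, and
forty decoy TFs binding at a uniform background rate. Counts are drawn from
a negative binomial to mimic sequencing depth dispersion — a fixture
convention, not a claim about any real dataset.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from findit import genome_io
from findit.mm_anno import AnnoConfig, mm_gene_scan

__all__ = ["FixtureSpec", "TFWorld", "make_genome", "make_signal", "make_tf_world",
           "make_cor_fixture", "make_mara_fixture", "make_null_world",
           "tf_chip_peaks", "write_world"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic world.

    Defaults follow the study shape the package targets: a small, compact
    genome (2 chromosomes x 2 Mb), 7 time-point samples, 1 planted TF plus
    40 decoys, a 20 kb scan radius, and strong planted effects (the planted
    TF binds 80% of the query features, decoys 10%).
    """

    n_chrom: int = 2
    chrom_len: int = 2_000_000
    n_genes: int = 100
    n_peaks: int = 300
    n_samples: int = 7
    n_tfs: int = 41
    planted_tf_id: str = "TF_planted"
    planted_effect: float = 0.8
    bg_rate: float = 0.1
    n_query_peaks: int = 60
    n_query_genes: int = 30
    cor_pairs: int = 5
    cor_target_r: float = 0.95
    dge_effect: float = 3.0
    scan_length: int = 20_000
    in_window_frac: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chrom, self.n_genes, self.n_samples, self.n_tfs) < 1 or self.n_peaks < 0:
            raise ValueError("counts must be >= 1 (peaks may be 0)")
        if not (0 <= self.planted_effect <= 1):
            raise ValueError("planted_effect must be in [0, 1]")


def _nb_counts(rng: np.random.Generator, mean: float, size, dispersion: float = 10.0):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def make_genome(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes with guaranteed spacing and peaks biased into scan windows.

    Genes occupy one uniform slot each (jittered within the slot) so TSSs
    never collide; a fraction ``in_window_frac`` of peaks is anchored within
    the scan window of a random gene, the rest fall uniformly.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = np.full(spec.n_chrom, spec.n_genes // spec.n_chrom)
    per_chrom[: spec.n_genes % spec.n_chrom] += 1
    gene_rows = []
    gid = 0
    for ci in range(spec.n_chrom):
        chrom = f"chr{ci + 1}"
        n = int(per_chrom[ci])
        if n == 0:
            continue
        slot = spec.chrom_len // n
        max_len = min(3000, slot - 10)
        if max_len < 200:
            raise ValueError(
                f"infeasible packing: {n} genes do not fit in {spec.chrom_len} bp"
            )
        for k in range(n):
            glen = int(rng.integers(1000, max_len + 1)) if max_len > 1000 else max_len
            start = k * slot + int(rng.integers(0, slot - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            gene_rows.append((f"g{gid:04d}", chrom, start, start + glen, strand))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    peak_rows = []
    for _ in range(spec.n_peaks):
        width = int(rng.integers(150, 400))
        if rng.random() < spec.in_window_frac and len(genes):
            g = genes.iloc[int(rng.integers(0, len(genes)))]
            offset = int(rng.integers(-spec.scan_length + width, spec.scan_length - width))
            anchor = int(g["tss"]) + offset
            chrom = g["chrom"]
        else:
            chrom = f"chr{int(rng.integers(1, spec.n_chrom + 1))}"
            anchor = int(rng.integers(width, spec.chrom_len - width))
        anchor = int(np.clip(anchor, width // 2, spec.chrom_len - width))
        start = anchor - width // 2
        end = start + width
        summit = anchor - start
        peak_rows.append((chrom, start, end, summit))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "summit_offset"])
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    peaks.insert(0, "peak_id", [f"pk{i + 1:05d}" for i in range(len(peaks))])
    peaks["summit_offset"] = peaks["summit_offset"].astype("Int64")
    peaks["score"] = np.round(rng.uniform(10, 1000, len(peaks)), 2)
    # drop coordinate duplicates that would make ids ambiguous after sorting
    peaks = peaks.drop_duplicates(["chrom", "start", "end"]).reset_index(drop=True)
    return genes, peaks


def _planted_pair(
    rng: np.random.Generator, base: np.ndarray, target_r: float, max_tries: int = 2000
) -> np.ndarray:
    """Draw a non-negative vector whose sample correlation with base is target_r +/- 0.05."""
    n = len(base)
    if target_r >= 1.0:
        return base * float(rng.uniform(0.5, 2.0))
    bz = (base - base.mean()) / base.std()
    for _ in range(max_tries):
        noise = rng.standard_normal(n)
        y = target_r * bz + np.sqrt(1 - target_r**2) * noise
        y = y * 10.0 + 60.0
        y = np.clip(y, 0.0, None)
        r = np.corrcoef(base, y)[0, 1]
        if abs(r - target_r) <= 0.05:
            return y
    raise ValueError(
        f"could not plant correlation {target_r} at n={n}; increase n_samples"
    )


def make_signal(
    spec: FixtureSpec, links: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None, peaks: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak and gene signal matrices with planted correlations and a trend.

    The first ``cor_pairs`` scan links (distinct peaks and genes) are planted
    with peak-gene correlation near ``cor_target_r``; one designated peak and
    gene pair carries a monotone temporal trend across the ordered samples.
    All other rows are independent negative-binomial noise.
    """
    rng = np.random.default_rng(spec.seed + 1)
    samples = [f"t{i}" for i in range(spec.n_samples)]
    if genes is None or peaks is None:
        genes, peaks = make_genome(spec)
    if links is None:
        links = mm_gene_scan(peaks, genes, AnnoConfig(scan_length=spec.scan_length))
    peak_mat = pd.DataFrame(
        _nb_counts(rng, 50.0, (len(peaks), spec.n_samples)),
        index=peaks["peak_id"].to_numpy(), columns=samples,
    )
    gene_mat = pd.DataFrame(
        _nb_counts(rng, 100.0, (len(genes), spec.n_samples)),
        index=genes["gene_id"].to_numpy(), columns=samples,
    )
    scan = links[links["mode"] == "scan"]
    used_p: set[str] = set()
    used_g: set[str] = set()
    planted = []
    for row in scan.itertuples(index=False):
        if len(planted) >= spec.cor_pairs:
            break
        if row.peak_id in used_p or row.gene_id in used_g:
            continue
        base = peak_mat.loc[row.peak_id].to_numpy()
        if base.std() == 0:
            continue
        gene_mat.loc[row.gene_id] = _planted_pair(rng, base, spec.cor_target_r)
        used_p.add(row.peak_id)
        used_g.add(row.gene_id)
        planted.append((row.peak_id, row.gene_id))
    # monotone temporal trend on one untouched peak and gene
    trend = np.linspace(10.0, 200.0, spec.n_samples) + rng.uniform(0, 1.0, spec.n_samples)
    trend = np.sort(trend)
    for pid in peak_mat.index:
        if pid not in used_p:
            peak_mat.loc[pid] = trend
            break
    for gid in gene_mat.index:
        if gid not in used_g:
            gene_mat.loc[gid] = trend * 2.0
            break
    peak_mat.attrs["planted_pairs"] = planted
    gene_mat.attrs["planted_pairs"] = planted
    return peak_mat, gene_mat


@dataclass
class TFWorld:
    """A TF-hit universe with one planted signal and coordinated DGE."""

    hits: dict[str, set[str]]
    tt_pairs: pd.DataFrame
    dge: pd.DataFrame
    query_peaks: list[str]
    query_genes: list[str]
    planted_targets: list[str]


def make_tf_world(
    spec: FixtureSpec, peaks: pd.DataFrame, genes: pd.DataFrame,
    links: pd.DataFrame | None = None,
) -> TFWorld:
    """Plant one influential TF among decoys.

    A set of query genes is designated; the query peak set is the peaks
    scan-linked to those genes (capturing the regulatory neighbourhood a
    real influential TF occupies). The planted TF binds ``planted_effect``
    of the query peaks and targets ``planted_effect`` of the query genes;
    decoys bind/target at ``bg_rate`` everywhere. The DGE table upregulates
    the planted targets (|log2FC| around ``dge_effect``, tiny padj) and
    leaves everything else static. Setting planted_effect equal to bg_rate
    produces a null world.
    """
    rng = np.random.default_rng(spec.seed + 2)
    peak_ids = peaks["peak_id"].tolist()
    gene_ids = genes["gene_id"].tolist()
    nq_g = min(spec.n_query_genes, len(gene_ids))
    query_genes = list(rng.choice(gene_ids, nq_g, replace=False))
    if links is not None:
        scan = links[links["mode"] == "scan"]
        query_peaks = sorted(set(scan.loc[scan["gene_id"].isin(query_genes), "peak_id"]))
        if not query_peaks:
            raise ValueError("query genes have no scan-linked peaks")
    else:
        nq_p = min(spec.n_query_peaks, len(peak_ids))
        query_peaks = list(rng.choice(peak_ids, nq_p, replace=False))
    bg_peaks = [p for p in peak_ids if p not in set(query_peaks)]
    bg_genes = [g for g in gene_ids if g not in set(query_genes)]

    hits: dict[str, set[str]] = {}
    tf_ids = [spec.planted_tf_id] + [f"TF_decoy{i:02d}" for i in range(1, spec.n_tfs)]
    for tf in tf_ids:
        qr = spec.planted_effect if tf == spec.planted_tf_id else spec.bg_rate
        sel_q = [p for p in query_peaks if rng.random() < qr]
        sel_b = [p for p in bg_peaks if rng.random() < spec.bg_rate]
        hits[tf] = set(sel_q) | set(sel_b)

    pair_rows = []
    planted_targets: list[str] = []
    for tf in tf_ids:
        if tf == spec.planted_tf_id:
            targets = [g for g in query_genes if rng.random() < spec.planted_effect]
            targets += [g for g in bg_genes if rng.random() < spec.bg_rate]
            planted_targets = sorted(set(targets) & set(query_genes))
        else:
            targets = [g for g in gene_ids if rng.random() < spec.bg_rate]
        for g in sorted(set(targets)):
            pair_rows.append((tf, g, round(float(rng.uniform(0.5, 1.0)), 3)))
    tt_pairs = pd.DataFrame(pair_rows, columns=["tf_id", "target_gene_id", "confidence"])

    dge_rows = []
    planted_set = set(planted_targets)
    for g in gene_ids:
        if g in planted_set:
            lfc = float(rng.normal(spec.dge_effect, 0.5))
            lfc = max(lfc, 1.5)
            padj = float(10.0 ** -rng.uniform(5, 50))
        else:
            lfc = float(rng.normal(0.0, 0.3))
            padj = float(rng.uniform(0.05, 1.0))
        dge_rows.append((g, lfc, padj))
    dge = genome_io.categorize_dge(
        pd.DataFrame(dge_rows, columns=["gene_id", "log2fc", "padj"])
    )
    return TFWorld(
        hits=hits, tt_pairs=tt_pairs, dge=dge,
        query_peaks=sorted(query_peaks), query_genes=sorted(query_genes),
        planted_targets=planted_targets,
    )


def tf_chip_peaks(peaks: pd.DataFrame, hits: dict[str, set[str]], tf_id: str) -> pd.DataFrame:
    """The peak intervals a TF hits, as a standalone ChIP-like peak set."""
    sel = peaks[peaks["peak_id"].isin(hits[tf_id])]
    return sel.reset_index(drop=True)


def make_mara_fixture(
    seed: int = 0,
    n_peaks: int = 200,
    n_motifs: int = 10,
    n_samples: int = 7,
    noise_frac: float = 0.1,
    planted_motif_scale: float = 0.0,
) -> dict:
    """Signal generated from known motif activities for recovery testing.

    Site counts are Poisson; true activities are centered Gaussian rows.
    The observed matrix is built so that log2(x + 1) with double centering
    returns counts x activities plus Gaussian noise with standard deviation
    ``noise_frac`` of the clean signal's. With ``planted_motif_scale`` > 1
    the first motif's activity varies that many times more than the decoys',
    making it the top variable motif by construction.
    """
    rng = np.random.default_rng(seed)
    motifs = [f"m{j:02d}" for j in range(n_motifs)]
    samples = [f"t{i}" for i in range(n_samples)]
    nmat = rng.poisson(2.0, (n_peaks, n_motifs)).astype(float)
    a0 = rng.standard_normal((n_motifs, n_samples))
    if planted_motif_scale:
        a0[0] *= planted_motif_scale
    a0 -= a0.mean(axis=1, keepdims=True)
    nc = nmat - nmat.mean(axis=0, keepdims=True)
    clean = nc @ a0
    noise = rng.standard_normal(clean.shape) * (noise_frac * clean.std())
    raw = clean + noise
    raw = raw - raw.min() + 1.0  # keep log2 argument positive
    signal = pd.DataFrame(
        np.exp2(raw) - 1.0,
        index=[f"pk{i:04d}" for i in range(n_peaks)], columns=samples,
    )
    site_counts = pd.DataFrame(nmat, index=signal.index, columns=motifs)
    activity = pd.DataFrame(a0, index=motifs, columns=samples)
    return {"signal": signal, "site_counts": site_counts, "activity": activity}


def make_null_world(
    seed: int = 0,
    n_peaks: int = 2000,
    n_query: int = 400,
    n_tfs: int = 50,
    hit_rate: float = 0.3,
) -> dict:
    """No-signal world: hits assigned uniformly at random, query drawn at random.

    Every TF-vs-query association is null by construction, so the fraction
    of tests below any level alpha estimates the statistics' actual size.
    """
    rng = np.random.default_rng(seed)
    ids = [f"x{i:05d}" for i in range(n_peaks)]
    query = set(rng.choice(ids, n_query, replace=False))
    hits = {
        f"TF{j:02d}": {ids[i] for i in np.flatnonzero(rng.random(n_peaks) < hit_rate)}
        for j in range(n_tfs)
    }
    return {"ids": ids, "query": query, "hits": hits}


def make_cor_fixture(
    seed: int = 0,
    n_genes: int = 50,
    n_planted: int = 5,
    target_r: float = 0.95,
    n_samples: int = 10,
) -> dict:
    """Enhancer-promoter world: per gene one promoter and one distal peak.

    Genes sit far apart so scan windows never overlap; ``n_planted`` distal
    peaks correlate with their promoter near ``target_r`` and the rest are
    independent noise. Returns peaks, genes, the peak signal matrix and the
    planted (distal, gene) pairs.
    """
    rng = np.random.default_rng(seed)
    spacing = 100_000
    gene_rows, peak_rows = [], []
    for i in range(n_genes):
        tss = spacing * (i + 1)
        gene_rows.append((f"g{i + 1:03d}", "chr1", tss, tss + 2000, "+", tss))
        peak_rows.append((f"prom{i + 1:03d}", "chr1", tss - 150, tss + 150, 150, None))
        peak_rows.append((f"dist{i + 1:03d}", "chr1", tss + 5000, tss + 5300, 150, None))
    genes = pd.DataFrame(gene_rows, columns=genome_io.GENE_COLUMNS)
    peaks = pd.DataFrame(peak_rows, columns=genome_io.PEAK_COLUMNS)
    peaks["summit_offset"] = peaks["summit_offset"].astype("Int64")
    samples = [f"t{i}" for i in range(n_samples)]
    signal = pd.DataFrame(
        _nb_counts(rng, 60.0, (len(peaks), n_samples)) + rng.uniform(0, 1.0, (len(peaks), n_samples)),
        index=peaks["peak_id"].to_numpy(), columns=samples,
    )
    planted = []
    for i in range(n_planted):
        prom, dist, gene = f"prom{i + 1:03d}", f"dist{i + 1:03d}", f"g{i + 1:03d}"
        signal.loc[dist] = _planted_pair(rng, signal.loc[prom].to_numpy(), target_r)
        planted.append((dist, gene))
    return {"genes": genes, "peaks": peaks, "signal": signal, "planted": planted}


def write_world(spec: FixtureSpec, outdir: str | os.PathLike) -> dict:
    """Generate a full world and write every artifact plus a manifest."""
    os.makedirs(outdir, exist_ok=True)
    genes, peaks = make_genome(spec)
    links = mm_gene_scan(peaks, genes, AnnoConfig(scan_length=spec.scan_length))
    peak_mat, gene_mat = make_signal(spec, links, genes, peaks)
    world = make_tf_world(spec, peaks, genes, links)
    paths = {
        "genes": "genes.gff3", "peaks": "peaks.bed",
        "peak_signal": "peak_signal.tsv", "gene_expr": "gene_expr.tsv",
        "tf_hits": "tf_hits.tsv", "tt_pairs": "tt_pairs.tsv", "dge": "dge.tsv",
        "query_peaks": "query_peaks.txt", "query_genes": "query_genes.txt",
    }
    paths = {k: os.path.join(outdir, v) for k, v in paths.items()}
    genome_io.write_gene_annotation(genes, paths["genes"])
    genome_io.write_peak_file(peaks, paths["peaks"])
    peak_mat.rename_axis("peak_id").to_csv(paths["peak_signal"], sep="\t")
    gene_mat.rename_axis("gene_id").to_csv(paths["gene_expr"], sep="\t")
    hit_rows = [(tf, p) for tf in sorted(world.hits) for p in sorted(world.hits[tf])]
    pd.DataFrame(hit_rows, columns=["tf_id", "peak_id"]).to_csv(
        paths["tf_hits"], sep="\t", index=False
    )
    world.tt_pairs.to_csv(paths["tt_pairs"], sep="\t", index=False)
    world.dge.to_csv(paths["dge"], sep="\t", index=False)
    with open(paths["query_peaks"], "w") as fh:
        fh.write("\n".join(world.query_peaks) + "\n")
    with open(paths["query_genes"], "w") as fh:
        fh.write("\n".join(world.query_genes) + "\n")
    manifest = {"spec": asdict(spec), "files": {k: os.path.basename(v) for k, v in paths.items()}}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"genes": genes, "peaks": peaks, "links": links,
            "peak_signal": peak_mat, "gene_expr": gene_mat, "world": world,
            "paths": paths}
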