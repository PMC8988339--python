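# Methods

## Coordinate model

All internal coordinates are 0-based, half-open (BED convention); GFF3/GTF
input is converted at the I/O boundary and nowhere else. A gene's TSS is
the 5' end of its feature span — `start` on '+', `end − 1` on '−'. For
multi-isoform annotations this is the gene-level span's 5' end; no isoform
selection is attempted. A peak's anchor is its summit when the file records
one (narrowPeak column 10), otherwise the interval midpoint (integer floor
division); all distances are anchor-to-TSS, signed negative when the anchor
lies 5' of the TSS in the gene's orientation.

## Annotation strategies

*Nearest gene* minimizes |anchor − TSS| over the peak's chromosome; ties
break to the smaller distance then the lexicographically smaller `gene_id`,
making output deterministic. *Gene scan* assigns a peak to every gene whose
window TSS ± `scan_length` contains the anchor; `scan_length` is a per-side
radius, default 20,000 bp — appropriate for compact genomes, and the single
most consequential tunable since it bounds both the link set and the RP
support. Orphan peaks fall back to nearest-gene links tagged
`nearest_fallback` so downstream RP can exclude them. *Gene bound* runs
nearest-gene first and then links each still-uncovered query gene to its
nearest peak; query genes on peakless chromosomes are reported as
unresolvable rather than erroring. The nearest-peak fallback measures to
the TSS only, not the gene body.

## Peak-gene correlation

Pearson correlation (Spearman optional) across samples, on values as
supplied — no internal log transform; normalization is deliberately the
caller's job, recorded here so nobody assumes otherwise. The p-value is the
two-sided test of r via t = r·√((n−2)/(1−r²)) with n − 2 df; for Spearman
the same transform is applied to the rank correlation. Zero-variance rows
yield an undefined r (NaN) excluded from filtering — an undefined
correlation must not masquerade as evidence of absence. Computation
proceeds from n = 3 but the output carries n; correlation at few paired
samples is fragile, which is exactly why the promoter-based mode exists:
`enhancer_promoter_cor` needs only the accessibility matrix, declaring the
peak nearest each TSS the gene's promoter and correlating every other peak
within the scan window against it. The high-confidence filter keeps links
with r > 0.8 and raw p < 0.01; raw rather than adjusted p is used because
the filter is a screen whose operating point was chosen on raw p, and both
thresholds are exposed (`r_min`, `p_max`).

## Regulatory potential

The decay weight is w(d) = 2^(−d/Δ): w(0) = 1 and w(Δ) = ½, so Δ is a
half-decay distance in bp. Defaults are Δ = 1 kb for TF ChIP peaks (sharp
binding) and Δ = 10 kb for accessibility (broad landscapes), both exposed;
the window (default = `scan_length`) truncates support. Region mode sums
w·signal over scan links only (fallback links excluded; genes without scan
links keep explicit zero rows). Coverage mode integrates per base over
[TSS − window, TSS + window] using closed-form partial geometric sums per
bedGraph interval, exact to the per-base definition within 1e−9. TF-hit
mode gives each peak unit weight; `rp_rank` is the descending rank of
`sum_rp` with average mid-ranks, so rank 1 is the strongest regulatory
neighbourhood. RP is linear in signal and strictly increases as a
contributing peak moves toward the TSS. No exon masking or
promoter-exclusion refinements are applied.

## Rank-product target calling

`diff_rank` is the ascending mid-rank of padj within the user-selected
expression category (default `up`; `down` and `both` available) — ranking
within the perturbation-consistent direction keeps repressed bystanders
from diluting the list. `rp_rank` is recomputed after intersecting the
ChIP and DGE gene universes (flag `recompute_rp_rank=False` keeps
full-universe ranks). The product `rp_rank × diff_rank` is exact including
fractional mid-ranks; only ranks enter, so any strictly monotone transform
of `sum_rp` or padj leaves the output unchanged. Final ordering is by the
ascending mid-rank of the product with lexicographic `gene_id` as
tie-break.

## TF statistics

All six tests are one-sided in the enrichment direction, since the
scientific question is always over-representation. Within one call,
p-values are Benjamini–Hochberg adjusted across TFs; `rank` is the position
under (p ascending, statistic descending, tf_id); and
z = Φ⁻¹((n − rank + 0.5)/n) — the 0.5/n offset keeps extremes finite.

* **Fisher**: one-sided hypergeometric tail of the 2×2 query/background ×
  hit/miss table (via the scipy hypergeometric survival function, which
  agrees with exact integer summation to ~1e−15); statistic = sample odds
  ratio with Haldane 0.5 correction when a cell is zero.
* **Wilcoxon** (used by `findit_enrich_wilcox`, `findit_tfhit`,
  `findit_region_rp`): authored in-package. When the smaller group has ≤ 8
  observations and the arrangement count is ≤ 200,000, the exact
  permutation null is enumerated over rank subsets — ties included, since
  mid-ranks enumerate as naturally as distinct ranks. Otherwise the normal
  approximation with tie and continuity corrections applies. All
  observations tied ⇒ p = 1 (no evidence).
* **TT-pair**: hypergeometric over-representation of a TF's known targets
  in the query gene set, GO-enrichment style; overlapping gene ids are
  reported for drill-down.
* **TF-hit**: per-gene binding-site counts are the number of TF-bound peaks
  scan-linked to the gene — unweighted by default, with a `weighted` option
  applying w(d); counts of query genes vs background enter the Wilcoxon.
* **Region-RP**: the TF-attributable RP of gene g in sample s sums w·signal
  over g's linked peaks bound by the TF; dividing by total RP gives a
  proportion (0 when RP = 0) whose scale-invariance makes samples
  comparable. Per sample, query vs background proportions enter the
  Wilcoxon; per-sample rankings are reported alongside a summary p =
  Bonferroni-corrected minimum across samples (samples are few and
  dependent, so FDR across them would be anticonservative). A per-(gene,
  TF, sample) detail table supports gene-level inspection.
* **MARA**: the signal matrix is log2(x+1)-transformed, then centered per
  peak and per sample; site counts are centered per motif (the minimal
  preprocessing that makes per-sample activities identifiable, recorded in
  output headers). Activities solve ridge regression per sample with one
  shared λ selected from a grid by generalized cross-validation averaged
  over samples (SVD once, all λ and samples reuse it); activity rows are
  re-centered — the model only identifies activity *differences* across
  samples — and per-motif standard deviation across samples measures
  variability. A rank-deficient count matrix with λ = 0 raises an error
  directing the user to λ > 0.

Replicate integration combines aligned rankings by geometric-mean p
(default), Stouffer's Σz/√k on the rank-derived z columns, or mean rank;
TFs absent from any table are dropped with a logged count, as a combined
coordinate needs all replicates. Jaccard co-occurrence is computed on hit
or target sets, optionally restricted to the query set; a pair of empty
sets is defined as 0 and the diagonal as 1.

## Synthetic data: what it emulates and what it cannot show

The generator mirrors the shape of a compact-genome developmental time
course: 2 chromosomes × 2 Mb, 100 genes placed in uniform jittered slots
(so TSSs never collide), 300 peaks of 150–400 bp with 80% anchored inside
some gene's scan window, 7 ordered samples, negative-binomial counts
(dispersion 10 — a fixture convention mimicking sequencing overdispersion,
not a claim about the method), one planted TF plus 40 decoys. The planted
TF binds 80% of the peaks linked to a designated 30-gene query set while
decoys bind 10% everywhere; its targets are upregulated (log2FC ≈ 3, padj
10^−5..10^−50) and everything else is static. Setting the planted effect
equal to the background rate yields a null world. The enhancer-promoter
fixture places one promoter and one distal peak per gene, 100 kb between
genes so windows never overlap, with 5 of 50 distal peaks correlated near
r = 0.95 over 10 samples — 10 rather than the minimum 8 because at n = 8
the r > 0.8 / p < 0.01 screen still passes ~1% of null links, making exact
recovery a coin flip rather than a property of the method. The MARA fixture
generates signal exactly as counts × known activities plus Gaussian noise
at 10% of the clean signal's scale.

Passing tests on these worlds show the algorithms do what their definitions
say under planted, well-separated signal; they do not show robustness to
the things real data add — mappability artifacts, copy-number and GC
biases, correlated replicates, motif redundancy between TF families,
isoform-dependent TSS choice, or trans-acting effects uncoupled from
binding. Recovery rates near 100% here are a correctness floor, not a
performance claim.

Calibration fixtures are sized so that the asymptotics the tests assume
actually hold: enrichment nulls use an 8,000-peak universe with a
1,600-peak query, making the discrete exact tests' achievable levels nearly
continuous, and binding-count nulls use ~7.6 scan links per gene (300
genes, 1,800 peaks), where direct simulation puts the Wilcoxon's size at
0.050. Each null test draws its own independent query: one shared query
across 50 TFs would correlate the tests through the gene-exposure geometry
and invalidate a binomial error bar on the pooled false-positive rate.

## Numerical choices and degenerate inputs

Deterministic tie-breaks everywhere (documented per operation above);
identical inputs give byte-identical outputs, and every output TSV header
records the tool version and parameter set. Simulation sizes throughout the
test suite and acceptance script (50–100 replicates, 2,000-table oracle
sweeps) were chosen as the smallest sizes at which the binomial error bars
are decisive. Geometric sums use the stable closed form (q^a − q^{b+1})/(1 − q).
Correlations are clipped to [−1, 1] before the t transform; |r| = 1 maps to
p = 0. Empty query sets, query = universe (no background), disjoint gene
universes, and empty TF peak sets raise errors; peaks on gene-less
chromosomes, genes on coverage-less chromosomes, TF hits outside the known
peak universe, and DGE rows outside the gene universe degrade gracefully
with logged counts.

## Known limitations

The nearest-peak fallback and promoter definition use a single TSS per
gene. `calc_rp_coverage` integrates per base and is O(window) per gene in
the worst case. MARA's GCV selects one λ shared across samples, which can
underfit when samples differ greatly in noise. The Wilcoxon normal
approximation is conservative-to-nominal only with ≥ ~5 distinct count
levels; very sparse binding tables at small gene universes should use the
exact path (small groups) or the Fisher statistic instead.
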