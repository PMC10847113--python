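# Methods

This note documents the models, parameters and numerical choices behind
`glioconnect`, and what the synthetic-data experiments do and do not show.

## Normalisation, scaling and quality control

Single-cell counts are library-size normalised to
`ln(1 + s·c/total)` with scale factor `s = 10⁴`.  Reported score vectors may
be z-scaled (sample sd, n−1 denominator) and winsorized to [−3, 3], in that
order; a zero-variance vector yields zeros with a warning rather than NaNs.

Fixed QC removes cells with detected genes outside [200, 8000], total counts
outside [500, 80 000], or > 10 % mitochondrial counts (genes flagged in
`gene_meta` or by the configurable `MT-` prefix; absent annotation skips the
rule with a warning).  A one-sided outlier rule then removes cells above
median + 3 × scaled MAD (1.4826 × median absolute deviation) of either the
gene or the count totals — either criterion suffices.  When the MAD is zero
the rule degenerates to removing everything strictly above the median (with
a 1e-12 guard); this is deliberate and documented rather than an error.
Bulk tables drop genes with total counts below 10 across all samples.

## Differential expression and signature cascades

*Single-cell route.*  Per line, a two-sided Wilcoxon rank-sum test per gene
on normalised values, pre-filtered to genes detected in ≥ 10 % of either
group with |logFC| ≥ 0.25.  The log fold change is the natural-log
difference of expm1-averaged group means (+1 pseudocount) — the convention
of the marker-test tooling this mirrors; the 0.4 aggregation threshold is
applied on this natural-log scale (a log2 switch is provided).  Bonferroni
correction runs over all genes in the matrix, not just pre-filter
survivors, again following that tooling.  The three-line aggregation keeps a
gene significant (adjusted p < 0.05) with consistent direction in all three
lines, or with consistent direction and |logFC| ≥ 0.4 in at least two lines
(the fold-change bar applies to both qualifying lines); genes with
conflicting significant directions are dropped.

*Bulk route.*  Per-gene negative-binomial GLM with a group term and a
cell-line covariate; median-of-ratios size factors; Wald test on the group
coefficient; Benjamini–Hochberg adjustment.  Dispersion is a design-aware
method-of-moments estimate — a Poisson fit with the full design supplies
fitted means, the residual moment estimator gives a per-gene φ, and each φ
is shrunk halfway (log scale) toward an exponential mean–dispersion trend.
This keeps null p-values near-uniform in simulation while avoiding full
empirical-Bayes machinery; small designs (n ≈ 6) remain slightly liberal,
as Wald tests are.  Log2 fold changes are reported unshrunk; thresholds
(adjusted p < 0.05, |log2FC| ≥ 1, boundary inclusive) are applied to the
unshrunk estimates.

*Labeling-intensity cascade.*  Three pairwise DEG tables (High-vs-Medium,
Medium-vs-Low, High-vs-Low) pass five ordered filters: FDR ≤ 0.05; present
in ≥ 2 comparisons; consistent direction; log CPM ≥ 2; and membership in the
top/bottom 50 by fold change in *every* comparison where the gene remains
(configurable to *any*).  Ranking for filter 5 is computed over the genes
surviving filters 1–4, within the FDR-significant entries of each
comparison.  Diffusion correction removes from the calcium signature every
gene present, in either direction, in the constitutively labeling control
signature.

## Module scores and classification

Genes are ranked by average normalised expression across cells and cut into
24 equal-frequency bins (ties broken by gene id, so binning is
deterministic).  Each signature gene contributes 100 control genes drawn
seeded and without replacement from its bin; bins smaller than 100
contribute all members.  The score is the mean over signature genes minus
the mean over the pooled controls, so a random gene set scores ≈ 0 and a
set equal to the whole universe scores exactly 0.  The connectivity score
is up-set score minus down-set score; classification is `high` iff
up > down strictly (ties → `low`, the strict reading of the rule).  The
chance control rebuilds the whole scoring path on 100 random signatures of
the derived sizes and averages the confusion metrics.  Quartile groups cut
at the 25th/75th percentiles with linear interpolation (type-7).

Gene-set overlaps use the upper-tail hypergeometric probability
P(X ≥ k); the universe size is always an explicit argument.

## Cell states and cluster typing

State scores are module scores of per-state marker sets, scored with
per-state derived seeds so the assignment is independent of dict order;
argmax ties break by the canonical order AC, MES1, MES2, OPC, NPC1, NPC2,
G1_S, G2_M (warned).  Cycling states participate in assignment but not in
the 2D projection, whose axes name only the six lineage states.  Cluster
typing computes NMS = S_type − S_malignant on cluster-median scores and
calls a cluster non-malignant when its maximal NMS exceeds
median + scaled MAD over all NMS values (the raw-vs-scaled MAD convention is
unstated upstream; scaled is used for consistency with QC); when several
types clear the threshold the largest NMS wins.  Manual reassignment (the
upstream workflow's CNV-based rescue) is supported as an explicit override
map rather than inferred.

## Calcium coactivity

Traces are smoothed with a Gaussian of σ = 10 s (converted to frames);
peaks are local maxima with prominence ≥ ¼ of the smoothed trace's range (a
common peak-finder default, exposed as a parameter); cells with < 4 peaks
are excluded.  For a pair at distance d ≤ 100 µm the admissible lags are
|τ| ∈ [d/25, d/4] s, discretised to whole frames with bounds rounded
inward; τ = 0 is excluded because it implies infinite propagation speed.
The pair statistic is the maximum Pearson correlation of the τ-shifted
a-segment against the b-segment over all admissible τ and all 10-min
segment positions, sliding in 30-s strides (the stride is unstated
upstream).  Correlations over windows are computed with cumulative sums;
zero-variance windows are skipped, and a pair with no defined window is
flagged undefined.

The null shifts the whole partner trace circularly by a random offset
> 5 min before the identical maximisation, so the same traces and the same
number of segment pairs are correlated while each trace's autocorrelation
is preserved.  An earlier variant that drew an independent partner segment
per position was found biased: empirical maxima slide both windows
together, so their combinations are highly correlated, whereas independent
draws explore more of the trace and stochastically enlarge the maximum.
Five null draws per eligible pair (a count unstated upstream) stabilise the
95th-percentile threshold; the percentile uses linear (type-7)
interpolation.  Pairs above the threshold are coactive; the graph is
symmetric by construction.  Activity stratification labels the lowest and
highest ⌈0.05·n⌉ cells by peak count as bottom/top and the cells between
the 47.5th and 52.5th percentiles as middle, with count ties expanding
groups.

## Synthetic data: what it emulates, and what it does not

The single-cell generator draws negative-binomial counts (variance
m + φ·m², gene-shared φ = 0.3 by default, gamma–Poisson mixture) with
per-gene log-normal baseline means (location 0.5, scale 1.0 — chosen so a
default cell's depth and detected-gene count resemble a QC-passing cell),
2 % mitochondrial genes, three lines × two sorted groups of 300 cells, and
40 up / 31 down planted connectivity genes (the sizes of the reference
71-gene signature) at multiplicative effect 3 in the respective sorted
group.  Cell
states are planted as 3× marker boosts on gene blocks orthogonal to the
connectivity genes unless configured to overlap.  The bulk generator adds
per-line log-normal baseline offsets as the covariate signal.  The calcium
generator scatters 20 cells in a 300-µm field, connects every pair within
100 µm (close-but-unconnected pairs do not occur, mirroring contact-based
TM networks — this is what makes planted-graph precision interpretable),
fires Poisson events at 0.01 Hz, propagates each event across an edge with
probability 0.8 delayed by distance/10 µm/s, and renders events as a
half-Gaussian rise + exponential decay kernel (width 5 s — calcium
transients are asymmetric) plus Gaussian noise.  All generators are
seed-deterministic.

Not emulated: ambient RNA, doublets, batch effects, cascading (multi-hop)
calcium propagation, photobleaching and drift.  Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated generative model, not performance on real recordings or real
droplet data.  Note one degeneracy of noise-free traces: a 10-min window
containing a single transient's exponential tail correlates perfectly at
any lag, so lag-recovery checks use event trains dense enough that every
window holds several transients.

## Problem sizes

Tests run the derivation on 3 × 2 × 120-cell matrices with 500–600 genes,
the chance control with 25–30 random sets, and coactivity on 12–20 cells ×
1184 frames; the analysis scripts use 300 cells per group and the full
defaults.  These sizes were chosen so every property (recovery, type-I
error, calibration) is measured with comfortable margins while the whole
suite stays fast enough to run habitually.

## Known limitations

The NB Wald test is not a reimplementation of DESeq2/edgeR internals and
will not match their numbers gene-for-gene; shrinkage of fold changes is an
optional ridge-style device, off by default.  The segment-pairing scheme of
the empirical coactivity maximisation (single window vs sliding) is not
fully specified upstream; the sliding-window reading implemented here is
the more conservative.  Whether τ = 0 was admissible upstream is likewise
unstated; it is excluded here and exposed for diagnostics.  The MAD=0
degenerate branch of the outlier rule removes all strictly-above-median
values, which is aggressive for heavily tied data.
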