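# Methods

This note documents the statistical models behind `hexspot`, the choices
made where a published description leaves room, and what the synthetic
data can and cannot establish.

## Lattice geometry and the neighbor graph

Spots are modeled as a hexagonally packed grid: odd array rows are offset
by half a pitch in x and rows are spaced `pitch · √3/2` in y, so each
interior spot has exactly six neighbors at the pitch distance
(100 µm center-to-center, 55 µm spot diameter by default; a standard
78 × 64 capture area holds 4992 spots).  The neighbor graph connects spots
whose center distance is within a relative tolerance (default 1e-3) of the
pitch.  Boundary spots simply have fewer neighbors; no wrap-around or
padding is applied.

## Normalization and differential expression

Counts are normalized to log CP10K: `log(1 + 1e4 · count / spot_total)`.
The downstream statistics — rank-sum tests, rank correlations, rank-based
signature scores — need a monotone, depth-corrected matrix, not a
particular error model, so no regularized-NB variance stabilization is
fitted; a DESeq-style median-of-ratios option exists for matrices dense
enough to support it.  Spots with zero totals are dropped with a warning.

Marker finding is one-vs-rest per cluster: a two-sided Wilcoxon rank-sum
test per gene (normal approximation with midranks and tie-corrected
variance), a natural-log fold-change `ln((mean(expm1 x_in)+1) /
(mean(expm1 x_rest)+1))` so the conventional `logFC > 0.25` cut applies on
the same scale as common single-cell toolkits, and Benjamini–Hochberg
adjustment **within each cluster across genes** (the behavior of standard
marker-finding functions; a global adjustment is a one-flag alternative).
Significance defaults: logFC > 0.25 and adjusted p < 0.05 — these are
configuration values, not constants.

## Cell-type enrichment (MIA) and composition

Enrichment of cluster DEGs against cell-type marker sets uses the
cumulative hypergeometric distribution.  The universe is **the set of
genes tested for differential expression**, not the whole genome: a larger
universe of never-observed genes would only inflate significance.  Both
tails are reported (enrichment `P(X ≥ k)` and depletion `P(X ≤ k)`), each
computed through the log-survival/log-CDF for stability and clipped to
`[5e-324, 1]`.

When no externally estimated per-spot composition table is supplied, a
marker-score proxy is used: per cell type, the mean normalized expression
of its markers, floored at zero and renormalized per spot to the simplex
(uniform fallback for all-zero spots).  This is a coarse stand-in for
reference-based deconvolution and is tagged as such in outputs.

Cluster composition profiles are compared with a hamming distance on
presence/absence bits: a cell type is "present" in a cluster when its mean
proportion is ≥ 1% (configurable), and the distance is the fraction of
cell types whose bits differ — a metric on the binarized vectors,
normalized to [0, 1] by the number of cell types.

## Spatial correlation

Cell-type co-occurrence is the Pearson correlation of per-spot proportions
across all spots for every unordered pair of types, Holm-adjusted across
the whole family, significant when r ≥ 0.3 **and** adjusted p < 0.05.
Gene–gene spatial correlation first replaces each spot's normalized value
by the mean over {self} ∪ neighbors (≤ 7 terms; boundary spots use what
they have) and then applies the same machinery to a **selected list** of
gene pairs; the Holm family is exactly that list and is recorded in the
output.  Correlation of a constant vector raises an error rather than
returning 0 or NaN — zero-variance inputs are marked untestable, never
silently passed.

## Signature scoring and pathway networks

ssGSEA: per spot, genes are ranked by expression (midrank ties).  Walking
the ranking from the top, the in-set running sum increments by
`|rank|^α / Σ_set |rank|^α` and the out-set sum by `1/(N − n_set)`; the
score is the integrated difference (sum over all positions of in-CDF minus
out-CDF), with α = 0.25.  The score is invariant to monotone transforms of
a spot's profile and to gene order within a set.  An optional min-max
rescaling across spots is off by default; when scoring multiple samples it
should be applied per sample.  Sets with fewer than 2 members in the
matrix (or covering the entire matrix) are skipped with a warning.

Hypoxia and other biological metagene lists are supplied by the user as
GMT; the synthetic generator plants its own signature program, so no
published gene list is bundled.

The pathway network has gene sets as nodes and an edge for every pair with
Jaccard index |A∩B|/|A∪B| above a threshold (default: any overlap).

## Differentiation proxy

Per-spot transcriptional diversity — the number of genes with a nonzero
count, optionally neighbor-smoothed — serves as a differentiation score
(diversity falls as cells differentiate; higher = less differentiated).
This is a deliberate simplification of trajectory-based tooling: it
ignores gene-count normalization models and Markov smoothing, and outputs
are tagged `diversity` so they cannot be mistaken for a full trajectory
method.  Genes tracking the proxy are ranked by Pearson correlation
against it, with top/bottom slices of the sorted table exposing the most
differentiation-associated genes in either direction.

## Ligand–receptor permutation test

For each (pair, cluster): partner expression is the cluster mean of the
normalized value, heteromeric partners take the **minimum over subunits**,
and the pair is tested only when both partners are expressed (value > 0)
in ≥ 40% of the cluster's spots (threshold applied per gene within each
cluster).  The observed statistic is the mean of the two partner means.
Each of 1000 permutations shuffles the full label vector once and
recomputes every statistic from that shuffle, preserving the null's
cross-pair correlation.  p = proportion of null means ≥ the observed mean;
the inclusive comparison makes a fully degenerate null (constant matrix)
give p = 1 rather than 0.  p-values have granularity 1/n_perm; zero means
"below 1/n_perm" and is displayed that way.  The test depends only on the
partition, so relabeling clusters cannot change p.

## mIHC quantification

Phenotypes are data-driven marker gates (required-positive /
required-negative sets, parseable from strings like `CD68+CD163+CD206−`);
gates are not mutually exclusive.  Densities are counts over compartment
area, `area_mm² = area_px² · (µm/px)² / 10⁶`.  Tumor proximity is the
Euclidean pixel distance to the nearest PanCK+ cell (k-d tree; verified
against brute force), scaled to µm, summarized per slide by the median
(robust to the long right tail of nearest-neighbor distances; mean by
flag).  Co-localization is the Spearman correlation of two phenotypes'
per-slide densities, Holm-adjusted across requested pairs, by default on
whole-slide densities with optional compartment or subtype restriction.
Subtype comparisons use Kruskal–Wallis with Dunn's post hoc test.

## Statistical primitives

Kruskal–Wallis uses midranks with tie correction and the χ²(k−1)
approximation.  Dunn's z statistic divides rank-mean differences by
`sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j))`; two-sided normal
p-values are adjusted with Bonferroni by default (Holm and BH available) —
the adjustment method is a recorded configuration field, since published
Dunn tables rarely state it.  Multiple-testing adjustment is delegated to
statsmodels and verified against hand-applied step-up/step-down formulas.

## Synthetic data: what it emulates, and what it does not

The ST generator emulates: the hexagonal lattice; contiguous histologic
regions (horizontal bands, one per subtype, doubling as spatial clusters);
per-spot cell-type mixtures from a Dirichlet favoring each region's
dominant type (concentration 12 vs 0.8, mean dominant share ≈ 0.79);
per-type expression profiles with 10 disjoint markers per type elevated
4-fold; a 15-gene signature program elevated 3-fold in one designated
region; ligand–receptor pairs co-elevated 4-fold in one designated
cluster; log-normal library sizes (median 5000, σ = 0.25) and negative
binomial counts (dispersion 2) for spot-level overdispersion.  Defaults
describe a desk-scale area of 36 × 28 = 1008 spots and 200 genes.  All
randomness flows from a single named generator seed recorded in the truth
object.

The mIHC generator emulates slides as homogeneous Poisson point patterns
per phenotype (defaults: PanCK+ at 400/mm² over the tumor half of a
1 mm² slide; macrophage phenotypes at 60–100/mm² over the whole slide),
with three planted effects: tumor attraction (cells placed at a Gaussian
offset, σ = 40 px, from a random PanCK+ parent), shared per-slide
abundance factors (log-normal, σ = 0.6) planting density co-localization,
and per-subtype density multipliers planting subtype trends.  The
tumor/stroma compartment is a fixed half-slide split.

Not emulated: realistic gene–gene co-expression beyond the planted
structure, segmentation noise or imaging artifacts, irregular tissue
boundaries, per-spot absolute cell counts (the truth is proportions), and
dropout structure beyond NB sampling.  Passing tests therefore demonstrate
that each method recovers the structure it is designed to detect under
its stated model — not that the model captures every property of real
tissue.

## Numerical and scale choices

p-values are clipped to `[5e-324, 1]`; hypergeometric tails are computed
in log space.  Duplicate feature names are disambiguated with `.1`, `.2`
suffixes in file order.  Midranks are used for all ties.  Degenerate
inputs fail loudly (zero-variance correlations raise; singleton clusters
and empty groups are errors naming the offender); recoverable oddities
(markers missing from the universe, slides without tumor cells, sets too
small to score) warn and continue with the affected rows marked.

Test and calibration problem sizes were chosen to keep the full suite
fast on a single CPU while leaving comfortable statistical margins:
300–1000-spot simulations, 20 replicate seeds for stochastic recovery
rates, 1000 permutations/replicates for calibration checks.  Recovery
rates at these sizes are saturated (≈100%), so the margins do not depend
on the exact sizes.

## Known limitations

- The marker-score composition proxy is biased toward types with many or
  highly expressed markers; externally estimated proportion tables are
  preferred when available and are accepted through the same interfaces.
- The diversity differentiation proxy is sensitive to sequencing depth in
  real data (deeper spots detect more genes); in the simulation depth and
  differentiation are independent, which flatters the proxy.
- The LR test shares one permutation stream across pairs; p-values are
  therefore correlated between pairs within a run (deliberately, matching
  the joint null), which matters if they are fed into FDR procedures that
  assume independence.
- Inter-cluster (cross-niche) ligand–receptor testing is out of scope;
  only the intra-cluster mode is implemented.
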