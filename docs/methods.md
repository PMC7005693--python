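# Methods

This note documents the models, conventions and numerical choices behind
`nichescreen`, in the order a run executes them, together with what the
synthetic data do and do not establish about behaviour on real data.

## Data model and scale discipline

Expression lives in a gene × cell matrix with per-cell lineage and batch
annotations and an explicit scale tag (`counts`, `rpkm`, `normalised`,
`log2`). Every operation declares the scales it accepts and raises
`ScaleError` otherwise; this is deliberate friction, since the screen's
threshold is meaningful only in RPKM units and the HVG test only on the
log scale. I/O formats are TSV (gene × cell matrix, annotation table,
gene lengths) and the MatrixMarket triplet.

## Normalisation

**RPKM.** `RPKM_gj = c_gj · 10⁹ / (L_g · T_j)` with `T_j` the cell's total
counted reads in the matrix. Using the in-matrix total makes the
transformation self-contained and exactly invariant to uniformly rescaling
a cell's counts. Note the compositional consequence: Σ_g RPKM·L = 10⁹ per
cell by construction.

**Size factors.** `size_factors()` is the median-of-ratios estimator: the
per-cell median of `c_gj / ref_g` over genes positive in every cell, with
`ref` the gene-wise geometric mean; when no gene is positive everywhere it
falls back, with a logged warning, to a pseudo-reference of per-gene
geometric means over nonzero entries. Identical cells get factors of
exactly 1.

**Normalised matrix.** `normalise_by_size_factors()` does *not* divide raw
counts by those factors. It first scales each cell to a common depth
(counts per million by default) and then divides out the median-of-ratios
factor of the depth-scaled matrix. The reason is a gauge subtlety: with a
geometric-mean reference over n cells, multiplying one cell's raw counts by
c multiplies the *entire* raw-quotient normalised matrix by c^(1/n) — and no
single size-factor definition can be both exactly invariant to per-cell
rescaling and equal to 1 for identical cells (scaling all cells jointly
forces a contradiction). Splitting depth removal from composition
correction resolves it: the two-step normalised matrix is invariant to any
per-cell count rescaling to floating-point precision, which is the property
downstream comparisons rely on, while the reported size factors keep their
conventional meaning. On equal-depth data the two constructions agree up to
a global constant, which the log-scale analyses absorb into the per-gene
mean.

**Medians and boxplots.** Per-lineage medians use the sample median (even
n: mean of the central pair). Boxplot summaries use linear-interpolation
quartiles (the common "type 7"; no convention was mandated), whiskers at
the most extreme data within 1.5 IQR of the box, outliers beyond.

## Ligand–receptor screen

Roles come from a curated catalogue (gene, role, source pathways); evidence
comes from an undirected scored PPI table (3-column or HIPPIE-dialect TSV;
duplicate edges collapse to the maximum confidence; symbols are upper-cased
and a `_HUMAN` suffix stripped). Pairing is the exact cross product of
ligands × receptors filtered by edges at `min_confidence` (default 0 — any
evidence; no cutoff is canonical). Dual-role genes may appear on either
side but never pair with themselves; PPI edges are undirected and the roles
supply direction.

A call is emitted for pair (ℓ, r) and ordered lineages (A, B) iff both
per-lineage medians reach τ = 5 RPKM. The boundary counts as expressed
(`inclusive=False` flips it). The specificity score
`min(fold(ℓ, A), fold(r, B))`, `fold(g,k) = (m_gk + ψ)/(max_{k'≠k} m_gk' + ψ)`
with ψ = 1, quantifies lineage restriction explicitly; it is a ranking
aid, not a test statistic. Ties sort lexicographically by (ligand,
receptor) so output order is reproducible. Statistical significance via
cell-label permutation is deliberately out of scope: the procedure is
threshold-based.

## Highly variable genes

On the log2 normalised matrix, a lowess trend (span 0.3, statsmodels, with
its default robustifying iterations, floored at 1e-8) fitted to per-gene
variance against per-gene mean is taken as the technical variance;
`(n−1)·total_var/tech_var` is referred to the upper tail of χ²(n−1),
Benjamini–Hochberg corrected, and a gene is called at q ≤ α (default 0.01)
when its excess variance is positive. The χ² ratio test is a transparent
variance-decomposition stand-in: it is exact for Gaussian log-expression
with a correctly estimated trend, and conservative for the mildly
platykurtic mixtures dropout produces. Constant genes are never called.
Degenerate inputs (all gene means equal) abort with an error rather than
fitting a meaningless trend.

## Enrichment

**Ranking.** Genes are ranked by `log2((mean_A + ψ)/(mean_B + ψ))` on the
normalised matrix, ψ = 1, ties broken by gene symbol before anything
stochastic happens. This pseudocounted mean-ratio ranking replaces a
negative-binomial differential-expression fit; the divergence affects rank
granularity only and is the package's documented simplification.

**Preranked GSEA.** With `NR = Σ_{g∈S} |s_g|^p` (weight p = 1, the tool
default), the running sum gains `|s_g|^p / NR` at members and loses
`1/(N − |S|)` elsewhere; the enrichment score is the excursion of maximal
magnitude, signed. An exact positive/negative magnitude tie (possible for
single-hit or near-complement sets) resolves to the positive excursion,
with a 1e-9 tolerance so floating-point summation order cannot flip the
sign. The null permutes set membership over gene labels (the preranked
convention; phenotype permutation needs per-sample data). Nominal p is the
same-sign tail fraction with a +1 correction, so p ≥ 1/(nperm+1) and never
0. NES divides ES by the mean same-sign null magnitude; FDR q follows the
pooled-null-NES convention (ratio of null to observed same-sign tail
fractions, clipped to [0, 1]), with Benjamini–Hochberg on nominal p
available via `fdr_method="bh"`. Sets are first intersected with the ranked
list, then size-filtered (5–500 by default); a set covering the whole list
is an error (the miss decrement is undefined).

**ORA.** The exact hypergeometric upper tail `P(X ≥ k)` with population
|universe|, `K = |set ∩ universe|` marked and |query| drawn, BH across sets.
The query must be contained in the universe.

**Similarity graph.** Nodes are sets at nominal p ≤ 0.05; edges join pairs
with overlap coefficient `|A∩B|/min(|A|,|B|)` ≥ 0.5 (Jaccard carried as an
attribute). Metric and cutoff are conventional defaults and configurable;
none are canonical.

## Pathway overlay

Pathways use a small JSON schema — nodes `{id, label, type ∈ {gene_product,
category, non_gene}, members}` (gene nodes exactly one member, categories
at least two) and labelled directed edges — plus a KGML-subset importer
(gene entries take the first graphics alias as symbol; group entries become
categories; relations become edges; compounds and coordinates ignored).
Gene nodes are coloured by `v = log2(median RPKM + 1)` for the chosen cell
type; categories take the maximum over members; genes missing from the
median table count as 0 with a warning. The colour window is [0, 15] in 20
bins of width 0.75, half-open `[k·w, (k+1)·w)` with the top bin closed, and
values above the window clamp to the last bin (the fixed window implies
clamping). Exports carry `value_<celltype>` / `bin_<celltype>` GraphML
attributes — bins, not colours, leaving the palette to the renderer — and a
JSON payload of per-member, per-lineage boxplot statistics (categories get
one boxplot per member, never pooled).

## Culture statistics

Population doublings use the printed constant verbatim:
`PDL = log10(N_t/N_{t−1}) / 0.30103` (not `log10(2)`, to match the stated
formula bit for bit); cumulative PDL is the interval sum, which telescopes
to the endpoint ratio. Embryo proportions are `100·X/total nuclei` for
NANOG⁺ and SOX17⁺, with the inner cell mass defined as their combined
count, so %ICM = %NANOG + %SOX17 exactly — image segmentation is out of
scope and marker sums are the ICM proxy. The group comparison is a
one-tailed two-sample Student t-test with pooled variance (the equal
variance assumption was not specified; Welch is available behind a flag);
the returned t is signed for the tested direction.

## Synthetic blastocyst data

The generator emulates the statistical structure the pipeline assumes:
per-gene baselines on the log2 RPKM scale (`Normal(baseline_log_mean,
gene_log_mean_sd)`, defaults 3.0 and 2.0 → medians roughly 0.5–250 RPKM),
lineage effects additive in log space, cell-to-cell biological noise
(`baseline_log_sd`, default 0.7 log2 units), optional multiplicative batch
effects (default off), optional Bernoulli dropout (default off, see below),
gene lengths uniform on 500–10,000 bp, and integer counts at a default
library size of 500,000 per cell.

Three constructions matter:

* **Compositional calibration.** RPKM satisfies Σ_g RPKM·L = 10⁹ per cell,
  so a gene planted "at 20 RPKM" only reads ~20 after the RPKM stage if the
  background sums correctly. The generator shifts all background baselines
  by a single global factor so the expected dropout-free Σ e·L is 10⁹;
  planted circuit and decoy genes keep their configured absolute levels.
  Calibration targets the dropout-free field, so raising the dropout rate
  only removes signal.
* **Quantile-coupled counts.** Counts are `Poisson⁻¹(u; λ)` with a uniform
  field `u` drawn once per dataset and `λ = e·L·(library/10⁹)`. Because the
  inverse CDF is monotone in λ and the dropout mask is nested in a shared
  uniform field, increasing `dropout_rate` under the same seed provably
  never increases any gene's mean count — a guarantee plain resampling
  cannot give.
* **Planted truth.** Default conditions: 2000 genes, 50 cells per lineage,
  six circuits (the PE→EPI IGF1/IGF1R motif plus five covering the other
  directions, one autocrine; on-lineage medians 8–30 RPKM, off-lineage
  0.3–0.6), 20 decoy pairs expressed at 0.5 RPKM everywhere (so only the
  threshold, not the pairing, can exclude them), 100 genes with 5×
  biological variance, and two 50-gene sets shifted +2 log2FC in one
  lineage. Effect sizes are free parameters chosen to sit comfortably but
  not trivially across the 5 RPKM threshold; they are not estimates of the
  real embryo data.

**Dropout default.** Dropout is off by default for the same reason batch
effects are: the upstream corrections that would remove them (imputation,
batch regression) are outside this package's scope, so the generator's
default conditions emulate the corrected matrix that enters these stages.
With a constant-rate zero spike the log-scale variance is dominated by
`p(1−p)·mean²`, which both hides planted overdispersion from the χ² ratio
test and decouples variance from the mean trend; runs with nonzero dropout
are supported and exercised by the monotonicity tests, but HVG calling on
heavily dropped-out, unimputed data should not be expected to be calibrated
— on real droplet-style data, impute or use a count-model method first.

**What passing tests do and do not show.** The synthetic data are
log-normal with Poisson counting noise, independent genes, equal-size
lineages and exactly labelled cells. Recovery results (screen precision and
recall of 1, HVG TPR ≥ 0.9 at realised FDR ≤ 0.05) certify the
implementation against its own model, not performance under mislabelled
lineages, correlated gene modules, UMI duplication, ambient RNA or doublets,
none of which are simulated.

## Pipeline and reproducibility

The `run` command chains simulate → catalogue → normalise → HVG → screen →
GSEA → enrichment graph → ORA → overlay, writing stable, schema-versioned
filenames plus a JSON run report (per-stage record counts, parameter echo,
seed, version; no timestamps). One seed is fanned out to the stochastic
stages through fixed offsets (simulation +0, GSEA permutations +1,
background gene sets +2, modulo 2³¹), so each stage is individually
reproducible and two runs with the same configuration are byte-identical.
Stage failures abort with the stage name; the partially written report
records the failed stage.

Default problem sizes (2000 × 150 simulation, 1000 GSEA permutations, 200
calibration trials in the acceptance script) were chosen so the full test
suite and the acceptance script each complete in well under a minute on a
single CPU while keeping the planted-recovery and calibration checks
statistically meaningful.

## Known limitations

* The screen is threshold-based by design; it attaches no p-value to a
  call, and the specificity score is a ranking heuristic.
* The mean-ratio log2FC ranking compresses ranks for low-expression genes
  relative to a model-based differential-expression fit.
* The χ² HVG test assumes the lowess trend consumes all technical variance;
  strong gene-gene correlation or unmodelled zero inflation will
  miscalibrate it.
* The KGML importer handles the gene/group/relation subset only.
* Single-cell permutation nulls, imputation, batch correction,
  dimensionality reduction and clustering are intentionally not provided.
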