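# Methods

This note documents the statistical model behind `capnorm`, the defaults
that matter, what the bundled simulator does and does not emulate, and the
numerical conventions adopted where the design was genuinely open.

## Data model

A dataset is a genes × samples matrix of non-negative integer read counts
with aligned metadata: per sample a batch, an assay level (`input` or
`enrichment`), a biological group, and a pair identifier linking each
enrichment library to its input library; per gene an origin class
(`endogenous`, `spikein`, `synthetic_nad`, `synthetic_m7g`) and a biotype.
Counts must be integers on load; every downstream normalized value is
real-valued on the log2(x+1) scale and is never coerced back to an integer.
Genes-as-rows is the declared orientation for all files and public
matrices; internal linear algebra transposes freely.

## Quality control

- **Sample outliers.** PCA is run on log2 counts-per-million of the
  top-variance genes (default up to 20 000; ties broken by gene order) and
  a generalized extreme studentized deviate (Rosner) test is applied to the
  PC1 scores (default α = 0.05, `max_outliers = ceil(0.1 · n)`). log-CPM is
  a deliberate, documented stand-in for a full variance-stabilizing
  transform: QC PCA only needs approximate variance flattening. Flagged
  samples are reported, not dropped, unless `--drop-outliers` is given.
- **Gene filtering.** A gene is kept when its CPM clears the CPM equivalent
  of `min_count = 20` at the median library size in at least `n_min`
  samples, `n_min` being the smallest group × assay design cell (damped to
  `10 + 0.7 · (n_min − 10)` above 10, mirroring the published large-n
  rule); ribosomal-RNA and TEC biotypes are then removed. The heuristic is
  re-implemented from its published description; the kept-gene set, not
  byte-identity with any external package, is the contract.
- **Saturation.** Counts are binomially thinned at each requested fraction
  and the mean number of endogenous genes with more than 10 reads is
  reported; at fraction 1.0 the data are untouched, so the value is exact.

## The NB-GLM engine

All significance ranking and enrichment calling uses one engine: per-gene
negative-binomial GLMs with log link, per-sample natural-log offsets and a
per-gene dispersion φ (Var = μ + φμ²), fitted by IRLS vectorised across
genes (the design matrix is shared, so each step is a batched p × p solve;
convergence at relative log-likelihood change < 1e-8 or 100 iterations,
linear predictors clipped at ±30). Dispersions are method-of-moments
estimates shrunk toward a hyperbolic mean–dispersion trend with prior
weight 10 against the residual degrees of freedom — an explicit,
self-contained scheme chosen because only gene *rankings* feed gene-set
selection, which is robust to moderate dispersion differences. Nested
models are compared by a chi-square likelihood-ratio test (df = rank
difference); all-zero genes get LR 0 and p 1 by convention; fold changes
are the coefficient of the dropped covariate in base 2, estimated with a
0.125 prior count to stabilise near-zero genes; FDR is Benjamini–Hochberg.
Measured on the bundled null simulation the type-I error at nominal 0.05
is within [0.03, 0.08] (see `scripts/acceptance.py`).

## Control-gene sets

- **Anchor** (default 1000): spike-in genes ranked *ascending* by the LR
  statistic of assay vs intercept. Batch is deliberately excluded from this
  model so batch variation survives in the anchor genes — that is what the
  RUV step consumes. With both gene-set LRTs, total-count log offsets
  absorb sequencing depth.
- **Negative evaluation** (default 500): endogenous genes least affected by
  *any* wanted covariate (assay + biological group vs intercept).
- **Positive evaluation** (default 500): endogenous genes ranked descending
  by the assay LR statistic. Overlaps with the negative set are removed
  from the negative side with a recorded warning.

Rankings are deterministic; ties break by gene order.

## Normalization space

Size factors are rescaled to geometric mean 1 so procedures are comparable;
offsets are their log2. Conventions per scaler: UQ uses the 75th percentile
(linear interpolation) over nonzero genes; DESeq discards genes with any
zero count; TMM trims M-values at 30% and A-values at 5% with delta-method
precision weights, the reference being the sample whose upper quartile is
closest to the mean; PoissonSeq discards genes with fewer than 5 total
reads and iterates depth estimates over the central half of the
goodness-of-fit distribution until change < 1e-6 (max 20 iterations).

RUV is estimated on the offset-adjusted log2 matrix. `W` holds the leading
right-singular vectors (orthonormal, per sample) of the centred
control-gene submatrix; `α` comes from unpenalised least squares of all
genes on `W`. Replicate groups: RUVs pools assay levels within each
biological group (the enrichment contrast therefore *enters* its
difference space), while RUVse crosses group with assay so a constant
enrichment effect is invisible to it — the variant's defining property,
verified in the test suite as a lower canonical correlation between `W`
and the assay indicator. `k` may not exceed the admissible rank of the
centred submatrix. The canonical enumeration (6 scalers × (none + 3
variants × k ≤ 5)) has 96 members; the unnormalized baseline is always
included.

## Evaluation metrics and score

Expression PCs are sample scores from an SVD of the gene-centred matrix
(default 3 PCs). Silhouette widths use Euclidean distance on those PCs,
with singleton clusters assigned 0 — the widely used convention. PAM_SIM
maximises the average silhouette over in-house PAM (BUILD + SWAP,
deterministic) clusterings with k = 2..min(10, n−1). UV/WV evaluation
factors are the first 3 right-singular vectors of the row-centred,
row-scaled evaluation-gene submatrix of the **unnormalized** log counts;
the weighted R̄² pools sums of squares across PCs (Σ SSR / Σ SST, intercept
included). RLE metrics: mean squared per-sample median RLE and the
population variance (ddof = 0) of per-sample RLE IQRs. Metric orientation
is +1 for BIO_SIM, EN_SIM, PAM_SIM, WV_COR and −1 for BATCH_SIM, UV_COR,
RLE_MED, RLE_IQR; oriented metrics are ranked ascending with ties
averaged, so the performance score (mean rank) is largest for the best
procedure. A metric undefined for any procedure (for instance BATCH_SIM
with a single batch) is dropped for all, with a warning.

Because the evaluation factors come from unnormalized counts, strong raw
batch structure contaminates the WV factors and bounds WV_COR away from 1
for *every* procedure, including an oracle that subtracts the exact
planted effects (measured ceiling ≈ 0.75 at the default simulation). WV_COR
should therefore be read comparatively across procedures, not as an
absolute preservation fraction.

## Enrichment calling

`find_enrichment` defaults to the *covariate-adjusted* formulation: the NB
LRT runs on the raw counts with the procedure's size-factor offsets and its
estimated `W` carried as covariates in both designs, so the adjustment is
used exactly once. The alternative `normalized-refit` mode back-transforms
`Y*` to pseudo-counts and refits without `W`. A gene is an NAD-RNA when its
fold change is ≥ 2 (boundary inclusive, equivalently log2 FC ≥ 1) at FDR
< 0.05. Synthetic spike-ins run through the same machinery and are
reported as sensitivity (NAD-capped, should be called) and specificity
(m7G-capped, should not) controls. Modification levels are the per-pair
log2 differences (enrichment − input) of adjusted values.

## Diagnostics and baselines

Batch summaries: cumulative-PC regression R² (covariate indicators
regressed on PCs 1..k, pooled sums of squares, non-decreasing in k),
per-gene one-way ANOVA counts at p < 0.01, per-gene Spearman correlation
with a numeric batch encoding (constant genes reported as 0 with a flag).
Preservation summaries: Rozeboom's squared vector correlation
1 − Π(1 − ρᵢ²) over canonical correlations, and the adjusted Rand index of
a PAM clustering of the first 3 PCs against assay labels. Jensen-Shannon
distances (log base 2, hence in [0, 1]) are computed per sample against
the mean distribution; profiles are renormalised internally, and
epitranscriptomic profiles built from modification levels are shifted
non-negative by min-subtraction first — a documented convention, since no
canonical mapping from log-ratios to distributions exists. The baselines
are standalone RUVg (anchor controls, k = 4, no scaling) and a RADAR-style
scaler (median-of-ratios on inputs; enrichment factors from the mean — or,
configurably, median — per-gene fold change over the top 1% of genes by
enrichment counts).

## Synthetic-data generator

The generator emulates a paired, batched spike-in design: endogenous genes
carry biology + batch + enrichment effects; exogenous spike-ins carry
batch + enrichment (a configurable 20% enriched by default) but no biology;
one synthetic spike-in is enriched (emulating a 5% NAD-capped pool) and
one is not (100% m7G-capped). Defaults, chosen once as desk-scale study
conditions: 2000 endogenous + 1000 spike-in genes, 2 groups × 6
input/enrichment pairs (24 libraries) over 3 batches, rank-2 batch factor
structure with per-gene log2 SD 1.0, enrichment log2 FC 2 on 5% of
endogenous genes, group effects N(0, 1) on 30% of endogenous genes, NB
dispersion 0.1, library sizes U(0.8M, 1.2M). Batch enters as low-rank
structure (factors × loadings) so the RUV factor model is the correct
generative family and recovery is a fair test; a full-rank per-gene
`shift` mode exercises robustness under misspecification. Counts are
Poisson-gamma draws, fully reproducible from the seed.

What the generator does **not** emulate: GC/length biases, zero inflation,
library-preparation composition effects beyond depth, correlated genes
within pathways, and read-level artefacts. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance guarantees on any particular real cohort.

## Problem sizes and limitations

The default test and acceptance runs use the 3002-gene × 24-library
configuration above; the full 96-procedure evaluation completes in a few
seconds. Known limitations: dispersion shrinkage is moment-based, not
empirical-Bayes, and can be slightly liberal (measured type-I ≈ 0.07 at
nominal 0.05); PAM is exact but O(n²k) per SWAP pass, sized for dozens to
a few hundred samples, not thousands; RUVse requires every group × assay
cell to hold at least two samples; and procedure selection by rank
aggregation does not adjudicate between near-tied procedures — inspect the
metric table when scores are close. In particular, an assay-pooled RUVs
procedure that absorbs the enrichment direction into `W` can sharpen
biological clustering enough (higher BIO_SIM/PAM_SIM) to edge out an
RUVse procedure by a few rank points on some realisations, at the cost of
EN_SIM and WV_COR; when the top scores are within a couple of points,
prefer the enrichment-protecting variant or check EN_SIM explicitly
before calling enrichment.
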