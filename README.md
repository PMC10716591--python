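# capnorm

Spike-in-aware normalization selection and enrichment calling for paired
input/enrichment epitranscriptomic RNA-seq (NAD-RNA-seq and similar
capture-based designs).

## The problem

Affinity-capture sequencing of modified RNAs (for example NAD-capped
transcripts) produces paired libraries per specimen: an **input** library of
total RNA and an **enrichment** library after capture. The quantity of
interest is the per-gene enrichment/input contrast, but multi-batch studies
carry technical variation that can dwarf it, and ordinary global scaling
cannot remove it without distorting the capture signal itself. `capnorm`
operationalises a spike-in-anchored strategy: exogenous spike-in RNAs added
in equal amounts to every sample carry the technical variation but no
biology of interest, so their least-enriched subset can anchor a
remove-unwanted-variation (RUV) factor model while data-driven metrics pick
the best normalization from a large candidate space.

## The model

Let `Y` be the log2-scale genes × samples expression matrix. Each candidate
normalization is a point in a two-part space:

1. **Global scaling** — per-sample size factors from one of: none, total
   count (TC), upper quartile (UQ), trimmed mean of M-values (TMM),
   median-of-ratios (DESeq) or PoissonSeq's iterative depth estimate —
   giving log2 offsets `O`.
2. **Factor regression** — `k` unwanted-variation factors `W` (samples × k)
   estimated by SVD of a centred control-gene submatrix, with nuisance
   coefficients `α` from least squares, under one of three centrings:
   - **RUVg**: controls row-centred globally;
   - **RUVs**: controls centred within biological replicate groups;
   - **RUVse**: controls centred within replicate groups formed *inside each
     assay level*, so the enrichment contrast can never leak into `W`.

The adjusted matrix is `Y* = Y − O − Wα̂`. Enumerating 6 scalers × (no RUV +
3 variants × k = 1..5) yields 96 procedures. Each is scored by eight
metrics — average silhouette widths by biology/batch/assay/PAM clustering,
weighted R̄² against wanted/unwanted evaluation factors, and the mean squared
median / IQR variance of relative log expression — oriented, ranked, and
rank-averaged into a single performance score. Enrichment is then called on
the selected normalization by a negative-binomial likelihood-ratio test:
genes with fold change ≥ 2 at Benjamini–Hochberg FDR < 0.05 are reported as
NAD-RNAs, with two synthetic spike-ins (one 5% NAD-capped, one 100%
m7G-capped) acting as built-in sensitivity and specificity controls.

## Worked example

```python
from capnorm import (SimParams, simulate_dataset, select_gene_sets,
                     enumerate_procedures, apply_procedure, metric_vector,
                     score_procedures, find_enrichment, log_transform)

ds, truth = simulate_dataset(SimParams(seed=1))     # 3002 genes x 24 libraries
gene_sets = select_gene_sets(ds)                    # anchor / negative / positive
raw_log = log_transform(ds.counts)

table = [(p, metric_vector(apply_procedure(ds, p, gene_sets),
                           ds.samples, raw_log, gene_sets))
         for p in enumerate_procedures()]           # all 96 procedures
scores = score_procedures(table)
print(scores.head(3).round(3))
```

```
                     BIO_SIM  BATCH_SIM  EN_SIM  PAM_SIM  UV_COR  WV_COR  RLE_MED  RLE_IQR  performance_score
procedure
DESeq+RUVse_k3         0.375     -0.124   0.534    0.746   0.035   0.588    0.000    0.001             72.125
TMM+RUVse_k3           0.375     -0.123   0.534    0.746   0.035   0.587    0.001    0.001             69.250
PoissonSeq+RUVse_k3    0.373     -0.125   0.536    0.746   0.033   0.594    0.008    0.001             67.625
```

The top procedures combine a scaler with the enrichment-protecting RUVse
variant: batch clustering is abolished (BATCH_SIM ≈ −0.12, UV_COR ≈ 0.03)
while assay separation survives (EN_SIM ≈ 0.53). Calling enrichment on the
winner:

```python
best = next(p for p, _ in table if p.name == scores.index[0])
top = apply_procedure(ds, best, gene_sets)
calls = find_enrichment(ds, top)
print(int(calls["is_nad_rna"].sum()))                   # 101
print(calls.loc[["SYN_NAD", "SYN_M7G"], ["log2_fc", "fdr", "is_nad_rna"]])
```

```
         log2_fc    fdr  is_nad_rna
SYN_NAD    1.781  0.000        True
SYN_M7G   -0.015  0.949       False
```

101 genes are called against 100 planted NAD genes; the NAD-capped synthetic
spike-in is recovered and the m7G-capped one is correctly rejected.

## Command line

The same stages are available as subcommands —
`capnorm simulate | qc | genesets | normalize | evaluate | enrich | diagnose`
— each reading `--counts/--samples/--genes` tables (TSV/CSV/MatrixMarket)
and writing TSV outputs plus a `run_params.yaml` log of parameters and
seeds. See `capnorm <subcommand> --help`.

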