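"""Normalization-performance metrics and rank-aggregated scoring.

Eight metrics summarise each candidate normalization:

=========  =================================================================
BIO_SIM    average silhouette width of samples grouped by the biological
           covariate of interest (on the first 3 expression PCs)  [+]
BATCH_SIM  average silhouette width grouped by batch               [−]
EN_SIM     average silhouette width grouped by assay               [+]
PAM_SIM    maximum average silhouette over PAM clusterings, k=2..10 [+]
UV_COR     weighted R̄² of expression PCs on unwanted-variation factors
           (SVD of the negative-evaluation genes in the raw log counts) [−]
WV_COR     same, on wanted-variation factors from positive-evaluation
           genes                                                    [+]
RLE_MED    mean squared per-sample median relative log expression   [−]
RLE_IQR    variance of the per-sample RLE interquartile range       [−]
=========  =================================================================

Each metric is oriented by the sign in brackets, procedures are ranked per
metric (ties averaged, best = highest rank) and the performance score is the
mean rank; the best procedure has the largest score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import rankdata

from .core import CapnormError, ParameterError
from .normalization import NormalizedMatrix, Procedure

METRICS = ("BIO_SIM", "BATCH_SIM", "EN_SIM", "PAM_SIM",
           "UV_COR", "WV_COR", "RLE_MED", "RLE_IQR")
# +1: larger is better; −1: smaller is better
ORIENTATION = {"BIO_SIM": 1, "BATCH_SIM": -1, "EN_SIM": 1, "PAM_SIM": 1,
               "UV_COR": -1, "WV_COR": 1, "RLE_MED": -1, "RLE_IQR": -1}


class MetricUndefinedError(CapnormError):
    pass


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def expression_pcs(values, n_pcs: int = 3) -> np.ndarray:
    """Sample scores on the first ``n_pcs`` principal components.

    ``values`` is genes × samples; each gene is centred across samples and
    the samples-as-observations scores (U·S of the SVD) are returned.
    """
    X = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples × genes
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    return U[:, :n_pcs] * s[:n_pcs]


def silhouette_widths(embedding, labels) -> np.ndarray:
    """Per-sample silhouette widths sil(i) = (b−a)/max(a,b).

    a(i): mean distance to other members of i's cluster; b(i): smallest mean
    distance to any other cluster.  Samples in singleton clusters get 0.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise MetricUndefinedError("silhouette needs at least two clusters")
    D = cdist(X, X)
    out = np.zeros(len(labels))
    for i in range(len(labels)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            out[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == lev].mean() for lev in levels if lev != labels[i])
        out[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


def pam_cluster(X: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic partitioning around medoids (BUILD + SWAP)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ParameterError("k must lie in [2, n_samples]")
    D = squareform(pdist(X))
    # BUILD: greedily add the medoid that most reduces total cost
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, None
        current = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    medoids = sorted(medoids)
    # SWAP until no improvement
    for _ in range(max_iter):
        cost = D[:, medoids].min(axis=1).sum()
        best = (cost, None)
        for mi, m in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                trial = medoids[:mi] + [j] + medoids[mi + 1:]
                c = D[:, trial].min(axis=1).sum()
                if c < best[0] - 1e-12:
                    best = (c, (mi, j))
        if best[1] is None:
            break
        mi, j = best[1]
        medoids[mi] = j
        medoids = sorted(medoids)
    return np.argmin(D[:, medoids], axis=1)


# ---------------------------------------------------------------------------
# metric operations
# ---------------------------------------------------------------------------

def similarity_metrics(normalized, samples: pd.DataFrame, n_pcs: int = 3,
                       bio_covariate: str = "group",
                       pam_k_max: int = 10) -> dict:
    """BIO_SIM / BATCH_SIM / EN_SIM / PAM_SIM on the first ``n_pcs`` PCs.

    Groupings with fewer than two levels yield ``None`` (metric absent).
    """
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    pcs = expression_pcs(values, n_pcs)

    def avg_sil(labels) -> float | None:
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            return None
        return float(silhouette_widths(pcs, labels).mean())

    out = {
        "BIO_SIM": avg_sil(samples[bio_covariate]),
        "BATCH_SIM": avg_sil(samples["batch"]),
        "EN_SIM": avg_sil(samples["assay"]),
    }
    best = -np.inf
    for k in range(2, min(pam_k_max, pcs.shape[0] - 1) + 1):
        lab = pam_cluster(pcs, k)
        if len(np.unique(lab)) < 2:
            continue
        best = max(best, silhouette_widths(pcs, lab).mean())
    out["PAM_SIM"] = float(best) if np.isfinite(best) else None
    return out


def weighted_r2(expr_pcs, eval_factors) -> float:
    """Weighted average coefficient of determination R̄² = ΣSSR_k / ΣSST_k.

    Each expression PC is regressed (with intercept) on all evaluation
    factors; sums of squares pool across PCs.  Zero-variance PCs are
    excluded with a warning.
    """
    P = np.asarray(expr_pcs, dtype=float)
    F = np.asarray(eval_factors, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if F.ndim == 1:
        F = F[:, None]
    X = np.column_stack([np.ones(F.shape[0]), F])
    sst_total = sse_total = 0.0
    for col in P.T:
        sst = ((col - col.mean()) ** 2).sum()
        if sst <= 1e-14:
            warnings.warn("zero-variance expression PC excluded from weighted R²")
            continue
        coef, *_ = np.linalg.lstsq(X, col, rcond=None)
        sse = ((col - X @ coef) ** 2).sum()
        sst_total += sst
        sse_total += sse
    if sst_total == 0.0:
        raise MetricUndefinedError("all expression PCs have zero variance")
    return float(np.clip(1.0 - sse_total / sst_total, 0.0, 1.0))


def evaluation_factors(raw_log: pd.DataFrame, eval_genes, n_factors: int = 3) -> np.ndarray:
    """Right-singular vectors of the row-centred, row-scaled evaluation-gene
    submatrix of the *unnormalized* log counts (samples × n_factors)."""
    eval_genes = list(eval_genes)
    Z = raw_log.loc[eval_genes].to_numpy(dtype=float)
    Z = Z - Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, ddof=1)
    ok = sd > 1e-12
    Z = Z[ok] / sd[ok][:, None]
    if Z.shape[0] == 0:
        raise MetricUndefinedError("all evaluation genes constant")
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    avail = int((s > 1e-10).sum())
    if n_factors > avail:
        warnings.warn(f"only {avail} evaluation factors available; reducing from {n_factors}")
        n_factors = avail
    return Vt[:n_factors].T


def uv_wv_cor(normalized, raw_log: pd.DataFrame, gene_sets, n_pcs: int = 3,
              n_factors: int = 3) -> tuple[float | None, float | None]:
    """(UV_COR, WV_COR): weighted R̄² of expression PCs on evaluation factors
    from the negative / positive evaluation genes respectively."""
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    pcs = expression_pcs(values, n_pcs)
    out = []
    for genes in (gene_sets.negative_eval, gene_sets.positive_eval):
        if not genes:
            out.append(None)
            continue
        F = evaluation_factors(raw_log, genes, n_factors)
        out.append(weighted_r2(pcs, F))
    return tuple(out)


def rle_metrics(normalized) -> tuple[float, float]:
    """(RLE_MED, RLE_IQR) from log-scale relative log expression.

    RLE_ij = value_ij − median_over_samples(value_i·); RLE_MED is the mean of
    squared per-sample median RLE; RLE_IQR the (population) variance of
    per-sample RLE IQRs.
    """
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    X = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if X.shape[1] < 2:
        raise ParameterError("RLE needs at least 2 samples")
    rle = X - np.median(X, axis=1, keepdims=True)
    med = np.median(rle, axis=0)
    q75, q25 = np.percentile(rle, [75, 25], axis=0)
    iqr = q75 - q25
    return float((med ** 2).mean()), float(np.var(iqr))


def metric_vector(normalized, samples: pd.DataFrame, raw_log: pd.DataFrame,
                  gene_sets, n_pcs: int = 3, n_factors: int = 3,
                  bio_covariate: str = "group") -> dict:
    """All eight metrics for one normalized matrix (absent metrics = None)."""
    out = similarity_metrics(normalized, samples, n_pcs=n_pcs,
                             bio_covariate=bio_covariate)
    uv, wv = uv_wv_cor(normalized, raw_log, gene_sets, n_pcs=n_pcs,
                       n_factors=n_factors)
    out["UV_COR"], out["WV_COR"] = uv, wv
    out["RLE_MED"], out["RLE_IQR"] = rle_metrics(normalized)
    return out


def score_procedures(metric_table) -> pd.DataFrame:
    """Rank-aggregate a list of ``(Procedure, metric dict)`` pairs.

    Metrics are multiplied by their orientation sign, ranked ascending with
    ties averaged (so the best procedure gets the highest rank) and averaged
    into ``performance_score``.  Metrics missing for any procedure are
    dropped for all with a warning.  Output is sorted best-first.
    """
    if len(metric_table) < 2:
        raise ParameterError("scoring needs at least 2 procedures")
    names = [p.name if isinstance(p, Procedure) else str(p) for p, _ in metric_table]
    df = pd.DataFrame([m for _, m in metric_table], index=names)
    df = df.reindex(columns=[m for m in METRICS if m in df.columns])
    incomplete = [c for c in df.columns if df[c].isna().any()]
    if incomplete:
        warnings.warn(f"metrics dropped (missing for some procedure): {incomplete}")
        df = df.drop(columns=incomplete)
    if df.shape[1] == 0:
        raise MetricUndefinedError("no metric defined for all procedures")
    ranks = pd.DataFrame(
        {c: rankdata(ORIENTATION[c] * df[c].to_numpy()) for c in df.columns},
        index=df.index,
    )
    out = df.copy()
    out["performance_score"] = ranks.mean(axis=1)
    out.index.name = "procedure"
    return out.sort_values("performance_score", ascending=False)
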