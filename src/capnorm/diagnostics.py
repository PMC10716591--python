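"""Benchmarking diagnostics for comparing normalizations.

Covers the batch-effect summaries (cumulative-PC regression R², per-gene
batch ANOVA counts, per-gene Spearman correlation with batch), preservation
summaries (Rozeboom squared vector correlation with the assay covariate,
adjusted Rand index of assay separation), per-sample Jensen-Shannon
distances to the cohort centroid, and the two baseline normalizers used for
comparison: standalone RUVg and a RADAR-style scaling scheme (median-of-
ratios on inputs, top-gene fold-change factors on enrichment libraries).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .core import (CapnormError, ConfigurationError, Dataset, ParameterError,
                   ValidationError, log_transform)
from .evaluation import expression_pcs, pam_cluster
from .normalization import (NormalizedMatrix, Procedure, apply_procedure,
                            compute_scale_factors)


def _indicator_matrix(covariate) -> np.ndarray:
    cov = pd.Series(covariate)
    if cov.nunique() < 2:
        raise ParameterError("covariate is constant; R² undefined")
    if pd.api.types.is_numeric_dtype(cov):
        return cov.to_numpy(dtype=float)[:, None]
    cat = pd.Categorical(cov)
    return np.column_stack([(cat == lev).astype(float) for lev in cat.categories[:-1]])


def _pooled_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """R² of the multivariate regression of Y's columns on [1, X], pooling
    sums of squares across columns."""
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    sst = sse = 0.0
    for col in Y.T:
        s = ((col - col.mean()) ** 2).sum()
        if s <= 1e-14:
            continue
        coef, *_ = np.linalg.lstsq(Xd, col, rcond=None)
        sse += ((col - Xd @ coef) ** 2).sum()
        sst += s
    if sst == 0.0:
        raise ParameterError("covariate indicators have no variance")
    return float(np.clip(1.0 - sse / sst, 0.0, 1.0))


def pc_covariate_r2(matrix, covariate, k_max: int = 6) -> pd.DataFrame:
    """R² of covariate indicators regressed on the first k PCs, k = 1..k_max.

    ``matrix`` is genes × samples (log scale).  Cumulative in k, hence
    non-decreasing.  Returns a DataFrame with columns ``k`` and ``r2``.
    """
    vals = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    X = vals.to_numpy(dtype=float) if isinstance(vals, pd.DataFrame) else np.asarray(vals, float)
    if k_max > X.shape[1] - 1:
        raise ParameterError("k_max must be at most samples − 1")
    pcs = expression_pcs(X, k_max)
    ind = _indicator_matrix(covariate)
    rows = [(k, _pooled_r2(ind, pcs[:, :k])) for k in range(1, pcs.shape[1] + 1)]
    return pd.DataFrame(rows, columns=["k", "r2"])


def anova_batch_count(matrix, batch, p_threshold: float = 0.01,
                      return_pvalues: bool = False):
    """Number of genes whose expression differs across batches (one-way
    ANOVA, p < ``p_threshold``).  Constant genes are excluded."""
    vals = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    X = vals.to_numpy(dtype=float) if isinstance(vals, pd.DataFrame) else np.asarray(vals, float)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    if len(levels) < 2 or any((batch == lev).sum() < 2 for lev in levels):
        raise ParameterError("ANOVA needs >= 2 batches with >= 2 samples each")
    groups = [X[:, batch == lev] for lev in levels]
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.f_oneway(*groups, axis=1)
    count = int((p[np.isfinite(p)] < p_threshold).sum())
    return (count, p) if return_pvalues else count


def gene_batch_spearman(matrix, batch) -> pd.DataFrame:
    """Per-gene Spearman correlation with a numerically-encoded batch.

    Constant genes get rho 0 with ``constant=True``.
    """
    vals = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if isinstance(vals, pd.DataFrame):
        index, X = vals.index, vals.to_numpy(dtype=float)
    else:
        X = np.asarray(vals, float)
        index = pd.RangeIndex(X.shape[0])
    b = pd.Series(batch)
    if not pd.api.types.is_numeric_dtype(b):
        b = pd.Series(pd.Categorical(b).codes)
    rb = stats.rankdata(b.to_numpy())
    rb = rb - rb.mean()
    R = stats.rankdata(X, axis=1).astype(float)
    R -= R.mean(axis=1, keepdims=True)
    denom = np.sqrt((R ** 2).sum(axis=1) * (rb ** 2).sum())
    constant = denom <= 1e-12
    rho = np.zeros(X.shape[0])
    np.divide(R @ rb, denom, out=rho, where=~constant)
    return pd.DataFrame({"rho": rho, "constant": constant}, index=index)


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-10 * max(s.max(), 1.0)).sum())
    if rank == 0:
        raise ParameterError("input has rank 0 after centring")
    return U[:, :rank]


def canonical_correlations(X, Y) -> np.ndarray:
    """Canonical correlations between the column spaces of centred X and Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    Qx, Qy = _orthonormal_basis(X), _orthonormal_basis(Y)
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def vector_correlation(expr_pcs, covariate_matrix) -> float:
    """Rozeboom's squared vector correlation 1 − Π(1 − ρ_i²) over the
    canonical correlations ρ_i."""
    rho = canonical_correlations(expr_pcs, covariate_matrix)
    return float(1.0 - np.prod(1.0 - rho ** 2))


def ari_separation(normalized, assay_labels, n_pcs: int = 3) -> float:
    """Adjusted Rand index between a PAM clustering of the first ``n_pcs``
    expression PCs (k = number of assay levels) and the assay labels."""
    vals = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    labels = np.asarray(assay_labels)
    k = len(np.unique(labels))
    if k < 2:
        raise ParameterError("assay labels must have both levels")
    pcs = expression_pcs(vals, n_pcs)
    clusters = pam_cluster(pcs, k)
    return float(adjusted_rand_score(labels, clusters))


def jensen_shannon_distance(profiles) -> np.ndarray:
    """Per-sample Jensen-Shannon distance (log base 2) to the centroid.

    ``profiles`` is samples × features, non-negative; each row is normalized
    to a probability distribution, the centroid is the mean distribution and
    the distance is sqrt(JSD(centroid, sample)) ∈ [0, 1].
    """
    P = profiles.to_numpy(dtype=float) if isinstance(profiles, pd.DataFrame) else np.asarray(profiles, float)
    if (P < 0).any():
        raise ValidationError("profiles must be non-negative")
    sums = P.sum(axis=1)
    if (sums <= 0).any():
        raise ValidationError("every profile must have positive total")
    P = P / sums[:, None]
    pc = P.mean(axis=0)

    def H(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    jsd = np.array([H(0.5 * (pc + pi)) - 0.5 * (H(pc) + H(pi)) for pi in P])
    return np.sqrt(np.clip(jsd, 0.0, 1.0))


def modification_profiles(mod_levels: pd.DataFrame) -> pd.DataFrame:
    """Map per-pair modification levels (genes × pairs, log2 ratios) to
    non-negative per-pair profiles for :func:`jensen_shannon_distance`.

    Each pair's profile is shifted by its own minimum (log-ratios have no
    canonical probability reading; min-subtraction is the documented
    convention here).  Returns pairs × genes.
    """
    X = mod_levels.to_numpy(dtype=float)
    shifted = X - X.min(axis=0, keepdims=True)
    return pd.DataFrame(shifted.T, index=mod_levels.columns,
                        columns=mod_levels.index)


# ---------------------------------------------------------------------------
# baseline normalizers
# ---------------------------------------------------------------------------

def radar_baseline(dataset: Dataset, top_fraction: float = 0.01,
                   summary: str = "mean") -> NormalizedMatrix:
    """Scaling-only baseline for paired enrichment designs.

    Input libraries are scaled by DESeq median-of-ratios.  Each enrichment
    library is scaled by the ``summary`` (mean or median) of per-gene fold
    changes F = enrichment / normalized-input over the ``top_fraction``
    genes ranked by enrichment counts (zero-input genes excluded with a
    warning).
    """
    samples = dataset.samples
    inputs = samples.index[samples["assay"] == "input"]
    if len(inputs) == 0:
        raise ConfigurationError("no input samples")
    in_scaling = compute_scale_factors(dataset.counts[list(inputs)], "DESeq")
    sf = pd.Series(np.ones(len(samples)), index=samples.index)
    sf.loc[inputs] = in_scaling.size_factors
    summarise = {"mean": np.mean, "median": np.median}[summary]

    n_top = max(1, int(np.ceil(top_fraction * dataset.n_genes)))
    fold_factors = {}
    for pid, sub in samples.groupby("pair_id"):
        en = sub.index[sub["assay"] == "enrichment"]
        inp = sub.index[sub["assay"] == "input"]
        if len(en) != 1 or len(inp) != 1:
            raise ValidationError(f"pair {pid!r} is incomplete")
        en_counts = dataset.counts[en[0]].to_numpy(dtype=float)
        in_norm = dataset.counts[inp[0]].to_numpy(dtype=float) / sf[inp[0]]
        top = np.argsort(-en_counts, kind="stable")[:n_top]
        ok = in_norm[top] > 0
        if not ok.all():
            warnings.warn(f"pair {pid!r}: {int((~ok).sum())} zero-input genes "
                          "excluded from the enrichment factor")
        if not ok.any():
            raise CapnormError(f"pair {pid!r}: no usable top genes")
        F = en_counts[top][ok] / in_norm[top][ok]
        fold_factors[en[0]] = float(summarise(F))
        sf.loc[en[0]] = fold_factors[en[0]]

    overall = sf / np.exp(np.log(sf).mean())
    values = log_transform(dataset.counts) - np.log2(overall.to_numpy())
    return NormalizedMatrix(
        values=values,
        procedure=Procedure(scaling="RADAR"),
        provenance={"method": "RADAR", "size_factors": overall,
                    "enrichment_fold_factors": fold_factors,
                    "ruv_W": None},
    )


def ruvg_baseline(dataset: Dataset, gene_sets, k: int = 4) -> NormalizedMatrix:
    """Standalone RUVg comparator: anchor controls, k factors, no scaling."""
    if k == 0:
        return apply_procedure(dataset, Procedure("none"), gene_sets)
    return apply_procedure(dataset, Procedure("none", "RUVg", k), gene_sets)
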