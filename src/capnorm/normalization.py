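"""The two-part normalization space: global scaling × RUV factor regression.

A *procedure* is one point in the cross product of

* a scaling method — none, total count (TC), upper quartile (UQ), trimmed
  mean of M-values (TMM), median-of-ratios (DESeq) or PoissonSeq's iterative
  depth estimate — yielding per-sample size factors (geometric mean 1) and
  log2-scale offsets, and
* a remove-unwanted-variation step — none, RUVg, RUVs or RUVse with k ≥ 1
  factors estimated by SVD of a (suitably centred) control-gene submatrix.

With offsets O = log2(size factors) and log2-scale expression Y, the
adjusted matrix is  Y* = Y − O − W α̂,  where W holds the unwanted-variation
factors and α̂ their OLS nuisance coefficients.  Enumerating 6 scalers × (no
RUV + 3 variants × k = 1..5) gives the canonical 96-procedure space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (ConfigurationError, Dataset, ModelError, ParameterError,
                   log_transform)
from .gene_sets import ControlGeneSets

SCALING_METHODS = ("none", "TC", "UQ", "TMM", "DESeq", "PoissonSeq")
RUV_VARIANTS = ("RUVg", "RUVs", "RUVse")


@dataclass
class ScalingResult:
    method: str
    size_factors: pd.Series          # per sample, geometric mean 1
    offsets: pd.Series               # log2(size_factors)
    excluded_genes: list = field(default_factory=list)


@dataclass
class RuvFit:
    variant: str
    k: int
    W: pd.DataFrame                  # samples × k
    alpha: pd.DataFrame              # k × genes
    control_genes: list


@dataclass(frozen=True)
class Procedure:
    scaling: str
    ruv_variant: str = "none"
    k: int = 0

    def __post_init__(self):
        if (self.ruv_variant == "none") != (self.k == 0):
            raise ParameterError("ruv_variant is 'none' iff k == 0")

    @property
    def name(self) -> str:
        if self.ruv_variant == "none":
            return self.scaling if self.scaling != "none" else "raw"
        return f"{self.scaling}+{self.ruv_variant}_k{self.k}"


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame             # genes × samples, log2 scale
    procedure: Procedure
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def _geo_rescale(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    if (raw <= 0).any() or not np.isfinite(raw).all():
        raise ModelError("size factors must be positive and finite")
    return raw / np.exp(np.log(raw).mean())


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Log2 trimmed-mean-of-M-values correction for one sample vs reference."""
    ok = (obs > 0) & (ref > 0)
    if ok.sum() < 2:
        return 0.0
    po, pr = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # precision weights from the delta method on binomial counts
    w = 1.0 / ((n_obs - obs[ok]) / (n_obs * obs[ok])
               + (n_ref - ref[ok]) / (n_ref * ref[ok]))
    lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    return float((w[keep] * m[keep]).sum() / w[keep].sum())


def _poissonseq_factors(y: np.ndarray, min_total: int = 5, tol: float = 1e-6,
                        max_iter: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Iterative sequencing-depth estimate using Poisson goodness-of-fit.

    Genes with total count < ``min_total`` are discarded; the working gene
    set is iteratively refined to those whose goodness-of-fit statistic lies
    in the central half of the distribution.
    """
    totals = y.sum(axis=1)
    eligible = totals >= min_total
    if eligible.sum() < 2:
        raise ModelError("too few genes with adequate counts for PoissonSeq")
    sub = y[eligible]
    sub_tot = sub.sum(axis=1)
    keep = np.ones(sub.shape[0], dtype=bool)
    d = sub.sum(axis=0) / sub.sum()
    for _ in range(max_iter):
        d_new = sub[keep].sum(axis=0) / sub[keep].sum()
        expected = np.outer(sub_tot, d_new)
        gof = ((sub - expected) ** 2 / np.maximum(expected, 1e-12)).sum(axis=1)
        lo, hi = np.quantile(gof, [0.25, 0.75])
        keep = (gof >= lo) & (gof <= hi)
        if not keep.any():
            keep = np.ones(sub.shape[0], dtype=bool)
        if np.abs(d_new - d).max() < tol:
            d = d_new
            break
        d = d_new
    return d, ~eligible


def compute_scale_factors(counts, method: str) -> ScalingResult:
    """Per-sample size factors for one of the global scaling methods.

    Factors are rescaled to geometric mean 1 so that procedures are
    directly comparable; ``offsets`` are their log2.
    """
    if isinstance(counts, Dataset):
        counts = counts.counts
    if method not in SCALING_METHODS:
        raise ParameterError(f"unknown scaling method {method!r}")
    y = counts.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    if n_samples < 2 and method != "none":
        raise ParameterError("scaling needs at least 2 samples")
    excluded: list = []

    if method == "none":
        raw = np.ones(n_samples)
    elif method == "TC":
        raw = y.sum(axis=0)
    elif method == "UQ":
        raw = np.array([
            np.quantile(col[col > 0], 0.75) if (col > 0).any() else 1.0
            for col in y.T
        ])
    elif method == "DESeq":
        allpos = (y > 0).all(axis=1)
        if not allpos.any():
            raise ModelError(
                "DESeq scaling needs at least one gene with nonzero counts in "
                "every sample; try TC or TMM"
            )
        excluded = list(counts.index[~allpos])
        ref = np.exp(np.log(y[allpos]).mean(axis=1))
        raw = np.median(y[allpos] / ref[:, None], axis=0)
    elif method == "TMM":
        libs = y.sum(axis=0)
        uq = np.array([
            np.quantile(col[col > 0] / n, 0.75) if (col > 0).any() else 0.0
            for col, n in zip(y.T, libs)
        ])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
        tmm = np.array([
            1.0 if s == ref_idx else
            2.0 ** _tmm_pair(y[:, s], y[:, ref_idx], libs[s], libs[ref_idx])
            for s in range(n_samples)
        ])
        raw = libs * tmm
    else:  # PoissonSeq
        d, excl_mask = _poissonseq_factors(y)
        excluded = list(counts.index[excl_mask])
        raw = d

    factors = _geo_rescale(raw)
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    return ScalingResult(method=method, size_factors=sf,
                         offsets=np.log2(sf).rename("offset"),
                         excluded_genes=excluded)


# ---------------------------------------------------------------------------
# RUV
# ---------------------------------------------------------------------------

def _replicate_centered(Z: np.ndarray, groups, sample_ids) -> np.ndarray:
    """Centre control-gene rows within each replicate group."""
    if isinstance(groups, pd.Series) and set(sample_ids).issubset(groups.index):
        labels = groups.loc[list(sample_ids)].astype(str).to_numpy()
    else:
        labels = np.asarray(groups, dtype=str)
    if len(labels) != Z.shape[1]:
        raise ParameterError("replicate_groups length must match sample count")
    Zc = Z.copy()
    for lev in np.unique(labels):
        cols = np.flatnonzero(labels == lev)
        if len(cols) < 2:
            raise ParameterError(
                f"replicate group {lev!r} has a single sample; RUVs/RUVse need >= 2"
            )
        Zc[:, cols] -= Zc[:, cols].mean(axis=1, keepdims=True)
    return Zc


def estimate_ruv_factors(log_expr: pd.DataFrame, control_genes, variant: str,
                         k: int, replicate_groups: pd.Series | None = None) -> RuvFit:
    """Estimate k unwanted-variation factors from negative-control genes.

    ``log_expr`` is the genes × samples log2 expression matrix (already
    offset-adjusted if a scaling step precedes this one).  For RUVg the
    control submatrix is row-centred before SVD; for RUVs/RUVse it is
    centred within each replicate group so that effects shared by a group
    (including, for RUVse, the enrichment effect) cannot enter the factor
    space.  ``W`` holds the leading right-singular directions (per-sample,
    orthonormal, each orthogonal to the group structure used for centring);
    ``alpha`` comes from OLS regression of every gene on W.
    """
    if variant not in RUV_VARIANTS:
        raise ParameterError(f"unknown RUV variant {variant!r}")
    if k < 1:
        raise ParameterError("k must be >= 1")
    control_genes = [g for g in control_genes]
    if not control_genes:
        raise ConfigurationError("empty control-gene list")
    missing = set(control_genes) - set(log_expr.index)
    if missing:
        raise ConfigurationError(f"control genes absent from matrix: {sorted(missing)[:5]}")
    if k > log_expr.shape[1]:
        raise ParameterError("k cannot exceed the number of samples")

    Z = log_expr.loc[control_genes].to_numpy(dtype=float)
    if variant == "RUVg":
        Zc = Z - Z.mean(axis=1, keepdims=True)
    else:
        if replicate_groups is None:
            raise ParameterError(f"{variant} requires replicate_groups")
        Zc = _replicate_centered(Z, replicate_groups, log_expr.columns)

    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    admissible = int((s > 1e-10).sum())
    if k > admissible:
        raise ParameterError(
            f"k={k} exceeds the admissible rank {admissible} of the centred "
            "control submatrix"
        )
    W = Vt[:k].T  # samples × k, orthonormal
    Y = log_expr.to_numpy(dtype=float)
    alpha, *_ = np.linalg.lstsq(W, Y.T, rcond=None)  # k × genes
    return RuvFit(
        variant=variant, k=k,
        W=pd.DataFrame(W, index=log_expr.columns,
                       columns=[f"W{i+1}" for i in range(k)]),
        alpha=pd.DataFrame(alpha, index=[f"W{i+1}" for i in range(k)],
                           columns=log_expr.index),
        control_genes=control_genes,
    )


def ruv_replicate_groups(samples: pd.DataFrame, variant: str) -> pd.Series | None:
    """Default replicate-group labels per variant.

    RUVs pools assay levels within each biological group (so enrichment
    contrasts enter the difference space); RUVse crosses assay with group so
    the enrichment effect is protected.
    """
    if variant == "RUVg":
        return None
    if variant == "RUVs":
        return samples["group"].astype(str)
    if variant == "RUVse":
        return samples["group"].astype(str) + "/" + samples["assay"].astype(str)
    raise ParameterError(f"unknown RUV variant {variant!r}")


def adjust_counts(log_expr: pd.DataFrame, ruv: RuvFit | None = None,
                  scaling: ScalingResult | None = None,
                  procedure: Procedure | None = None) -> NormalizedMatrix:
    """Y* = Y − O − W α̂ on the log2 scale.

    With no RUV fit and no scaling this is the identity on ``log_expr``.
    """
    vals = log_expr.to_numpy(dtype=float).copy()
    if scaling is not None:
        off = scaling.offsets.loc[log_expr.columns].to_numpy()
        vals = vals - off[None, :]
    if ruv is not None:
        W = ruv.W.loc[log_expr.columns].to_numpy()
        A = ruv.alpha[log_expr.index].to_numpy()
        if W.shape[1] != A.shape[0]:
            raise ParameterError("RUV fit shapes not conformable")
        vals = vals - (W @ A).T
    proc = procedure or Procedure(
        scaling=scaling.method if scaling else "none",
        ruv_variant=ruv.variant if ruv else "none",
        k=ruv.k if ruv else 0,
    )
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=log_expr.index, columns=log_expr.columns),
        procedure=proc,
        provenance={
            "size_factors": None if scaling is None else scaling.size_factors,
            "offsets_log2": None if scaling is None else scaling.offsets,
            "ruv_W": None if ruv is None else ruv.W,
            "control_genes": None if ruv is None else ruv.control_genes,
        },
    )


# ---------------------------------------------------------------------------
# procedure space
# ---------------------------------------------------------------------------

def enumerate_procedures(scaling_set=SCALING_METHODS, ruv_variants=RUV_VARIANTS,
                         k_max: int = 5) -> list[Procedure]:
    """Deterministic cross product of scalers × ({no RUV} ∪ variants × k)."""
    if not scaling_set:
        raise ParameterError("scaling_set must be non-empty")
    if ruv_variants and k_max < 1:
        raise ParameterError("k_max must be >= 1")
    # the unnormalized baseline is always part of the space
    scalers = (["none"] if "none" not in scaling_set else []) + list(scaling_set)
    procs: list[Procedure] = []
    seen = set()
    for s in scalers:
        combos = [("none", 0)] + [(v, k) for v in ruv_variants
                                  for k in range(1, k_max + 1)]
        for v, k in combos:
            p = Procedure(scaling=s, ruv_variant=v, k=k)
            if p not in seen:
                seen.add(p)
                procs.append(p)
    return procs


def apply_procedure(dataset: Dataset, procedure: Procedure,
                    gene_sets: ControlGeneSets | None = None) -> NormalizedMatrix:
    """Run one full normalization procedure on a dataset.

    Composition: size factors → offset-adjusted log2 expression → RUV factor
    estimation on the anchor set → adjustment.  Provenance (factors, W,
    controls) travels with the result so downstream tests can reuse it.
    """
    scaling = compute_scale_factors(dataset.counts, procedure.scaling)
    log_expr = log_transform(dataset.counts)
    adj = log_expr - scaling.offsets.to_numpy()  # broadcasts over columns
    ruv = None
    if procedure.ruv_variant != "none":
        if gene_sets is None or not gene_sets.anchor:
            raise ConfigurationError(
                f"procedure {procedure.name} needs a non-empty anchor set"
            )
        groups = ruv_replicate_groups(dataset.samples, procedure.ruv_variant)
        ruv = estimate_ruv_factors(adj, gene_sets.anchor,
                                   procedure.ruv_variant, procedure.k,
                                   replicate_groups=groups)
    out = adjust_counts(log_expr, ruv=ruv, scaling=scaling, procedure=procedure)
    out.provenance["anchor_set"] = None if gene_sets is None else list(gene_sets.anchor)
    return out
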