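"""Sample outlier detection, gene filtering and saturation assessment.

Outliers are flagged by a generalized extreme studentized deviate (Rosner)
test on the first principal component of a variance-flattened matrix
(log2 counts-per-million of the top-variance genes).  Gene filtering
re-implements the published expression-filter heuristic: a gene is kept
when its CPM exceeds the CPM equivalent of ``min_count`` at the median
library size in at least as many samples as the smallest design cell, and
ribosomal-RNA / TEC biotypes are removed.  Sequencing saturation is
assessed by binomial downsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CapnormError, Dataset, ParameterError


@dataclass
class QcReport:
    outlier_samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    kept_genes: list = field(default_factory=list)
    n_removed_low_expression: int = 0
    n_removed_biotype: int = 0
    saturation_curve: pd.DataFrame | None = None


def _log_cpm(counts: pd.DataFrame) -> np.ndarray:
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / np.maximum(libs, 1.0) * 1e6
    return np.log2(cpm + 1.0)


def rosner_test(x, max_outliers: int, alpha: float = 0.05) -> list[int]:
    """Generalized ESD test; returns indices of detected outliers.

    At step i the most extreme remaining point is removed and its
    studentized deviate R_i compared with the critical value λ_i; the
    declared outliers are the first i* removals where i* is the largest i
    with R_i > λ_i.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_outliers < 1 or max_outliers > n - 2:
        raise ParameterError("max_outliers must lie in [1, n-2]")
    idx = list(range(n))
    removed: list[int] = []
    n_signif = 0
    for i in range(1, max_outliers + 1):
        sub = x[idx]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        r = dev[j] / sd
        removed.append(idx.pop(j))
        m = n - i  # points remaining after removal
        p = 1.0 - alpha / (2.0 * (m + 1))
        t = stats.t.ppf(p, m - 1)
        lam = m * t / math.sqrt((m - 1 + t**2) * (m + 1))
        if r > lam:
            n_signif = i
    return removed[:n_signif]


def detect_outlier_samples(dataset: Dataset, n_top_genes: int = 20000,
                           alpha: float = 0.05,
                           max_outliers: int | None = None) -> QcReport:
    """Flag outlying samples via Rosner's test on PC1 scores."""
    n = dataset.n_samples
    if n < 4:
        raise ParameterError("outlier detection needs at least 4 samples")
    if max_outliers is None:
        max_outliers = max(1, math.ceil(0.1 * n))
    if n < max_outliers + 2:
        raise ParameterError("need at least max_outliers + 2 samples")

    X = _log_cpm(dataset.counts)
    var = X.var(axis=1)
    top = np.argsort(-var, kind="stable")[: min(n_top_genes, X.shape[0])]
    sub = X[top]
    centred = (sub - sub.mean(axis=1, keepdims=True)).T  # samples × genes
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    pc1 = U[:, 0] * s[0]
    flagged = rosner_test(pc1, max_outliers=max_outliers, alpha=alpha)
    out = pd.DataFrame(
        {"pc1_score": pc1[flagged]},
        index=dataset.counts.columns[flagged],
    )
    out.index.name = "sample_id"
    return QcReport(outlier_samples=out)


def _is_ribosomal(biotype: str) -> bool:
    return "rrna" in str(biotype).lower()


def filter_genes(dataset: Dataset, min_count: float = 20,
                 min_prop: float = 0.7) -> tuple[Dataset, QcReport]:
    """Expression and biotype gene filter.

    The CPM cutoff is ``min_count`` scaled to the median library size; a
    gene passes when it clears the cutoff in at least ``n_min`` samples,
    where ``n_min`` is the smallest group × assay cell (damped by
    ``min_prop`` above 10 samples, mirroring the published large-n rule).
    Ribosomal-RNA and TEC biotypes are then removed.
    """
    counts = dataset.counts
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    cpm_cutoff = min_count / np.median(libs) * 1e6
    cells = dataset.samples["group"].astype(str) + "/" + dataset.samples["assay"].astype(str)
    n_min = cells.value_counts().min()
    if n_min > 10:
        n_min = 10 + (n_min - 10) * min_prop
    cpm = counts.to_numpy(dtype=float) / np.maximum(libs, 1.0) * 1e6
    keep_expr = (cpm >= cpm_cutoff).sum(axis=1) >= n_min

    biotypes = dataset.genes["biotype"]
    bad_biotype = biotypes.map(_is_ribosomal).to_numpy() | (biotypes == "TEC").to_numpy()
    keep = keep_expr & ~bad_biotype
    if not keep.any():
        raise CapnormError(
            "all genes removed by filtering; review min_count and biotypes"
        )
    kept_ids = list(counts.index[keep])
    report = QcReport(
        kept_genes=kept_ids,
        n_removed_low_expression=int((~keep_expr).sum()),
        n_removed_biotype=int((keep_expr & bad_biotype).sum()),
    )
    return dataset.subset_genes(kept_ids), report


def saturation_curve(dataset: Dataset, fractions, detect_threshold: int = 10,
                     seed: int = 0) -> pd.DataFrame:
    """Mean number of endogenous genes detected after binomial downsampling.

    For each fraction f in (0, 1], every count is thinned Binomial(y, f)
    (f = 1 leaves the data untouched) and the mean over samples of the
    number of endogenous genes with count > ``detect_threshold`` is
    reported.
    """
    fractions = sorted(set(float(f) for f in fractions))
    if any(not (0.0 < f <= 1.0) for f in fractions):
        raise ParameterError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    endo = dataset.gene_ids("endogenous")
    y = dataset.counts.loc[endo].to_numpy()
    rows = []
    for f in fractions:
        thinned = y if f == 1.0 else rng.binomial(y, f)
        detected = (thinned > detect_threshold).sum(axis=0)
        rows.append((f, float(detected.mean())))
    return pd.DataFrame(rows, columns=["fraction", "genes_detected"])
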