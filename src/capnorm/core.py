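"""Data containers and file I/O for paired input/enrichment count experiments.

The central object is :class:`Dataset`: a genes × samples matrix of
non-negative integer read counts together with aligned sample metadata
(batch, assay, biological group, input/enrichment pairing) and gene
metadata (origin, biotype).  Genes are rows and samples are columns
everywhere in the public API, following the bulk-RNA-seq convention;
normalized values are real-valued on the log2 scale and are never coerced
back to integers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

ORIGINS = ("endogenous", "spikein", "synthetic_nad", "synthetic_m7g")
ASSAYS = ("input", "enrichment")

SAMPLE_COLUMNS = ("batch", "assay", "group", "pair_id")
GENE_COLUMNS = ("origin", "biotype")


class CapnormError(Exception):
    """Base class for all package errors."""


class ValidationError(CapnormError):
    """Cross-reference or invariant violation in input tables."""


class DataError(CapnormError):
    """Malformed numeric data (negative or non-integer counts, NaN p-values...)."""


class ParameterError(CapnormError):
    """Invalid or infeasible parameter combination."""


class ModelError(CapnormError):
    """Degenerate statistical model (rank-deficient design, no residual df...)."""


class ConfigurationError(CapnormError):
    """A required input (gene set, origin class, assay level) is missing."""


@dataclass
class Dataset:
    """Counts plus aligned sample and gene metadata.

    Parameters
    ----------
    counts
        genes × samples DataFrame of non-negative integers; index are gene
        ids, columns are sample ids.
    samples
        one row per sample (index = sample id) with columns ``batch``,
        ``assay`` (``input`` / ``enrichment``), ``group`` and ``pair_id``.
    genes
        one row per gene (index = gene id) with columns ``origin`` (one of
        ``endogenous``, ``spikein``, ``synthetic_nad``, ``synthetic_m7g``)
        and ``biotype``; an optional positive ``length`` column is allowed.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValidationError("gene and sample identifiers must be unique")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise DataError("counts must be numeric")
        if np.isnan(vals.astype(float)).any():
            raise DataError("counts contain missing values")
        if (vals < 0).any():
            bad = c.index[(vals < 0).any(axis=1)][:5].tolist()
            raise DataError(f"negative counts for genes {bad}")
        if not np.allclose(vals, np.round(vals)):
            raise DataError("counts must be integers")

        missing = set(c.columns) - set(self.samples.index)
        extra = set(self.samples.index) - set(c.columns)
        if missing or extra:
            raise ValidationError(
                f"sample metadata mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        missing_g = set(c.index) - set(self.genes.index)
        extra_g = set(self.genes.index) - set(c.index)
        if missing_g or extra_g:
            raise ValidationError(
                "gene metadata mismatch: "
                f"missing={sorted(missing_g)[:5]} extra={sorted(extra_g)[:5]}"
            )
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValidationError(f"sample table lacks required column {col!r}")
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise ValidationError(f"gene table lacks required column {col!r}")
        bad_origin = set(self.genes["origin"]) - set(ORIGINS)
        if bad_origin:
            raise ValidationError(f"unknown gene origin levels: {sorted(bad_origin)}")
        bad_assay = set(self.samples["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ValidationError(f"assay must be one of {ASSAYS}, got {sorted(bad_assay)}")

        # reorder metadata to matrix order
        self.samples = self.samples.loc[c.columns]
        self.genes = self.genes.loc[c.index]

        # pairing: each pair id maps to exactly one input and one enrichment
        for pid, sub in self.samples.groupby("pair_id"):
            assays = sorted(sub["assay"])
            if assays != ["enrichment", "input"]:
                raise ValidationError(
                    f"pair {pid!r} must link exactly one input and one enrichment "
                    f"sample, got assays {assays}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def gene_ids(self, origin: str | None = None) -> list[str]:
        if origin is None:
            return list(self.counts.index)
        return list(self.genes.index[self.genes["origin"] == origin])

    def subset_genes(self, gene_ids) -> "Dataset":
        gene_ids = list(gene_ids)
        return Dataset(
            counts=self.counts.loc[gene_ids].copy(),
            samples=self.samples.copy(),
            genes=self.genes.loc[gene_ids].copy(),
        )

    def subset_samples(self, sample_ids) -> "Dataset":
        sample_ids = list(sample_ids)
        return Dataset(
            counts=self.counts[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
            genes=self.genes.copy(),
        )


# -- I/O -------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def _mtx_sidecars(counts_path: Path) -> tuple[Path, Path]:
    stem = counts_path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def load_dataset(counts_path, samples_path, genes_path, format: str = "tsv") -> Dataset:
    """Load and validate a dataset from disk.

    ``format`` is one of ``tsv``, ``csv`` (counts as a labelled table with the
    first column holding gene ids) or ``mtx`` (MatrixMarket matrix with
    ``<stem>.rows.txt`` / ``<stem>.cols.txt`` sidecar label files).  Metadata
    tables are TSV for ``tsv``/``mtx`` and CSV for ``csv``.
    """
    counts_path = Path(counts_path)
    if format in _SEPS:
        counts = pd.read_csv(counts_path, sep=_SEPS[format], index_col=0)
    elif format == "mtx":
        rows_path, cols_path = _mtx_sidecars(counts_path)
        mat = scipy.io.mmread(counts_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = rows_path.read_text().split()
        sample_ids = cols_path.read_text().split()
        counts = pd.DataFrame(np.asarray(mat), index=gene_ids, columns=sample_ids)
    else:
        raise ParameterError(f"unknown format {format!r}; use tsv, csv or mtx")

    meta_sep = _SEPS.get(format, "\t")
    samples = pd.read_csv(samples_path, sep=meta_sep, index_col=0, dtype=str)
    genes = pd.read_csv(genes_path, sep=meta_sep, index_col=0)
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise DataError("counts did not parse as a numeric matrix")
    counts = counts.astype(np.int64) if np.allclose(
        counts.to_numpy(), np.round(counts.to_numpy())
    ) else counts
    return Dataset(counts=counts, samples=samples, genes=genes)


def save_dataset(dataset: Dataset, counts_path, samples_path, genes_path,
                 format: str = "tsv") -> None:
    """Write a dataset back to disk in any supported ``format`` (round-trips
    with :func:`load_dataset`)."""
    counts_path = Path(counts_path)
    if format in _SEPS:
        dataset.counts.to_csv(counts_path, sep=_SEPS[format])
    elif format == "mtx":
        rows_path, cols_path = _mtx_sidecars(counts_path)
        scipy.io.mmwrite(str(counts_path), scipy.sparse.coo_matrix(dataset.counts.to_numpy()))
        rows_path.write_text("\n".join(dataset.counts.index) + "\n")
        cols_path.write_text("\n".join(dataset.counts.columns) + "\n")
    else:
        raise ParameterError(f"unknown format {format!r}")
    meta_sep = _SEPS.get(format, "\t")
    dataset.samples.to_csv(samples_path, sep=meta_sep)
    dataset.genes.to_csv(genes_path, sep=meta_sep)


def log_transform(matrix):
    """Elementwise ``log2(x + 1)``.

    Monotone, maps 0 to 0, invertible on its range via ``2**y - 1``.
    Accepts arrays or DataFrames and preserves labels.
    """
    vals = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if (vals < 0).any():
        raise DataError("log_transform requires non-negative input")
    out = np.log2(vals + 1.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out
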