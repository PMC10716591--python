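"""Selection of the three control-gene sets driving normalization and scoring.

Three disjoint roles, all ranked by the NB likelihood-ratio statistic:

* **anchor** — exogenous spike-in genes *least* affected by the capture step
  (assay tested against an intercept-only model, batch deliberately left out
  of the model so that batch variation survives into these genes); they are
  the negative controls from which unwanted-variation factors are estimated.
* **negative evaluation** — endogenous genes least affected by *any* wanted
  covariate (assay + biological group); residual variation among them
  measures unwanted variation left after normalization.
* **positive evaluation** — endogenous genes most strongly enriched by
  capture; they measure preservation of the wanted signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, Dataset
from .diffstats import nb_glm_lrt

DEFAULT_ANCHOR_SIZE = 1000
DEFAULT_EVAL_SIZE = 500


@dataclass
class ControlGeneSets:
    anchor: list[str]
    negative_eval: list[str]
    positive_eval: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.anchor), len(self.negative_eval), len(self.positive_eval))


def _libsize_offsets(counts: pd.DataFrame) -> np.ndarray:
    """Natural-log library-size offsets, centred at geometric mean 1."""
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    libs = np.maximum(libs, 1.0)
    off = np.log(libs)
    return off - off.mean()


def assay_design(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(full, reduced) designs for an enrichment-vs-input test."""
    assay = (samples["assay"] == "enrichment").to_numpy(dtype=float)
    full = np.column_stack([np.ones(len(samples)), assay])
    reduced = np.ones((len(samples), 1))
    return full, reduced


def covariate_design(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(full, reduced) designs spanning all wanted covariates (assay + group)."""
    assay = (samples["assay"] == "enrichment").to_numpy(dtype=float)
    cols = [np.ones(len(samples)), assay]
    groups = pd.Categorical(samples["group"])
    for level in groups.categories[1:]:
        cols.append((groups == level).astype(float))
    full = np.column_stack(cols)
    reduced = np.ones((len(samples), 1))
    return full, reduced


def _ranked_genes(dataset: Dataset, gene_ids: list[str], full, reduced,
                  offsets) -> pd.DataFrame:
    counts = dataset.counts.loc[gene_ids]
    res = nb_glm_lrt(counts, full, reduced, offsets=offsets)
    # stable sort: ties broken by gene order
    return res.iloc[np.argsort(res["lr_stat"].to_numpy(), kind="stable")]


def _take(ranked_ids: list[str], n: int, label: str, warn_list: list[str]) -> list[str]:
    if n > len(ranked_ids):
        warn_list.append(
            f"{label}: requested {n} genes but only {len(ranked_ids)} candidates"
        )
        warnings.warn(warn_list[-1])
        n = len(ranked_ids)
    return ranked_ids[:n]


def select_anchor_set(dataset: Dataset, n: int = DEFAULT_ANCHOR_SIZE,
                      _warnings: list[str] | None = None) -> list[str]:
    """The ``n`` least significantly enriched spike-in genes."""
    spike = dataset.gene_ids("spikein")
    if not spike:
        raise ConfigurationError("no spike-in genes in dataset; anchor set undefined")
    if set(dataset.samples["assay"]) != {"input", "enrichment"}:
        raise ConfigurationError("anchor selection needs both assay levels")
    full, reduced = assay_design(dataset.samples)
    ranked = _ranked_genes(dataset, spike, full, reduced,
                           _libsize_offsets(dataset.counts))
    return _take(list(ranked.index), n, "anchor", _warnings if _warnings is not None else [])


def select_negative_eval(dataset: Dataset, n: int = DEFAULT_EVAL_SIZE,
                         _warnings: list[str] | None = None) -> list[str]:
    """The ``n`` endogenous genes least affected by any wanted covariate."""
    endo = dataset.gene_ids("endogenous")
    if not endo:
        raise ConfigurationError("no endogenous genes in dataset")
    full, reduced = covariate_design(dataset.samples)
    ranked = _ranked_genes(dataset, endo, full, reduced,
                           _libsize_offsets(dataset.counts))
    return _take(list(ranked.index), n, "negative_eval",
                 _warnings if _warnings is not None else [])


def select_positive_eval(dataset: Dataset, n: int = DEFAULT_EVAL_SIZE,
                         _warnings: list[str] | None = None) -> list[str]:
    """The ``n`` endogenous genes most significantly enriched by capture."""
    endo = dataset.gene_ids("endogenous")
    if not endo:
        raise ConfigurationError("no endogenous genes in dataset")
    if set(dataset.samples["assay"]) != {"input", "enrichment"}:
        raise ConfigurationError("positive-evaluation selection needs both assay levels")
    full, reduced = assay_design(dataset.samples)
    ranked = _ranked_genes(dataset, endo, full, reduced,
                           _libsize_offsets(dataset.counts))
    ids = list(ranked.index)[::-1]  # descending LR
    return _take(ids, n, "positive_eval", _warnings if _warnings is not None else [])


def select_gene_sets(dataset: Dataset, n_anchor: int = DEFAULT_ANCHOR_SIZE,
                     n_negative: int = DEFAULT_EVAL_SIZE,
                     n_positive: int = DEFAULT_EVAL_SIZE) -> ControlGeneSets:
    """Select all three control-gene sets in one pass."""
    warns: list[str] = []
    anchor = select_anchor_set(dataset, n_anchor, _warnings=warns)
    neg = select_negative_eval(dataset, n_negative, _warnings=warns)
    pos = select_positive_eval(dataset, n_positive, _warnings=warns)
    overlap = set(neg) & set(pos)
    if overlap:
        # disjointness invariant: drop shared genes from the negative set
        warns.append(f"{len(overlap)} genes in both evaluation sets; removed from negative_eval")
        neg = [g for g in neg if g not in overlap]
    return ControlGeneSets(anchor=anchor, negative_eval=neg, positive_eval=pos,
                           warnings=warns)
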