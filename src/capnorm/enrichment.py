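"""NAD-RNA identification and per-sample modification levels.

A gene is called NAD-capped when its enrichment-vs-input fold change of
normalized counts is at least ``fc_threshold`` (default 2, boundary
inclusive) at FDR < ``fdr_threshold`` (default 0.05).  The test is the NB
likelihood-ratio test from :mod:`capnorm.diffstats`; by default it runs on
the raw counts with the procedure's size-factor offsets and its estimated
unwanted-variation factors W carried as model covariates, so the adjustment
is used exactly once ("covariate-adjusted" mode).  The alternative
"normalized-refit" mode back-transforms the adjusted matrix to pseudo-counts
and refits without W.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ConfigurationError, Dataset, ValidationError
from .diffstats import nb_glm_lrt
from .normalization import NormalizedMatrix


def _design_with_w(samples: pd.DataFrame, W: pd.DataFrame | None):
    assay = (samples["assay"] == "enrichment").to_numpy(dtype=float)
    base = [np.ones(len(samples))]
    groups = pd.Categorical(samples["group"])
    for level in groups.categories[1:]:
        base.append((groups == level).astype(float))
    if W is not None:
        base.extend(W.loc[samples.index].to_numpy().T)
    reduced = np.column_stack(base)
    full = np.column_stack([reduced[:, :1], assay, reduced[:, 1:]])
    return full, reduced


def find_enrichment(dataset: Dataset, normalized: NormalizedMatrix,
                    fc_threshold: float = 2.0, fdr_threshold: float = 0.05,
                    mode: str = "covariate-adjusted",
                    origins=("endogenous", "synthetic_nad", "synthetic_m7g"),
                    ) -> pd.DataFrame:
    """Enrichment calls per gene.

    Returns a DataFrame indexed by gene id with ``log2_fc``, ``p_value``,
    ``fdr``, ``is_nad_rna`` and ``origin``.  Synthetic spike-ins run through
    the same machinery and act as sensitivity (NAD-capped, must be called)
    and specificity (m7G-capped, must not) controls.
    """
    if set(dataset.samples["assay"]) != {"input", "enrichment"}:
        raise ConfigurationError("enrichment calling needs both assay levels")
    gene_ids = [g for g in normalized.values.index
                if dataset.genes.loc[g, "origin"] in origins]
    samples = dataset.samples

    if mode == "covariate-adjusted":
        counts = dataset.counts.loc[gene_ids]
        W = normalized.provenance.get("ruv_W")
        full, reduced = _design_with_w(samples, W)
        sf = normalized.provenance.get("size_factors")
        offsets = None if sf is None else np.log(sf.loc[samples.index].to_numpy())
        res = nb_glm_lrt(counts, full, reduced, offsets=offsets)
    elif mode == "normalized-refit":
        pseudo = np.rint(np.maximum(2.0 ** normalized.values.loc[gene_ids] - 1.0, 0.0))
        full, reduced = _design_with_w(samples, None)
        res = nb_glm_lrt(pseudo.astype(int), full, reduced)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    lfc_cut = np.log2(fc_threshold)
    out = pd.DataFrame(
        {
            "log2_fc": res["log2_fold_change"],
            "lr_stat": res["lr_stat"],
            "p_value": res["p_value"],
            "fdr": res["fdr"],
        },
        index=res.index,
    )
    out["is_nad_rna"] = (out["log2_fc"] >= lfc_cut - 1e-12) & (out["fdr"] < fdr_threshold)
    out["origin"] = dataset.genes.loc[out.index, "origin"].to_numpy()
    return out


def modification_levels(normalized: NormalizedMatrix,
                        samples: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-pair log2(enrichment/input) of adjusted values.

    One column per ``pair_id``; raises if any pair is incomplete.
    """
    vals = normalized.values
    bad = []
    cols = {}
    for pid, sub in samples.groupby("pair_id"):
        en = sub.index[sub["assay"] == "enrichment"]
        inp = sub.index[sub["assay"] == "input"]
        if len(en) != 1 or len(inp) != 1:
            bad.append(pid)
            continue
        cols[pid] = vals[en[0]] - vals[inp[0]]
    if bad:
        raise ValidationError(f"incomplete input/enrichment pairs: {sorted(bad)}")
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    return out
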