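"""Synthetic-data generator emulating the spike-in experimental design.

Each simulated experiment contains endogenous genes (biology + batch +
enrichment effects), exogenous spike-in genes (batch + enrichment but no
biology of interest), one synthetic spike-in that is partially NAD-capped
(hence enriched by capture) and one that is fully m7G-capped (not
enriched).  Libraries come in input/enrichment pairs sharing biological
means and batch; counts are negative binomial around a log-linear mean

    log2 mu = base + group effect + assay effect + batch structure,

with columns rescaled to target library sizes.  Batch enters by default as
a low-rank factor model (per-batch factor vectors × per-gene loadings), the
generative family the RUV adjustment assumes, so recovery tests are fair; a
full-rank per-gene shift mode exercises robustness to misspecification.
Ground truth (NAD labels, batch factors/loadings, library sizes) travels
with the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Dataset, ParameterError

SYN_NAD_ID = "SYN_NAD"
SYN_M7G_ID = "SYN_M7G"


@dataclass
class SimParams:
    """Study-design parameters for :func:`simulate_dataset`.

    Defaults emulate a desk-scale version of a paired spike-in experiment:
    2000 endogenous + 1000 spike-in genes, 2 biological groups × 6 pairs
    (24 libraries) across 3 batches, rank-2 batch structure with per-gene
    SD 1.0 on the log2 scale, a 4-fold (log2 = 2) enrichment effect on 5%
    of endogenous genes and on the synthetic NAD spike-in, and NB
    dispersion 0.1.
    """

    n_endogenous: int = 2000
    n_spikein: int = 1000
    n_samples_per_group: int = 6          # input/enrichment pairs per group
    n_batches: int = 3
    n_groups: int = 2
    batch_sd: float = 1.0                 # log2-scale SD of batch structure
    n_batch_factors: int = 2
    batch_mode: str = "factor"            # "factor" (low-rank) or "shift"
    enrichment_lfc: float = 2.0           # log2 FC of true NAD genes
    frac_nad: float = 0.05
    frac_spikein_enriched: float = 0.2
    group_lfc_sd: float = 1.0
    frac_group_de: float = 0.3
    dispersion: float = 0.1
    lib_size_range: tuple = (8e5, 1.2e6)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_endogenous, self.n_spikein, self.n_samples_per_group,
               self.n_batches, self.n_groups) < 1:
            raise ParameterError("all design counts must be >= 1")
        for frac in (self.frac_nad, self.frac_spikein_enriched, self.frac_group_de):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError("fractions must lie in [0, 1]")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.batch_sd > 0 and self.n_batches < 2:
            raise ParameterError("batch_sd > 0 requires >= 2 batches")
        if self.batch_mode not in ("factor", "shift"):
            raise ParameterError("batch_mode must be 'factor' or 'shift'")


@dataclass
class SimulationTruth:
    true_nad_genes: list
    batch_factors: pd.DataFrame          # samples × n_batch_factors (factor mode)
    batch_loadings: pd.DataFrame         # genes × n_batch_factors
    enrichment_effects: pd.Series        # per-gene log2 FC
    group_effects: pd.DataFrame          # genes × groups log2 offsets
    size_factors: pd.Series              # per-sample target library sizes
    enriched_spikeins: list = field(default_factory=list)
    true_negative_controls: list = field(default_factory=list)


def simulate_dataset(params: SimParams | None = None, **overrides
                     ) -> tuple[Dataset, SimulationTruth]:
    """Generate a paired input/enrichment dataset plus its ground truth.

    Fully reproducible from ``params.seed``.
    """
    if params is None:
        params = SimParams(**overrides)
    elif overrides:
        raise ParameterError("pass either params or keyword overrides, not both")
    params.validate()
    rng = np.random.default_rng(params.seed)

    endo_ids = [f"ENDO{i:05d}" for i in range(params.n_endogenous)]
    spike_ids = [f"SPIKE{i:05d}" for i in range(params.n_spikein)]
    gene_ids = endo_ids + spike_ids + [SYN_NAD_ID, SYN_M7G_ID]
    G = len(gene_ids)
    origin = (["endogenous"] * params.n_endogenous
              + ["spikein"] * params.n_spikein
              + ["synthetic_nad", "synthetic_m7g"])
    genes = pd.DataFrame({"origin": origin, "biotype": "protein_coding"},
                         index=pd.Index(gene_ids, name="gene_id"))
    genes.loc[spike_ids, "biotype"] = "spikein_rna"
    genes.loc[[SYN_NAD_ID, SYN_M7G_ID], "biotype"] = "synthetic_rna"

    # -- samples: pairs assigned round-robin to batches ------------------
    rows = []
    pair_no = 0
    for g in range(params.n_groups):
        for r in range(params.n_samples_per_group):
            batch = f"b{pair_no % params.n_batches + 1}"
            pid = f"p{pair_no + 1:03d}"
            for assay in ("input", "enrichment"):
                rows.append({
                    "sample_id": f"{pid}_{'in' if assay == 'input' else 'en'}",
                    "batch": batch, "assay": assay,
                    "group": f"g{g + 1}", "pair_id": pid,
                })
            pair_no += 1
    samples = pd.DataFrame(rows).set_index("sample_id")
    S = len(samples)

    # -- effect components (log2 scale) ----------------------------------
    base = np.empty(G)
    base[: params.n_endogenous] = rng.normal(5.0, 2.0, params.n_endogenous)
    base[params.n_endogenous:-2] = rng.normal(5.0, 2.0, params.n_spikein)
    base[-2:] = 8.0

    group_levels = [f"g{g + 1}" for g in range(params.n_groups)]
    group_eff = np.zeros((G, params.n_groups))
    n_de = int(round(params.frac_group_de * params.n_endogenous))
    de_idx = rng.choice(params.n_endogenous, size=n_de, replace=False)
    group_eff[de_idx, 1:] = rng.normal(0.0, params.group_lfc_sd,
                                       size=(n_de, params.n_groups - 1))

    enr = np.zeros(G)
    n_nad = int(round(params.frac_nad * params.n_endogenous))
    nad_idx = rng.choice(params.n_endogenous, size=n_nad, replace=False)
    enr[nad_idx] = params.enrichment_lfc
    n_spike_enr = int(round(params.frac_spikein_enriched * params.n_spikein))
    spike_enr_idx = params.n_endogenous + rng.choice(
        params.n_spikein, size=n_spike_enr, replace=False)
    enr[spike_enr_idx] = params.enrichment_lfc
    enr[-2] = params.enrichment_lfc      # synthetic NAD spike-in
    enr[-1] = 0.0                        # synthetic m7G spike-in

    b = params.n_batch_factors
    batch_levels = sorted(samples["batch"].unique())
    if params.batch_mode == "factor":
        per_batch = rng.normal(0.0, 1.0, size=(len(batch_levels), b))
        F = np.vstack([per_batch[batch_levels.index(bt)]
                       for bt in samples["batch"]])          # samples × b
        L = rng.normal(0.0, params.batch_sd / np.sqrt(b), size=(G, b))
        batch_term = (L @ F.T) if params.batch_sd > 0 else np.zeros((G, S))
        if params.batch_sd == 0:
            L = np.zeros((G, b))
    else:  # full-rank per-gene shift per batch
        shifts = rng.normal(0.0, params.batch_sd, size=(G, len(batch_levels)))
        cols = np.array([batch_levels.index(bt) for bt in samples["batch"]])
        batch_term = shifts[:, cols]
        F = np.zeros((S, b))
        L = np.zeros((G, b))

    assay_ind = (samples["assay"] == "enrichment").to_numpy(dtype=float)
    gcodes = np.array([group_levels.index(g) for g in samples["group"]])
    mu_log2 = (base[:, None]
               + group_eff[:, gcodes]
               + np.outer(enr, assay_ind)
               + batch_term)

    rel = 2.0 ** mu_log2
    lib = rng.uniform(*params.lib_size_range, size=S)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]

    if params.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / params.dispersion
        counts = rng.poisson(rng.gamma(shape, mu / shape))

    dataset = Dataset(
        counts=pd.DataFrame(counts.astype(np.int64), index=genes.index,
                            columns=samples.index),
        samples=samples,
        genes=genes,
    )
    truth = SimulationTruth(
        true_nad_genes=[endo_ids[i] for i in sorted(nad_idx)],
        batch_factors=pd.DataFrame(F, index=samples.index,
                                   columns=[f"f{i+1}" for i in range(b)]),
        batch_loadings=pd.DataFrame(L, index=genes.index,
                                    columns=[f"f{i+1}" for i in range(b)]),
        enrichment_effects=pd.Series(enr, index=genes.index),
        group_effects=pd.DataFrame(group_eff, index=genes.index,
                                   columns=group_levels),
        size_factors=pd.Series(lib, index=samples.index),
        enriched_spikeins=[gene_ids[i] for i in sorted(spike_enr_idx)],
        true_negative_controls=[gene_ids[i] for i in range(params.n_endogenous, G - 2)
                                if enr[i] == 0.0],
    )
    return dataset, truth


def evaluate_against_truth(calls: pd.DataFrame, truth: SimulationTruth) -> dict:
    """Precision / recall / F1 of NAD calls against the planted labels.

    Only endogenous genes enter the comparison; the call table's endogenous
    universe must cover every true NAD gene.
    """
    endo_calls = calls[calls["origin"] == "endogenous"] if "origin" in calls else calls
    universe = set(endo_calls.index)
    true_set = set(truth.true_nad_genes)
    if not true_set <= universe:
        missing = sorted(true_set - universe)[:5]
        raise ParameterError(f"call table does not cover true NAD genes: {missing}")
    called = set(endo_calls.index[endo_calls["is_nad_rna"]])
    tp = len(called & true_set)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(true_set) if true_set else float("nan")
    f1 = (0.0 if not called or tp == 0
          else 2 * precision * recall / (precision + recall))
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_called": len(called),
        "n_true": len(true_set),
        "no_calls": not called,
    }
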