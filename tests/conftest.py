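import numpy as np
import pandas as pd
import pytest

from capnorm import select_gene_sets
from capnorm.core import Dataset
from capnorm.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def sim_default():
    """Default study-conditions simulation, seed fixed."""
    return simulate_dataset(SimParams(seed=1))


@pytest.fixture(scope="session")
def gene_sets_default(sim_default):
    ds, _ = sim_default
    return select_gene_sets(ds)


def make_toy_dataset(counts, origins=None, biotypes=None, batches=None,
                     groups=None):
    """Small paired dataset builder: samples come as in/en pairs."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    assert n_samples % 2 == 0
    gene_ids = [f"g{i}" for i in range(n_genes)]
    rows = []
    for p in range(n_samples // 2):
        for assay, suffix in (("input", "in"), ("enrichment", "en")):
            rows.append({
                "sample_id": f"p{p}_{suffix}",
                "batch": (batches[p] if batches else "b1"),
                "assay": assay,
                "group": (groups[p] if groups else "g1"),
                "pair_id": f"p{p}",
            })
    samples = pd.DataFrame(rows).set_index("sample_id")
    genes = pd.DataFrame(
        {
            "origin": origins or ["endogenous"] * n_genes,
            "biotype": biotypes or ["protein_coding"] * n_genes,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return Dataset(
        counts=pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                            columns=samples.index),
        samples=samples,
        genes=genes,
    )


@pytest.fixture()
def toy_dataset():
    rng = np.random.default_rng(42)
    return make_toy_dataset(rng.poisson(50, size=(6, 4)))
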