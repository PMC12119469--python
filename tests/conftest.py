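import numpy as np
import pandas as pd
import pytest

from lobeomics.io import CountMatrix, SampleSheet
from lobeomics.simulate import sim_bulk, sim_chromatin, sim_gene_models


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """A tiny fixture bundle shared by pipeline-level tests."""
    from lobeomics.simulate import write_fixture_bundle

    outdir = tmp_path_factory.mktemp("bundle") / "tiny"
    write_fixture_bundle(outdir, scale="tiny", seed=11)
    return outdir


@pytest.fixture(scope="session")
def bulk_sim():
    """Default bulk simulation with planted trend genes (seeded)."""
    return sim_bulk(n_genes=400, seed=21)


@pytest.fixture(scope="session")
def chromatin_sim():
    models = sim_gene_models(
        n_genes=150,
        chrom_sizes={"chr1": 3_000_000, "chr2": 3_000_000},
        seed=22,
        promoter_disjoint=True,
    )
    return models, sim_chromatin(models, seed=23)


def make_count_matrix(counts, groups, lobes=None, replicates=None):
    """Small helper to assemble a CountMatrix from a dense array."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    sample_ids = [f"s{i}" for i in range(n)]
    table = pd.DataFrame(
        {
            "group": groups,
            "lobe": lobes if lobes is not None else ["L"] * n,
            "replicate": replicates if replicates is not None else list(range(1, n + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    frame = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=sample_ids
    )
    return CountMatrix(frame, SampleSheet(table))
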