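import numpy as np
import pandas as pd
import pytest

from phnatlas import synth
from phnatlas.io import AbundanceProfile, GeneCatalog


@pytest.fixture(scope="session")
def small_config():
    return synth.SimulationConfig(
        n_genomes=60, n_samples=24, read_depth=2e5, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    truth, catalog = synth.generate_community(small_config)
    dataset = synth.simulate_profiles(truth, catalog, small_config)
    return dataset, catalog, small_config


@pytest.fixture(scope="session")
def noise_free_dataset():
    config = synth.SimulationConfig(
        n_genomes=80, n_samples=16, read_depth=1e5, noise_free=True, seed=13
    )
    truth, catalog = synth.generate_community(config)
    dataset = synth.simulate_profiles(truth, catalog, config)
    return dataset, catalog, config


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """A complete on-disk input bundle, small enough for fast end-to-end runs."""
    from phnatlas import pipeline

    outdir = tmp_path_factory.mktemp("bundle")
    config = synth.SimulationConfig(
        n_genomes=60, n_samples=24, read_depth=2e5, seed=7
    )
    pipeline.write_synthetic_bundle(outdir, config)
    return outdir, config


def random_profile(rng, n_genes=6, n_samples=4):
    genes = [f"gene{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    values = rng.gamma(1.0, 1.0, size=(n_genes, n_samples))
    values[rng.random(values.shape) < 0.2] = 0.0
    return AbundanceProfile(pd.DataFrame(values, index=genes, columns=samples))


def toy_catalog(entries):
    """entries: list of (gene_id, function_id, length[, taxon_bin, is_scg])."""
    rows = []
    for e in entries:
        gene_id, function_id, length = e[:3]
        taxon = e[3] if len(e) > 3 else None
        is_scg = e[4] if len(e) > 4 else False
        rows.append(
            {
                "gene_id": gene_id,
                "function_id": function_id,
                "length": length,
                "taxon_bin": taxon,
                "is_scg": is_scg,
            }
        )
    return GeneCatalog(pd.DataFrame(rows))
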