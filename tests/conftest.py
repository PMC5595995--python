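"""Shared fixtures: synthetic datasets run through the calling stage once per session."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mchscape import calling, io as mio
from mchscape.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def run_calling(ds, threshold=1e-5):
    """Coverage-filter, integrate and binomially call a simulated dataset."""
    table = mio.coverage_filter(ds.multi_aligner_table())
    icfg = calling.IntegrationConfig(non_conversion_rate=ds.config.ncr)
    meth = calling.integrate_methylation(table, icfg, context_index=ds.context)
    return calling.call_methylated(meth, icfg, threshold=threshold)


def make_dataset(mode, seed=1, genome_length=300_000, n_genes=40,
                 gene_length_range=(1000, 5000), **overrides):
    cfg = SimulationConfig.for_mode(
        mode, seed=seed, genome_length=genome_length, n_genes=n_genes,
        gene_length_range=gene_length_range, **overrides,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def esc_dataset():
    """ESC-mode dataset large enough for profile, motif and width analyses."""
    return make_dataset("esc", seed=11, genome_length=800_000, n_genes=120,
                        gene_length_range=(1050, 6000))


@pytest.fixture(scope="session")
def esc_methylome(esc_dataset):
    return run_calling(esc_dataset)


@pytest.fixture(scope="session")
def neuron_dataset():
    return make_dataset("neuron", seed=12, genome_length=800_000, n_genes=120,
                        gene_length_range=(1050, 6000))


@pytest.fixture(scope="session")
def neuron_methylome(neuron_dataset):
    return run_calling(neuron_dataset)


@pytest.fixture(scope="session")
def small_esc_dataset():
    return make_dataset("esc", seed=13, genome_length=150_000, n_genes=15,
                        gene_length_range=(1000, 4000))


@pytest.fixture(scope="session")
def small_esc_methylome(small_esc_dataset):
    return run_calling(small_esc_dataset)


def toy_methylome(rows):
    """Build a methylome DataFrame from (chrom, pos, strand, cclass, trinuc, level) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "cclass", "trinuc", "level"])
    df["symclass"] = np.where(
        df["cclass"] == "CpG", "CpG",
        np.where(df["trinuc"].str[2] == "G", "CpHpG", "CpHpH"),
    )
    df["depth"] = 20
    df["meth"] = (df["level"] * 20).round().astype(int)
    df["n_aligners"] = 2
    return df
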