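#!/usr/bin/env python
"""Simulate a small WGBS cohort: two ESC-like and two neuron-like samples.

Writes per-sample datasets (genome FASTA, three aligner count tables, gene
models, expression, H3K36me3-like peaks, ground truth) under
results/datasets/<sample>/. Later steps consume these files only, so the
whole analysis runs from what this script produces.
"""

from pathlib import Path

from mchscape.simulate import SimulationConfig, simulate_dataset, write_dataset

OUT = Path("results/datasets")
COHORT = [
    ("esc_1", "esc", 101),
    ("esc_2", "esc", 102),
    ("neuron_1", "neuron", 103),
    ("neuron_2", "neuron", 104),
]
GENOME_LENGTH = 600_000
N_GENES = 90
GENE_LENGTHS = (1050, 6000)


def main():
    for sample, mode, seed in COHORT:
        cfg = SimulationConfig.for_mode(
            mode, seed=seed, genome_length=GENOME_LENGTH, n_genes=N_GENES,
            gene_length_range=GENE_LENGTHS,
        )
        ds = simulate_dataset(cfg)
        write_dataset(ds, OUT / sample)
        cph = ds.truth[ds.truth["cclass"] == "CpH"]["true_m"]
        print(f"{sample} ({mode}): {len(ds.truth)} sites, "
              f"mean true mCpH level {cph.mean():.4f}")
    print(f"datasets written under {OUT}/")


if __name__ == "__main__":
    main()
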