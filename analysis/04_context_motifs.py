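#!/usr/bin/env python
"""Trinucleotide-context methylation preferences and hyper-mCpH motifs.

ESC-like samples are expected to prefer CAG (DNMT3b-style deposition) and
neuron-like samples CAC (DNMT3a-style); the consensus motif at
hyper-methylated CpHs (level > 0.5) makes the same contrast. Writes
results/context/*.
"""

from pathlib import Path

from mchscape import context_motif as cm, io as mio, reference

METH = Path("results/methylomes")
DATASETS = Path("results/datasets")
OUT = Path("results/context")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for path in sorted(METH.glob("*.methylome.tsv.gz")):
        sample = path.name.split(".")[0]
        meth = mio.read_methylome(path)
        genome = reference.load_fasta(DATASETS / sample / "genome.fa")

        summ = cm.context_mean_levels(meth)
        cm.context_summary_frame(summ).to_csv(OUT / f"{sample}.context_summary.tsv",
                                              sep="\t", index=False)
        prox = cm.context_mean_levels(meth, scope="mCpG-proximal")
        cm.context_summary_frame(prox).to_csv(OUT / f"{sample}.context_summary_proximal.tsv",
                                              sep="\t", index=False)
        pfm = cm.motif_at_hypermethylated(meth, genome)
        pfm.write(OUT / f"{sample}.motif_pfm.tsv")

        bc = summ["by_context"]
        print(f"{sample}: mean mCAG {bc['CAG']['mean']:.4f}, mean mCAC "
              f"{bc['CAC']['mean']:.4f}; hyper-mCpH consensus {pfm.consensus} "
              f"({pfm.n_sites} sites)")


if __name__ == "__main__":
    main()
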