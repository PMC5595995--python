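#!/usr/bin/env python
"""Gene-body CpH methylation vs expression and H3K36me3 occupancy.

Per sample: gene-body mCpH/mCAG summaries, Spearman correlation with FPKM
(expected positive in ESC-like, negative in neuron-like samples) and with
the H3K36me3 overlap rate (expected stronger than with FPKM in ESC-like
samples), the metagene profile by expression group, and the
hyper-mCAG + H3K36me3 gene screen. Writes results/genes/*.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mchscape import genes as gm, io as mio

METH = Path("results/methylomes")
DATASETS = Path("results/datasets")
OUT = Path("results/genes")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for path in sorted(METH.glob("*.methylome.tsv.gz")):
        sample = path.name.split(".")[0]
        meth = mio.read_methylome(path)
        d = DATASETS / sample
        genes = gm.load_gene_table(d / "genes.tsv")
        expression = pd.read_csv(d / "expression.tsv", sep="\t")
        peaks = pd.read_csv(d / "peaks.bed", sep="\t", header=None,
                            names=["chrom", "start", "end"])

        summ = gm.build_gene_summaries(meth, genes, expression, peaks)
        summ.round(6).to_csv(OUT / f"{sample}.gene_summaries.tsv", sep="\t", index=False)
        rho_fpkm = gm.expression_correlation(summ.rename(columns={"mean_mcph": "mean_level"}))
        rho_ovl = gm.expression_correlation(
            summ.rename(columns={"mean_mcph": "mean_level"})
            .drop(columns=["fpkm"]).rename(columns={"overlap_rate": "fpkm"})
        )

        parts = [gm.metagene_profile(meth, genes, expression, group=g)
                 for g in ("high20", "low20", "all")]
        pd.concat(parts).round(6).to_csv(OUT / f"{sample}.metagene.tsv", sep="\t", index=False)
        tss, tts = gm.tss_tts_bins()
        hi_body = np.nanmean(parts[0]["mean"].to_numpy()[tss:tts])
        lo_body = np.nanmean(parts[1]["mean"].to_numpy()[tss:tts])

        selected, quantile = gm.screen_genes(summ)
        selected.round(6).to_csv(OUT / f"{sample}.screened_genes.tsv", sep="\t", index=False)

        print(f"{sample}: rho(mCpH, FPKM) = {rho_fpkm:+.3f}, rho(mCpH, H3K36me3 "
              f"overlap) = {rho_ovl:+.3f}; body mCpH high20 {hi_body:.4f} vs low20 "
              f"{lo_body:.4f}; screen keeps {len(selected)} genes "
              f"(mCAG cut at the {quantile:.2f} quantile)")


if __name__ == "__main__":
    main()
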