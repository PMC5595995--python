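#!/usr/bin/env python
"""Integrate the three aligners' count tables and call methylated cytosines.

For each cohort sample: coverage filter (>=5 pooled reads from >=2 aligners),
read-depth weighted integration minus the non-conversion rate, binomial
calling at p < 1e-5, and an artificial-methylome FDR curve confirming the
threshold operates below 1% FDR. Writes results/methylomes/<sample>.* .
"""

from pathlib import Path

import pandas as pd

from mchscape import calling, io as mio, reference

DATASETS = Path("results/datasets")
OUT = Path("results/methylomes")
NCR = 0.005


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for sample_dir in sorted(DATASETS.iterdir()):
        sample = sample_dir.name
        genome = reference.load_fasta(sample_dir / "genome.fa")
        ctx = reference.classify_cytosines(genome)
        tables = [
            mio.read_cytosine_report(sample_dir / f"aligner{j}.tsv.gz", "generic", f"aligner{j}")[0]
            for j in (1, 2, 3)
        ]
        table = mio.coverage_filter(pd.concat(tables, ignore_index=True))
        icfg = calling.IntegrationConfig(non_conversion_rate=NCR)
        meth = calling.integrate_methylation(table, icfg, context_index=ctx)
        calib = calling.calibrate_fdr(meth, NCR, seed=1)
        meth = calling.call_methylated(meth, icfg)
        mio.write_methylome(meth, OUT / f"{sample}.methylome.tsv.gz")
        calib.to_frame().to_csv(OUT / f"{sample}.calibration.tsv", sep="\t", index=False)
        i = (calib.thresholds == 1e-5).argmax()
        print(f"{sample}: {len(meth)} sites, {int(meth['called'].sum())} called; "
              f"FDR at 1e-5 = {calib.fdr[i]:.2e}, chosen threshold {calib.chosen_threshold}")


if __name__ == "__main__":
    main()
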