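"""Trinucleotide-context methylation summaries and hyper-mCpH motif extraction.

DNMT3a and DNMT3b deposit CpH methylation with different sequence
preferences (CAC-centric vs CAG-centric), so the mean methylation level per
trinucleotide context — genome-wide or restricted to mCpG-proximal windows —
and the consensus motif at hyper-methylated CpHs (level > 0.5) are the core
read-outs distinguishing ESC-like from neuron-like methylomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import HYPER_MCPH_LEVEL
from .reference import reverse_complement

FOCUS_CONTEXTS = ["CAC", "CAT", "CAA", "CAG"]
PROXIMAL_ANCHOR_LEVEL = 0.5   #: anchors for the mCpG-proximal scope use level > 0.5
PROXIMAL_WINDOW = 100


def context_mean_levels(
    methylome: pd.DataFrame,
    scope: str = "genome-wide",
    proximal_window: int = PROXIMAL_WINDOW,
    anchor_level: float = PROXIMAL_ANCHOR_LEVEL,
) -> dict:
    """Unweighted mean CpH level per trinucleotide context and symmetry class.

    ``scope="genome-wide"`` uses every CpH; ``scope="mCpG-proximal"``
    restricts to CpHs within +-``proximal_window`` bp of a CpG with level
    greater than ``anchor_level``. Contexts with zero sites are reported
    absent (NaN mean, count 0).
    """
    cph = methylome[methylome["cclass"] == "CpH"]
    if scope == "mCpG-proximal":
        cph = _restrict_proximal(methylome, cph, proximal_window, anchor_level)
    elif scope != "genome-wide":
        raise ValueError(f"unknown scope: {scope!r}")

    tri = cph["trinuc"].astype(str).to_numpy()
    lev = cph["level"].to_numpy()
    by_context = {}
    for ctx in FOCUS_CONTEXTS:
        m = tri == ctx
        by_context[ctx] = {"mean": float(lev[m].mean()) if m.any() else float("nan"),
                           "n": int(m.sum())}
    other = ~np.isin(tri, FOCUS_CONTEXTS)
    by_context["other"] = {"mean": float(lev[other].mean()) if other.any() else float("nan"),
                           "n": int(other.sum())}

    sym = cph["symclass"].astype(str).to_numpy()
    by_symclass = {}
    for sc in ("CpHpG", "CpHpH"):
        m = sym == sc
        by_symclass[sc] = {"mean": float(lev[m].mean()) if m.any() else float("nan"),
                           "n": int(m.sum())}
    return {"scope": scope, "by_context": by_context, "by_symclass": by_symclass}


def _restrict_proximal(methylome, cph, window, anchor_level):
    anchors = methylome[(methylome["cclass"] == "CpG") & (methylome["level"] > anchor_level)]
    keep_idx = []
    for chrom in cph["chrom"].astype(str).unique():
        t = cph[cph["chrom"].astype(str) == chrom]
        a = anchors[anchors["chrom"].astype(str) == chrom]
        if a.empty or t.empty:
            continue
        apos = np.sort(a["pos"].to_numpy())
        tpos = t["pos"].to_numpy()
        right = np.searchsorted(apos, tpos)
        left = np.clip(right - 1, 0, apos.size - 1)
        right = np.clip(right, 0, apos.size - 1)
        dist = np.minimum(np.abs(apos[right] - tpos), np.abs(tpos - apos[left]))
        keep_idx.append(t.index[dist <= window])
    if not keep_idx:
        return cph.iloc[0:0]
    return cph.loc[np.concatenate([k.to_numpy() for k in keep_idx])]


def context_summary_frame(summary: dict) -> pd.DataFrame:
    rows = [
        {"scope": summary["scope"], "group": "context", "name": k, **v}
        for k, v in summary["by_context"].items()
    ] + [
        {"scope": summary["scope"], "group": "symclass", "name": k, **v}
        for k, v in summary["by_symclass"].items()
    ]
    return pd.DataFrame(rows)


class PositionFrequencyMatrix:
    """Base counts at positions -1..+4 around hyper-methylated CpHs.

    ``counts`` is a 4 x 6 array (rows A, C, G, T); ``consensus`` is the
    per-column argmax with ties broken in fixed base order A<C<G<T and
    recorded in ``tie_columns``.
    """

    POSITIONS = list(range(-1, 5))
    BASES = "ACGT"

    def __init__(self, counts: np.ndarray):
        if counts.shape != (4, len(self.POSITIONS)):
            raise ValueError("PFM must be 4 x 6")
        self.counts = counts.astype(np.int64)
        self.consensus = "".join(self.BASES[i] for i in np.argmax(self.counts, axis=0))
        colmax = self.counts.max(axis=0)
        self.tie_columns = [
            self.POSITIONS[j]
            for j in range(self.counts.shape[1])
            if (self.counts[:, j] == colmax[j]).sum() > 1
        ]

    @property
    def n_sites(self) -> int:
        return int(self.counts[:, 0].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.BASES), columns=self.POSITIONS)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            self.to_frame().to_csv(fh, sep="\t")
            fh.write(f"#consensus\t{self.consensus}\n")


def motif_at_hypermethylated(
    methylome: pd.DataFrame,
    genome: dict[str, str],
    level_cut: float = HYPER_MCPH_LEVEL,
    window: tuple[int, int] = (-1, 4),
) -> PositionFrequencyMatrix:
    """PFM of the sequence window around hyper-methylated CpHs (level > cut).

    Sequences are read 5'->3' on each site's own strand; sites whose window
    leaves the chromosome are dropped. Uses the level cutoff, not the
    binomial call.
    """
    lo, hi = window
    hyper = methylome[(methylome["cclass"] == "CpH") & (methylome["level"] > level_cut)]
    if hyper.empty:
        raise ValueError("no CpH sites above the hyper-methylation cutoff")
    counts = np.zeros((4, hi - lo + 1), dtype=np.int64)
    base_index = {b: i for i, b in enumerate("ACGT")}
    n_used = 0
    for chrom in hyper["chrom"].astype(str).unique():
        seq = genome[chrom]
        sub = hyper[hyper["chrom"].astype(str) == chrom]
        for pos, strand in zip(sub["pos"].to_numpy(), sub["strand"].astype(str)):
            if strand == "+":
                s, e = pos + lo, pos + hi + 1
                if s < 0 or e > len(seq):
                    continue
                frag = seq[s:e]
            else:
                s, e = pos - hi, pos - lo + 1
                if s < 0 or e > len(seq):
                    continue
                frag = reverse_complement(seq[s:e])
            if any(b not in base_index for b in frag):
                continue
            for j, b in enumerate(frag):
                counts[base_index[b], j] += 1
            n_used += 1
    if n_used == 0:
        raise ValueError("no hyper-methylated CpH with a complete sequence window")
    return PositionFrequencyMatrix(counts)
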