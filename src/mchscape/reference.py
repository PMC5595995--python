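"""Reference genome handling and cytosine context classification.

Every cytosine on either strand of the genome is classified into CpG vs CpH,
its trinucleotide context (3-mer read 5'->3' on the cytosine's own strand,
starting at the cytosine, e.g. ``CAG``), and its symmetry class: ``CpG``,
symmetric ``CpHpG`` (third base G) or asymmetric ``CpHpH`` (third base A/C/T).

Coordinates are 0-based internally. A reverse-strand cytosine is anchored at
the forward-strand coordinate of its G, so each genomic position carries at
most one site per strand (cytosine-report convention). Report writers emit
1-based positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import COMPLEMENT_CODE, seq_to_codes

TRINUC_LABELS = ["C" + a + b for a in "ACGT" for b in "ACGT"]

CCLASS_CAT = pd.CategoricalDtype(["CpG", "CpH"])
SYMCLASS_CAT = pd.CategoricalDtype(["CpG", "CpHpG", "CpHpH"])
STRAND_CAT = pd.CategoricalDtype(["+", "-"])


def load_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an in-memory {chrom: uppercase sequence} mapping."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=False, build_index=True)
    genome = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _classify_chrom(chrom: str, seq: str) -> pd.DataFrame:
    codes = seq_to_codes(seq)
    n = codes.size

    # forward-strand cytosines with a full, N-free 3-mer window
    fidx = np.flatnonzero(codes == 1)
    fidx = fidx[fidx + 2 < n]
    if fidx.size:
        ok = (codes[fidx + 1] >= 0) & (codes[fidx + 2] >= 0)
        fidx = fidx[ok]
    f1, f2 = codes[fidx + 1], codes[fidx + 2]

    # reverse-strand cytosines are forward-strand Gs; context read on revcomp
    ridx = np.flatnonzero(codes == 2)
    ridx = ridx[ridx - 2 >= 0]
    if ridx.size:
        ok = (codes[ridx - 1] >= 0) & (codes[ridx - 2] >= 0)
        ridx = ridx[ok]
    r1 = COMPLEMENT_CODE[codes[ridx - 1]]
    r2 = COMPLEMENT_CODE[codes[ridx - 2]]

    pos = np.concatenate([fidx, ridx])
    rev = np.concatenate([np.zeros(fidx.size, bool), np.ones(ridx.size, bool)])
    c1 = np.concatenate([f1, r1])
    c2 = np.concatenate([f2, r2])

    order = np.lexsort((rev, pos))
    pos, rev, c1, c2 = pos[order], rev[order], c1[order], c2[order]

    is_cpg = c1 == 2
    sym = np.where(is_cpg, 0, np.where(c2 == 2, 1, 2))
    df = pd.DataFrame(
        {
            "chrom": pd.Categorical([chrom] * pos.size),
            "pos": pos.astype(np.int64),
            "strand": pd.Categorical.from_codes(rev.astype(np.int8), dtype=STRAND_CAT),
            "cclass": pd.Categorical.from_codes((~is_cpg).astype(np.int8), dtype=CCLASS_CAT),
            "trinuc": pd.Categorical.from_codes(
                (c1 * 4 + c2).astype(np.int8), categories=TRINUC_LABELS
            ),
            "symclass": pd.Categorical.from_codes(sym.astype(np.int8), dtype=SYMCLASS_CAT),
        }
    )
    return df


def classify_cytosines(genome: dict[str, str]) -> pd.DataFrame:
    """Classify every cytosine on both strands of ``genome``.

    Returns a context index sorted by (chrom, pos, strand) with columns
    chrom, pos (0-based), strand, cclass, trinuc, symclass. Sites whose 3-mer
    window runs off the chromosome end or contains N are dropped.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty reference")
    frames = [_classify_chrom(c, genome[c]) for c in genome]
    out = pd.concat(frames, ignore_index=True)
    out["chrom"] = out["chrom"].astype(pd.CategoricalDtype(list(genome.keys())))
    return out


def isolated_cpg_subset(sites: pd.DataFrame, radius: int = 500) -> pd.DataFrame:
    """CpG sites with no *other* CpG dyad within ``radius`` bp.

    A palindromic CpG produces two sites 1 bp apart (one per strand); the two
    are one dyad and never disqualify each other. CpGs on both strands of
    other dyads are counted (configurable only through the dyad definition).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cpg = sites[sites["cclass"] == "CpG"]
    keep_parts = []
    for chrom, grp in cpg.groupby("chrom", observed=True):
        dyad = grp["pos"].to_numpy() - (grp["strand"].to_numpy() == "-").astype(np.int64)
        uniq = np.unique(dyad)
        if uniq.size <= 1:
            iso = uniq
        else:
            gap_prev = np.concatenate(([np.iinfo(np.int64).max], np.diff(uniq)))
            gap_next = np.concatenate((np.diff(uniq), [np.iinfo(np.int64).max]))
            iso = uniq[(gap_prev > radius) & (gap_next > radius)]
        keep_parts.append(grp[np.isin(dyad, iso)])
    if not keep_parts:
        return cpg.iloc[0:0]
    return pd.concat(keep_parts).sort_index()


def write_context_index(sites: pd.DataFrame, path) -> None:
    """Write the context index as a (gzip-transparent) TSV with 1-based positions."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False, compression=_gz(path))


def read_context_index(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["chrom"] = pd.Categorical(df["chrom"])
    df["strand"] = df["strand"].astype(STRAND_CAT)
    df["cclass"] = df["cclass"].astype(CCLASS_CAT)
    df["symclass"] = df["symclass"].astype(SYMCLASS_CAT)
    df["trinuc"] = df["trinuc"].astype(pd.CategoricalDtype(TRINUC_LABELS))
    return df


def _gz(path):
    return {"method": "gzip", "mtime": 0} if str(path).endswith(".gz") else None
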