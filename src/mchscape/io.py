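"""Reading and reconciling per-cytosine count tables from multiple aligners.

Three tab-separated dialects are supported, all with 1-based positions:

``generic``
    5 columns: chrom, pos, strand, total_reads, methylated_reads.
``cx``
    Bismark coverage/CX-style: chrom, pos, strand, count_methylated,
    count_unmethylated, context_class (CpG/CHG/CHH), trinucleotide.
``methratio``
    BSMAP methratio.py layout: chr, pos, strand, context, ratio,
    eff_CT_count, C_count, CT_count, ...; methylated = C_count,
    total = CT_count.

Gzip is handled transparently by extension. The in-memory multi-aligner
table is a long DataFrame with one row per (site, aligner):
columns chrom, pos (0-based), strand, aligner, total, meth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import STRAND_CAT, _gz

logger = logging.getLogger(__name__)

MULTI_COLUMNS = ["chrom", "pos", "strand", "aligner", "total", "meth"]


@dataclass
class ParseReport:
    """Per-file bookkeeping: rows kept, malformed rows, M>t rejections."""

    n_rows: int = 0
    n_malformed: int = 0
    n_meth_exceeds_total: int = 0
    n_zero_depth: int = 0
    n_context_mismatch: int = 0
    messages: list = field(default_factory=list)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Categorical([]),
            "pos": pd.Series([], dtype=np.int64),
            "strand": pd.Series([], dtype=STRAND_CAT),
            "aligner": pd.Categorical([]),
            "total": pd.Series([], dtype=np.int64),
            "meth": pd.Series([], dtype=np.int64),
        }
    )


def read_cytosine_report(
    path,
    dialect: str,
    aligner_id: str,
    context_index: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ParseReport]:
    """Parse one aligner's cytosine report into the long multi-aligner layout.

    Rows with total == 0 are retained (flagged in the report); rows with
    meth > total are rejected and counted. If ``context_index`` is given,
    cx-dialect context columns are cross-checked against it and mismatches
    counted as warnings.
    """
    rep = ParseReport()
    if dialect == "generic":
        names = ["chrom", "pos", "strand", "total", "meth"]
        usecols = list(range(5))
    elif dialect == "cx":
        names = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinuc"]
        usecols = list(range(7))
    elif dialect == "methratio":
        names = ["chrom", "pos", "strand", "context", "ratio", "eff_ct", "meth", "total"]
        usecols = list(range(8))
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=names,
            usecols=usecols,
            comment="#",
            dtype={"chrom": str, "strand": str},
            on_bad_lines="skip",
        )
    except pd.errors.EmptyDataError:
        return _empty_table(), rep

    n_raw = len(df)
    num_cols = {"generic": ["pos", "total", "meth"], "cx": ["pos", "meth", "unmeth"],
                "methratio": ["pos", "meth", "total"]}[dialect]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = df[num_cols].notna().all(axis=1) & df["strand"].isin(["+", "-"])
    rep.n_malformed = int(n_raw - ok.sum())
    df = df[ok].copy()
    for c in num_cols:
        df[c] = df[c].astype(np.int64)

    if dialect == "cx":
        df["total"] = df["meth"] + df["unmeth"]

    bad = df["meth"] > df["total"]
    rep.n_meth_exceeds_total = int(bad.sum())
    if rep.n_meth_exceeds_total:
        logger.warning("%s: %d rows with meth > total rejected", path, rep.n_meth_exceeds_total)
    df = df[~bad]

    out = pd.DataFrame(
        {
            "chrom": pd.Categorical(df["chrom"]),
            "pos": df["pos"].to_numpy() - 1,  # to 0-based
            "strand": df["strand"].astype(STRAND_CAT),
            "aligner": pd.Categorical([aligner_id] * len(df)),
            "total": df["total"].to_numpy(),
            "meth": df["meth"].to_numpy(),
        }
    )
    rep.n_rows = len(out)
    rep.n_zero_depth = int((out["total"] == 0).sum())

    if dialect in ("cx", "methratio") and context_index is not None and len(out):
        ref = context_index.set_index(["chrom", "pos", "strand"])["trinuc"]
        key = pd.MultiIndex.from_frame(out[["chrom", "pos", "strand"]].astype({"chrom": str, "strand": str}))
        ref_tr = ref.reindex(key)
        claimed = df["trinuc" if dialect == "cx" else "context"].astype(str).to_numpy()
        known = ref_tr.notna().to_numpy()
        rep.n_context_mismatch = int((known & (ref_tr.to_numpy().astype(str) != claimed)).sum())
        if rep.n_context_mismatch:
            logger.warning("%s: %d context mismatches vs reference", path, rep.n_context_mismatch)
    return out, rep


def coverage_filter(
    table: pd.DataFrame, min_depth: int = 5, min_aligners: int = 2
) -> pd.DataFrame:
    """Keep sites with summed depth >= min_depth covered by >= min_aligners aligners.

    The default reading of "covered by more than 5 reads, aligned by more than
    two aligners" is >=5 and >=2; pass min_depth=6, min_aligners=3 for the
    literal strict reading.
    """
    if min_depth < 1 or min_aligners < 1:
        raise ValueError("min_depth and min_aligners must be >= 1")
    if table.empty:
        return table
    key, uniq = _factorize_sites(table)
    depth = np.bincount(key, weights=table["total"].to_numpy(), minlength=len(uniq))
    nalg = np.bincount(
        key[table["total"].to_numpy() > 0], minlength=len(uniq)
    )
    good = (depth >= min_depth) & (nalg >= min_aligners)
    return table[good[key]]


def _factorize_sites(table: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Integer site id per row for groupby-free aggregation."""
    key, uniq = pd.factorize(
        pd.MultiIndex.from_arrays(
            [table["chrom"], table["pos"], table["strand"]], names=["chrom", "pos", "strand"]
        ),
        sort=True,
    )
    return key, uniq


METHYLOME_COLUMNS = ["chrom", "pos", "strand", "cclass", "trinuc", "level", "depth", "meth", "n_aligners"]


def write_methylome(methylome: pd.DataFrame, path) -> None:
    """Write an integrated methylome as TSV (1-based positions, gzip by extension)."""
    out = methylome.copy()
    out["pos"] = out["pos"] + 1
    out["level"] = out["level"].round(6)
    out.to_csv(path, sep="\t", index=False, compression=_gz(path))


def read_methylome(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["chrom"] = pd.Categorical(df["chrom"])
    df["strand"] = df["strand"].astype(STRAND_CAT)
    return df
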