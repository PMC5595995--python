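"""Gene-body methylation, metagene profiles, expression and histone coupling.

Gene models carry (gene_id, chrom, strand, tss, tts); the gene body is the
TSS..TTS interval and only genes longer than 1 kb are analysed. The metagene
axis maps each gene body plus 20%-of-length flanks affinely onto 1000 bins,
which places the TSS in bin 142 and the TTS in bin 857 (1-based floor
convention). The histone overlapping rate of a gene is the fraction of its
body covered by the union of peak intervals. The H3K36me3 + mCAG screen
selects genes with mean gene-body CAG methylation above 0.05 and overlap
rate above 0.5, excluding LOC/Rik placeholder symbols.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._util import covered_length

logger = logging.getLogger(__name__)

MIN_GENE_LENGTH = 1000
MCAG_CUT = 0.05
OVERLAP_CUT = 0.5
EXCLUDED_PREFIXES = ("LOC", "Rik")
METAGENE_BINS = 1000
METAGENE_FLANK = 0.2
METAGENE_SMOOTH = 30


def load_gene_table(path) -> pd.DataFrame:
    """Read a gene model table: BED12 or the 6-column TSV dialect.

    The TSV dialect has a header (gene_id, chrom, strand, tss, tts, length);
    BED12 is recognised by its 12 tab-separated columns without header.
    """
    peek = pd.read_csv(path, sep="\t", header=None, nrows=1)
    if peek.shape[1] >= 12:
        bed = pd.read_csv(path, sep="\t", header=None).iloc[:, :6]
        bed.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
        tss = np.where(bed["strand"] == "+", bed["start"], bed["end"])
        tts = np.where(bed["strand"] == "+", bed["end"], bed["start"])
        genes = pd.DataFrame(
            {"gene_id": bed["gene_id"], "chrom": bed["chrom"], "strand": bed["strand"],
             "tss": tss, "tts": tts}
        )
    else:
        genes = pd.read_csv(path, sep="\t")
    genes["length"] = (genes["tts"] - genes["tss"]).abs()
    if (genes["length"] <= 0).any():
        raise ValueError("zero-length gene model")
    return genes


def _body_bounds(genes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s = np.minimum(genes["tss"], genes["tts"]).to_numpy()
    e = np.maximum(genes["tss"], genes["tts"]).to_numpy()
    return s, e


def gene_body_methylation(
    methylome: pd.DataFrame,
    genes: pd.DataFrame,
    context_filter: str = "all",
    min_len: int = MIN_GENE_LENGTH,
) -> pd.DataFrame:
    """Unweighted mean CpH-site level within each gene body (TSS..TTS).

    ``context_filter`` is one of ``all`` (every CpH), ``CAG`` (CAG trinuc
    only) or ``CpHpG`` (symmetric CpH). Genes shorter than ``min_len`` are
    dropped; genes with zero qualifying sites are absent from the result
    (counted in a warning).
    """
    genes = genes[genes["length"] > min_len]
    cph = methylome[methylome["cclass"] == "CpH"]
    if context_filter == "CAG":
        cph = cph[cph["trinuc"].astype(str) == "CAG"]
    elif context_filter == "CpHpG":
        cph = cph[cph["symclass"].astype(str) == "CpHpG"]
    elif context_filter != "all":
        raise ValueError(f"unknown context filter: {context_filter!r}")

    rows = []
    n_empty = 0
    for chrom, grp in genes.groupby("chrom", observed=True):
        sub = cph[cph["chrom"].astype(str) == str(chrom)].sort_values("pos")
        pos = sub["pos"].to_numpy()
        lev = sub["level"].to_numpy()
        cum = np.concatenate(([0.0], np.cumsum(lev)))
        s, e = _body_bounds(grp)
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="left")
        n = hi - lo
        mean = np.where(n > 0, (cum[hi] - cum[lo]) / np.maximum(n, 1), np.nan)
        n_empty += int((n == 0).sum())
        for gid, m, k, length in zip(grp["gene_id"], mean, n, grp["length"]):
            if k > 0:
                rows.append({"gene_id": gid, "mean_level": float(m), "n_sites": int(k),
                             "length": int(length)})
    if n_empty:
        logger.warning("%d genes with zero qualifying sites dropped", n_empty)
    return pd.DataFrame(rows)


def expression_groups(expression: pd.DataFrame, quantile: float = 0.2) -> pd.DataFrame:
    """Tag genes high20/low20/mid by FPKM quantile (ties kept inclusively)."""
    fpkm = expression["fpkm"].to_numpy()
    lo_cut = np.quantile(fpkm, quantile)
    hi_cut = np.quantile(fpkm, 1 - quantile)
    grp = np.where(fpkm >= hi_cut, "high20", np.where(fpkm <= lo_cut, "low20", "mid"))
    out = expression.copy()
    out["group"] = grp
    return out


def tss_tts_bins(nbins: int = METAGENE_BINS, flank: float = METAGENE_FLANK) -> tuple[int, int]:
    """1-based metagene bin indices of the TSS and TTS (142, 857 at defaults)."""
    span = 1.0 + 2.0 * flank
    return int(np.floor(flank / span * nbins)), int(np.floor((flank + 1.0) / span * nbins))


def metagene_profile(
    methylome: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    group: str = "all",
    nbins: int = METAGENE_BINS,
    flank: float = METAGENE_FLANK,
    smooth_window: int = METAGENE_SMOOTH,
    min_len: int = MIN_GENE_LENGTH,
) -> pd.DataFrame:
    """Mean CpH methylation across the normalised gene-body axis.

    Each gene's span [TSS - flank*L, TTS + flank*L] is mapped affinely onto
    ``nbins`` bins (bin order flipped for minus-strand genes), per-bin means
    are taken within genes then averaged over genes, and the result is
    smoothed with a centered ``smooth_window``-bin moving average.
    ``group`` selects high20/low20/all by FPKM quantile.
    """
    genes = genes[genes["length"] > min_len].copy()
    if group != "all":
        if expression is None:
            raise ValueError("expression table required for grouping")
        tagged = expression_groups(expression)
        wanted = set(tagged.loc[tagged["group"] == group, "gene_id"])
        genes = genes[genes["gene_id"].isin(wanted)]
    if genes.empty:
        raise ValueError(f"no genes in group {group!r}")

    cph = methylome[methylome["cclass"] == "CpH"]
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for chrom, grp in genes.groupby("chrom", observed=True):
        sub = cph[cph["chrom"].astype(str) == str(chrom)].sort_values("pos")
        pos = sub["pos"].to_numpy()
        lev = sub["level"].to_numpy()
        s, e = _body_bounds(grp)
        minus = (grp["strand"] == "-").to_numpy()
        L = (e - s).astype(float)
        span_s = s - flank * L
        span_len = (1 + 2 * flank) * L
        lo = np.searchsorted(pos, np.floor(span_s), side="left")
        hi = np.searchsorted(pos, np.ceil(s + (1 + flank) * L), side="right")
        for i in range(len(grp)):
            p = pos[lo[i]:hi[i]]
            v = lev[lo[i]:hi[i]]
            if p.size == 0:
                continue
            # bin by base midpoint: tie-free, so strand flip mirrors exactly
            frac = (p + 0.5 - span_s[i]) / span_len[i]
            b = np.clip(np.floor(frac * nbins).astype(np.int64), 0, nbins - 1)
            if minus[i]:
                b = nbins - 1 - b
            gs = np.bincount(b, weights=v, minlength=nbins)
            gn = np.bincount(b, minlength=nbins)
            has = gn > 0
            sums[has] += gs[has] / gn[has]
            counts[has] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    from ._util import moving_average

    w = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    smoothed = moving_average(mean, w)
    return pd.DataFrame(
        {"bin": np.arange(1, nbins + 1), "group": group, "mean": mean,
         "smoothed": smoothed, "n_genes": counts}
    )


def expression_correlation(summaries: pd.DataFrame, value_col: str = "mean_level") -> float:
    """Spearman rank correlation between gene-body methylation and FPKM."""
    sub = summaries.dropna(subset=[value_col, "fpkm"])
    if len(sub) < 10:
        raise ValueError("need at least 10 genes with methylation and expression")
    x = sub[value_col].to_numpy()
    y = sub["fpkm"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def histone_overlap_rate(genes: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each gene body covered by the union of histone peaks.

    overlapping rate = |union(peaks) intersect body| / body length. Peaks are
    half-open BED-style intervals and overlapping peaks are merged first.
    """
    if (genes["length"] <= 0).any():
        raise ValueError("zero-length gene")
    rates = np.zeros(len(genes))
    for chrom, grp in genes.groupby("chrom", observed=True):
        pk = peaks[peaks["chrom"].astype(str) == str(chrom)]
        s, e = _body_bounds(grp)
        if pk.empty:
            cov = np.zeros(len(grp), dtype=np.int64)
        else:
            cov = covered_length(s, e, pk["start"].to_numpy(), pk["end"].to_numpy())
        rates[genes.index.get_indexer(grp.index)] = cov / (e - s)
    out = genes[["gene_id"]].copy()
    out["overlap_rate"] = rates
    return out


def build_gene_summaries(
    methylome: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    peaks: pd.DataFrame | None = None,
    min_len: int = MIN_GENE_LENGTH,
) -> pd.DataFrame:
    """Join per-gene mCpH and mCAG means with FPKM and histone overlap rate."""
    all_cph = gene_body_methylation(methylome, genes, "all", min_len=min_len)
    all_cph = all_cph.rename(columns={"mean_level": "mean_mcph", "n_sites": "n_cph"})
    cag = gene_body_methylation(methylome, genes, "CAG", min_len=min_len)
    cag = cag.rename(columns={"mean_level": "mean_mcag", "n_sites": "n_cag"})[
        ["gene_id", "mean_mcag", "n_cag"]
    ]
    out = all_cph.merge(cag, on="gene_id", how="left")
    if expression is not None:
        out = out.merge(expression[["gene_id", "fpkm"]], on="gene_id", how="left")
    if peaks is not None:
        rates = histone_overlap_rate(genes[genes["length"] > min_len], peaks)
        out = out.merge(rates, on="gene_id", how="left")
    return out


def screen_genes(
    summaries: pd.DataFrame,
    mcag_cut: float = MCAG_CUT,
    overlap_cut: float = OVERLAP_CUT,
    min_len: int = MIN_GENE_LENGTH,
    excluded_prefixes: tuple[str, ...] = EXCLUDED_PREFIXES,
) -> tuple[pd.DataFrame, float]:
    """Genes with hyper-methylated CAGs on H3K36me3-covered bodies.

    Keeps genes with mean_mcag > mcag_cut, overlap_rate > overlap_cut,
    length > min_len and an id not starting with an excluded prefix
    (LOC/Rik placeholders by default). Also returns the empirical quantile
    of ``mcag_cut`` in the mean_mcag distribution, so the cut can be read as
    a "top x%" statement.
    """
    s = summaries.dropna(subset=["mean_mcag", "overlap_rate"])
    named = ~s["gene_id"].astype(str).str.startswith(tuple(excluded_prefixes))
    passing = (
        (s["mean_mcag"] > mcag_cut)
        & (s["overlap_rate"] > overlap_cut)
        & (s["length"] > min_len)
        & named
    )
    quantile = float((summaries["mean_mcag"].dropna() <= mcag_cut).mean())
    selected = s[passing].sort_values("mean_mcag", ascending=False).reset_index(drop=True)
    return selected, quantile
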