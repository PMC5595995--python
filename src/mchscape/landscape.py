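"""Genome-binned and distance-resolved mCpG/mCpH landscape analysis.

The genome is cut into fixed blocks (default 1 kb) carrying per-class,
per-strand mean methylation; distance profiles resolve CpH methylation as a
function of the signed, strand-oriented offset from anchor CpGs (negative =
5' of the anchor cytosine on the anchor's strand); autocorrelation of the
profiles detects short-range (8-10 bp) and nucleosome-scale (~180 bp)
periodicity; per-sample proximal pattern vectors feed hierarchical
clustering of methylomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._util import covered_length, expand_ranges, moving_average
from .calling import MCPG_LEVEL, UNMETH_CPG_LEVEL

logger = logging.getLogger(__name__)

_ANCHOR_CHUNK = 4096


# ---------------------------------------------------------------------------
# genome blocks

def bin_genome(methylome: pd.DataFrame, block_size: int = 1000) -> pd.DataFrame:
    """Per-block unweighted mean methylation by cytosine class and strand.

    Requires a methylome with a ``cclass`` column. Means are NaN where a
    block has no site of the class; counts are always present.
    """
    df = methylome[["chrom", "pos", "strand", "cclass", "level"]].copy()
    df["block"] = df["pos"].to_numpy() // block_size
    is_cpg = (df["cclass"] == "CpG").to_numpy()
    fwd = (df["strand"] == "+").to_numpy()

    count_name = {"mcpg": "n_cpg", "mcph": "n_cph"}

    def agg(mask, name):
        sub = df[mask]
        g = sub.groupby(["chrom", "block"], observed=True)["level"]
        out = g.agg(["mean", "size"])
        out.columns = [f"mean_{name}", count_name.get(name, f"n_{name}")]
        return out

    parts = [
        agg(is_cpg, "mcpg"),
        agg(~is_cpg, "mcph"),
        agg(is_cpg & fwd, "mcpg_fwd"),
        agg(is_cpg & ~fwd, "mcpg_rev"),
        agg(~is_cpg & fwd, "mcph_fwd"),
        agg(~is_cpg & ~fwd, "mcph_rev"),
    ]
    blocks = pd.concat(parts, axis=1)
    for c in blocks.columns:
        if c.startswith("n_"):
            blocks[c] = blocks[c].fillna(0).astype(np.int64)
    blocks = blocks.reset_index()
    blocks["start"] = blocks["block"] * block_size
    blocks["end"] = blocks["start"] + block_size
    return blocks.drop(columns="block").sort_values(["chrom", "start"]).reset_index(drop=True)


def block_correlation(
    blocks: pd.DataFrame, min_cpg: int = 10, min_cph: int = 10
) -> float:
    """Pearson correlation of (mean mCpG, mean mCpH) over well-populated blocks.

    Blocks qualify when they contain more than ``min_cpg`` CpGs and more than
    ``min_cph`` CpHs. Returns NaN when either vector is constant.
    """
    qual = blocks[(blocks["n_cpg"] > min_cpg) & (blocks["n_cph"] > min_cph)]
    qual = qual.dropna(subset=["mean_mcpg", "mean_mcph"])
    if len(qual) < 3:
        raise ValueError("insufficient blocks")
    x = qual["mean_mcpg"].to_numpy()
    y = qual["mean_mcph"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant block means; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def annotate_blocks_genic(
    blocks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_flank: int = 5000,
    min_overlap: int = 500,
) -> pd.DataFrame:
    """Label blocks promoter / intragenic / intergenic.

    Promoter = TSS +- ``promoter_flank``; intragenic = TSS..TTS; a block is
    assigned to a genic category when more than ``min_overlap`` bp of it is
    covered (promoter checked first), else intergenic.
    """
    out = blocks.copy()
    out["region"] = "intergenic"
    for chrom, grp in out.groupby("chrom", observed=True):
        g = genes[genes["chrom"].astype(str) == str(chrom)]
        if g.empty:
            continue
        body_s = np.minimum(g["tss"], g["tts"]).to_numpy()
        body_e = np.maximum(g["tss"], g["tts"]).to_numpy()
        prom_s = np.maximum(g["tss"].to_numpy() - promoter_flank, 0)
        prom_e = g["tss"].to_numpy() + promoter_flank
        qs, qe = grp["start"].to_numpy(), grp["end"].to_numpy()
        prom_cov = covered_length(qs, qe, prom_s, prom_e)
        body_cov = covered_length(qs, qe, body_s, body_e)
        lab = np.where(prom_cov > min_overlap, "promoter",
                       np.where(body_cov > min_overlap, "intragenic", "intergenic"))
        out.loc[grp.index, "region"] = lab
    return out


def hemi_strand_analysis(blocks: pd.DataFrame, diff_cut: float = 0.5) -> dict:
    """Cis vs trans mCpH in blocks whose CpG methylation is hemi (strand-biased).

    Over blocks with |mean mCpG(+)-mean mCpG(-)| > ``diff_cut``, pairs the
    mean CpH level on the higher-mCpG strand (cis) with the other strand
    (trans) and tests the paired difference with a Wilcoxon signed-rank test.
    """
    need = ["mean_mcpg_fwd", "mean_mcpg_rev", "mean_mcph_fwd", "mean_mcph_rev"]
    q = blocks.dropna(subset=need)
    diff = q["mean_mcpg_fwd"] - q["mean_mcpg_rev"]
    q = q[diff.abs() > diff_cut]
    if q.empty:
        raise ValueError("no hemi-methylated blocks")
    fwd_high = (q["mean_mcpg_fwd"] > q["mean_mcpg_rev"]).to_numpy()
    cis = np.where(fwd_high, q["mean_mcph_fwd"], q["mean_mcph_rev"])
    trans = np.where(fwd_high, q["mean_mcph_rev"], q["mean_mcph_fwd"])
    d = cis - trans
    if np.allclose(d, 0):
        pvalue = 1.0
    else:
        pvalue = float(stats.wilcoxon(cis, trans).pvalue)
    return {
        "cis_mean": float(np.mean(cis)),
        "trans_mean": float(np.mean(trans)),
        "pvalue": pvalue,
        "n_blocks": int(len(q)),
    }


# ---------------------------------------------------------------------------
# distance profiles

def _split_anchor_sites(methylome: pd.DataFrame, anchor_condition: str):
    cpg = methylome[methylome["cclass"] == "CpG"]
    if anchor_condition == "methylated":
        return cpg[cpg["level"] >= MCPG_LEVEL]
    if anchor_condition == "unmethylated":
        return cpg[cpg["level"] < UNMETH_CPG_LEVEL]
    raise ValueError(f"unknown anchor condition: {anchor_condition!r}")


def _iter_window_pairs(anchors: pd.DataFrame, targets: pd.DataFrame, radius: int):
    """Yield (anchor rows, target rows, signed strand-oriented offsets) per chunk."""
    for chrom in anchors["chrom"].astype(str).unique():
        a = anchors[anchors["chrom"].astype(str) == chrom]
        t = targets[targets["chrom"].astype(str) == chrom]
        if a.empty or t.empty:
            continue
        t = t.sort_values("pos")
        tpos = t["pos"].to_numpy()
        apos = a["pos"].to_numpy()
        arev = (a["strand"].to_numpy() == "-")
        for c0 in range(0, len(a), _ANCHOR_CHUNK):
            asub = slice(c0, c0 + _ANCHOR_CHUNK)
            ap, ar = apos[asub], arev[asub]
            lo = np.searchsorted(tpos, ap - radius, side="left")
            hi = np.searchsorted(tpos, ap + radius + 1, side="left")
            owner, flat = expand_ranges(lo, hi)
            if flat.size == 0:
                continue
            off = tpos[flat] - ap[owner]
            off[ar[owner]] *= -1
            yield a.iloc[asub], a.index[asub], owner, t.iloc[flat], off


@dataclass
class DistanceProfile:
    anchor_condition: str
    mode: str            # "probability" or "level"
    radius: int
    binwidth: int
    table: pd.DataFrame  # columns: offset, value, n
    n_anchors: int = 0

    @property
    def offsets(self) -> np.ndarray:
        return self.table["offset"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy()


def distance_probability_profile(
    methylome: pd.DataFrame,
    radius: int = 500,
    binwidth: int = 10,
    anchor_condition: str = "methylated",
    min_mcph_per_block: int = 1,
) -> DistanceProfile:
    """Probability that a 10-bp offset block around an anchor CpG holds a called mCpH.

    Anchors are CpGs in the given level condition (methylated >= 0.8,
    unmethylated < 0.2); mCpHs are binomially *called* CpH sites (the
    ``called`` column), both strands. For each offset block the value is the
    fraction of anchor windows whose block contains >= ``min_mcph_per_block``
    called mCpHs.
    """
    if "called" not in methylome:
        raise ValueError("methylome must carry binomial calls (run call_methylated)")
    anchors = _split_anchor_sites(methylome, anchor_condition)
    mcph = methylome[(methylome["cclass"] == "CpH") & methylome["called"]]
    nbins = (2 * radius) // binwidth + 1
    hits = np.zeros(nbins, dtype=np.int64)
    n_anchors = len(anchors)
    if n_anchors == 0:
        warnings.warn(f"no anchors in condition {anchor_condition!r}", stacklevel=2)
        table = pd.DataFrame({"offset": [], "value": [], "n": []})
        return DistanceProfile(anchor_condition, "probability", radius, binwidth, table, 0)

    anchor_base = 0
    for a_rows, _, owner, t_rows, off in _iter_window_pairs(anchors, mcph, radius):
        bins = (off + radius) // binwidth
        pair_key = (anchor_base + owner) * nbins + bins
        if min_mcph_per_block <= 1:
            uniq = np.unique(pair_key)
        else:
            uniq, counts = np.unique(pair_key, return_counts=True)
            uniq = uniq[counts >= min_mcph_per_block]
        hits += np.bincount(uniq % nbins, minlength=nbins)
        anchor_base += len(a_rows)

    offs = np.arange(nbins) * binwidth - radius
    table = pd.DataFrame({"offset": offs, "value": hits / n_anchors, "n": hits})
    return DistanceProfile(anchor_condition, "probability", radius, binwidth, table, n_anchors)


def distance_level_profile(
    methylome: pd.DataFrame,
    radius: int = 500,
    anchor_condition: str = "methylated",
    same_strand_only: bool = True,
) -> DistanceProfile:
    """Per-bp mean CpH methylation level at each signed offset from anchor CpGs.

    Offsets are oriented 5'->3' on the anchor's strand. By default only CpHs
    on the anchor's strand contribute (a strand-agnostic convention would
    cancel the asymmetric -4 bp peak); pass same_strand_only=False to pool
    both strands.
    """
    anchors = _split_anchor_sites(methylome, anchor_condition)
    cph = methylome[methylome["cclass"] == "CpH"]
    width = 2 * radius + 1
    sums = np.zeros(width)
    counts = np.zeros(width, dtype=np.int64)
    for a_rows, _, owner, t_rows, off in _iter_window_pairs(anchors, cph, radius):
        lv = t_rows["level"].to_numpy()
        if same_strand_only:
            same = t_rows["strand"].to_numpy() == a_rows["strand"].to_numpy()[owner]
            off, lv = off[same], lv[same]
        idx = off + radius
        sums += np.bincount(idx, weights=lv, minlength=width)
        counts += np.bincount(idx, minlength=width)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame({"offset": np.arange(-radius, radius + 1), "value": mean, "n": counts})
    return DistanceProfile(anchor_condition, "level", radius, 1, table, len(anchors))


def sliding_window_profile(profile: DistanceProfile, window: int = 10) -> DistanceProfile:
    """Centered moving-average smoothing of a profile (truncated at the edges).

    Even windows are widened to the next odd size so the average is centered.
    """
    w = window if window % 2 == 1 else window + 1
    smoothed = moving_average(profile.values, w)
    table = profile.table.copy()
    table["value"] = smoothed
    return DistanceProfile(
        profile.anchor_condition, profile.mode, profile.radius, profile.binwidth,
        table, profile.n_anchors,
    )


# ---------------------------------------------------------------------------
# correlation vs distance and kernel width recovery

def distance_correlation_profile(
    methylome: pd.DataFrame,
    radius: int = 300,
    pairing: str = "nearest",
    same_strand_only: bool = True,
) -> pd.DataFrame:
    """Per-offset association between anchor mCpG level and CpH level.

    For each signed strand-oriented offset, computes over (anchor, CpH) pairs
    the Pearson correlation and the covariance of (anchor level, CpH level).
    ``pairing="nearest"`` pairs each CpH with its nearest methylated-CpG
    anchor only (matching a nearest-anchor deposition model, free of
    multi-anchor attenuation); ``pairing="window"`` pairs all anchors within
    the radius.
    """
    anchors = _split_anchor_sites(methylome, "methylated")
    cph = methylome[methylome["cclass"] == "CpH"]
    width = 2 * radius + 1
    n = np.zeros(width, dtype=np.int64)
    sx = np.zeros(width)
    sy = np.zeros(width)
    sxx = np.zeros(width)
    syy = np.zeros(width)
    sxy = np.zeros(width)

    def accumulate(off, alev, clev):
        idx = off + radius
        np.add.at(n, idx, 1)
        np.add.at(sx, idx, alev)
        np.add.at(sy, idx, clev)
        np.add.at(sxx, idx, alev * alev)
        np.add.at(syy, idx, clev * clev)
        np.add.at(sxy, idx, alev * clev)

    if pairing == "nearest":
        for chrom in anchors["chrom"].astype(str).unique():
            a = anchors[anchors["chrom"].astype(str) == chrom].sort_values("pos")
            t = cph[cph["chrom"].astype(str) == chrom]
            if a.empty or t.empty:
                continue
            apos = a["pos"].to_numpy()
            arev = a["strand"].to_numpy() == "-"
            alev = a["level"].to_numpy()
            tpos = t["pos"].to_numpy()
            right = np.searchsorted(apos, tpos)
            left = np.clip(right - 1, 0, apos.size - 1)
            right = np.clip(right, 0, apos.size - 1)
            use_right = np.abs(apos[right] - tpos) < np.abs(tpos - apos[left])
            nearest = np.where(use_right, right, left)
            off = tpos - apos[nearest]
            off[arev[nearest]] *= -1
            keep = np.abs(off) <= radius
            if same_strand_only:
                keep &= (t["strand"].to_numpy() == "-") == arev[nearest]
            accumulate(off[keep], alev[nearest][keep], t["level"].to_numpy()[keep])
    elif pairing == "window":
        for a_rows, _, owner, t_rows, off in _iter_window_pairs(anchors, cph, radius):
            alev = a_rows["level"].to_numpy()[owner]
            clev = t_rows["level"].to_numpy()
            if same_strand_only:
                same = t_rows["strand"].to_numpy() == a_rows["strand"].to_numpy()[owner]
                off, alev, clev = off[same], alev[same], clev[same]
            accumulate(off, alev, clev)
    else:
        raise ValueError(f"unknown pairing: {pairing!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        mx, my = sx / n, sy / n
        cov = sxy / n - mx * my
        vx = sxx / n - mx * mx
        vy = syy / n - my * my
        pcc = cov / np.sqrt(vx * vy)
    return pd.DataFrame(
        {"offset": np.arange(-radius, radius + 1), "n": n, "pcc": pcc, "cov": cov,
         "mean": my}
    )


def kernel_width_estimate(
    corr_profile: pd.DataFrame,
    smooth: int = 15,
    exclude_center: int = 8,
    column: str = "mean",
) -> float:
    """Half-maximum decay distance of the anchor-CpH coupling, in bp.

    Operates on the per-offset mean CpH level around nearest anchors by
    default (``column="mean"``; ``"cov"``/``"pcc"`` also accepted but carry
    far more sampling noise because methylated-CpG anchor levels vary
    little). Interpolates across a small central exclusion zone (which can
    carry localised motif spikes), smooths, folds the two signed sides,
    subtracts the far-tail baseline, and interpolates the first crossing of
    half the peak. Under a Gaussian-envelope deposition kernel whose
    half-max sits at the kernel width, the returned value estimates that
    width.
    """
    offs = corr_profile["offset"].to_numpy()
    vals = corr_profile[column].to_numpy().astype(float)
    good = np.isfinite(vals) & (np.abs(offs) > exclude_center)
    vals = np.interp(offs, offs[good], vals[good])
    vals = moving_average(vals, smooth if smooth % 2 else smooth + 1)

    radius = int(offs.max())
    # offsets are contiguous -radius..radius; average the two signed sides
    folded = 0.5 * (vals[radius:] + vals[radius::-1])
    baseline = np.nanmedian(folded[int(radius * 0.8):])
    search = folded - baseline
    peak = np.nanmax(search[exclude_center:])
    half = peak / 2.0
    below = np.flatnonzero((search < half) & (np.arange(folded.size) > exclude_center))
    if below.size == 0:
        return float(radius)
    i = below[0]
    # linear interpolation between the last point above and first below
    x0, x1 = i - 1, i
    y0, y1 = search[x0], search[x1]
    if y0 == y1:
        return float(i)
    return float(x0 + (y0 - half) / (y0 - y1))


# ---------------------------------------------------------------------------
# periodicity

def periodicity_score(
    values: np.ndarray,
    lag_range: tuple[int, int] = (5, 15),
    n_permutations: int = 0,
    seed=0,
) -> dict:
    """Autocorrelation peak of a (mean-detrended) profile over a lag range.

    Returns {"best_lag", "score", "null_95"}; ``null_95`` is the 95th
    percentile of the max score over ``n_permutations`` circular shifts
    (NaN when 0 permutations are requested).
    """
    x = np.asarray(values, dtype=float)
    good = np.isfinite(x)
    if good.sum() < x.size:
        x = np.where(good, x, np.nanmean(x))
    lo, hi = lag_range
    if x.size < 2 * hi:
        raise ValueError("profile shorter than twice the maximum lag")
    x = x - x.mean()

    def _best(arr):
        denom = float(np.dot(arr, arr))
        if denom == 0:
            return lo, 0.0
        scores = [float(np.dot(arr[:-lag], arr[lag:])) / denom for lag in range(lo, hi + 1)]
        i = int(np.argmax(scores))
        return lo + i, scores[i]

    best_lag, score = _best(x)
    null_95 = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = _best(np.roll(x, rng.integers(1, x.size)))[1]
        null_95 = float(np.percentile(null, 95))
    return {"best_lag": int(best_lag), "score": float(score), "null_95": null_95}


# ---------------------------------------------------------------------------
# multi-sample proximal pattern clustering

@dataclass
class PatternClustering:
    vectors: pd.DataFrame       # offsets/blocks x samples
    pcc: pd.DataFrame           # samples x samples
    linkage: np.ndarray
    order: list
    newick: str

    def cut(self, n_clusters: int) -> dict:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.pcc.index, labels))


def proximal_pattern_matrix(
    samples: dict[str, pd.DataFrame],
    radius: int = 100,
    mode: str = "proximal",
    block_size: int = 1000,
    linkage_method: str = "average",
) -> PatternClustering:
    """Pairwise PCC and hierarchical clustering of per-sample methylation patterns.

    ``mode="proximal"``: each sample is summarised by its mCpG-proximal
    (+-radius bp) per-offset mean mCpH level vector. ``mode="blocks"``: the
    per-block mean CpH level vector (1 kb by default), for genome-wide sample
    clustering. Distance is 1 - PCC with average linkage by default.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    cols = {}
    for sid, meth in samples.items():
        if mode == "proximal":
            prof = distance_level_profile(meth, radius=radius)
            cols[sid] = pd.Series(prof.values, index=prof.offsets)
        elif mode == "blocks":
            blk = bin_genome(meth, block_size=block_size)
            idx = pd.MultiIndex.from_frame(blk[["chrom", "start"]].astype({"chrom": str}))
            cols[sid] = pd.Series(blk["mean_mcph"].to_numpy(), index=idx)
        else:
            raise ValueError(f"unknown mode: {mode!r}")
    vectors = pd.DataFrame(cols).dropna()
    ids = list(vectors.columns)
    mat = vectors.to_numpy()
    with np.errstate(invalid="ignore"):
        pcc = np.corrcoef(mat.T)
    if np.isnan(pcc).any():
        warnings.warn("constant pattern vector: NaN correlations present", stacklevel=2)
    pcc_df = pd.DataFrame(pcc, index=ids, columns=ids)
    dist = 1.0 - pcc
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(ids), k=1)]
    Z = hierarchy.linkage(condensed, method=linkage_method)
    order = [ids[i] for i in hierarchy.leaves_list(Z)]
    newick = _linkage_to_newick(Z, ids)
    return PatternClustering(vectors, pcc_df, Z, order, newick)


def _linkage_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, ids)
    return str(tree).strip()
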