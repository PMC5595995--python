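"""Methylation-level integration and binomial methylation calling.

Integration pools reads across aligners as a read-depth weighted average,

    Me_i = (sum_j M_ij) / (sum_j t_ij) - non_conversion_rate,

clamped at 0, where t_ij / M_ij are the total / unconverted read counts of
aligner j at cytosine i and the non-conversion rate is the fraction of
unmethylated cytosines that escape bisulfite conversion.

A cytosine is *called* methylated when the upper-tail binomial probability
Pr(X >= k_i), X ~ Binomial(n_i, p) with p the non-conversion rate, falls
below a p-value threshold. The threshold is calibrated against an artificial
null methylome with identical per-site depths and simulated counts
k* ~ Binomial(n_i, p): FDR(t) = null calls / real calls, and the chosen
threshold is the largest t with FDR(t) below the target (default 0.01).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import _factorize_sites

logger = logging.getLogger(__name__)

# status cutoffs used downstream (levels, not calls)
MCPG_LEVEL = 0.8            #: CpG counted as methylated when level >= 0.8
UNMETH_CPG_LEVEL = 0.2      #: CpG counted as unmethylated when level < 0.2
HYPER_MCPH_LEVEL = 0.5      #: CpH counted as hyper-methylated when level > 0.5
DEFAULT_PVALUE_THRESHOLD = 1e-5
DEFAULT_FDR_TARGET = 0.01


@dataclass
class IntegrationConfig:
    """Non-conversion rate and clamping behaviour for level integration."""

    non_conversion_rate: float = 0.005
    clamp_negative: bool = True

    def __post_init__(self):
        if not 0 <= self.non_conversion_rate < 0.1:
            raise ValueError("non_conversion_rate must be in [0, 0.1)")
        if self.non_conversion_rate > 0.05:
            warnings.warn("non-conversion rate above 0.05 is suspicious", stacklevel=2)


def integrate_methylation(
    table: pd.DataFrame,
    cfg: IntegrationConfig,
    context_index: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pool a multi-aligner count table into one integrated record per site.

    Returns a methylome DataFrame (chrom, pos, strand, level, depth, meth,
    n_aligners, plus cclass/trinuc/symclass when a context index is given).
    Sites with zero pooled depth are skipped with a warning.
    """
    if table.empty:
        raise ValueError("empty multi-aligner table")
    key, uniq = _factorize_sites(table)
    n_sites = len(uniq)
    depth = np.bincount(key, weights=table["total"].to_numpy(), minlength=n_sites).astype(np.int64)
    meth = np.bincount(key, weights=table["meth"].to_numpy(), minlength=n_sites).astype(np.int64)
    nalg = np.bincount(key[table["total"].to_numpy() > 0], minlength=n_sites)

    nonzero = depth > 0
    if (~nonzero).any():
        logger.warning("%d sites with zero pooled depth skipped", int((~nonzero).sum()))

    with np.errstate(invalid="ignore", divide="ignore"):
        level = meth / np.where(depth == 0, 1, depth) - cfg.non_conversion_rate
    if cfg.clamp_negative:
        level = np.maximum(level, 0.0)

    res = pd.DataFrame(
        {
            "chrom": pd.Categorical(uniq.get_level_values(0)[nonzero]),
            "pos": uniq.get_level_values(1).to_numpy()[nonzero],
            "strand": uniq.get_level_values(2)[nonzero],
            "level": level[nonzero],
            "depth": depth[nonzero],
            "meth": meth[nonzero],
            "n_aligners": nalg[nonzero],
        }
    )
    if context_index is not None:
        ctx = context_index[["chrom", "pos", "strand", "cclass", "trinuc", "symclass"]].astype(
            {"chrom": str, "strand": str}
        )
        res = res.astype({"chrom": str, "strand": str}).merge(
            ctx, on=["chrom", "pos", "strand"], how="left"
        )
        res["chrom"] = pd.Categorical(res["chrom"])
        res["strand"] = res["strand"].astype(pd.CategoricalDtype(["+", "-"]))
    return res


def binom_pvalue(k, n, p) -> np.ndarray | float:
    """Upper-tail binomial probability Pr(X >= k), X ~ Binomial(n, p)."""
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p < 1):
        raise ValueError("require 0 < p < 1")
    out = stats.binom.sf(k - 1, n, p)
    return float(out) if out.ndim == 0 else out


def call_methylated(
    methylome: pd.DataFrame,
    cfg: IntegrationConfig,
    threshold: float = DEFAULT_PVALUE_THRESHOLD,
) -> pd.DataFrame:
    """Binomial methylation calls on the raw pooled counts (meth, depth).

    Adds ``pvalue`` and ``called`` columns; called iff pvalue < threshold
    (strict). The test uses the pooled counts, not the subtracted level.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    out = methylome.copy()
    out["pvalue"] = binom_pvalue(
        out["meth"].to_numpy(), out["depth"].to_numpy(), cfg.non_conversion_rate
    )
    out["called"] = out["pvalue"] < threshold
    return out


def simulate_artificial_methylome(depths: np.ndarray, p: float, seed) -> np.ndarray:
    """Simulated null methylated-read counts k* ~ Binomial(depth, p) per site.

    ``seed`` may be an int or a numpy Generator/SeedSequence.
    """
    rng = np.random.default_rng(seed)
    depths = np.asarray(depths, dtype=np.int64)
    return rng.binomial(depths, p)


@dataclass
class FdrCalibration:
    thresholds: np.ndarray
    real_calls: np.ndarray
    null_calls: np.ndarray
    fdr: np.ndarray
    chosen_threshold: float | None
    seed: object = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "real_calls": self.real_calls,
                "null_calls": self.null_calls,
                "fdr": self.fdr,
            }
        )


def calibrate_fdr(
    methylome: pd.DataFrame,
    p: float,
    fdr_target: float = DEFAULT_FDR_TARGET,
    thresholds=None,
    seed=0,
    n_replicates: int = 1,
) -> FdrCalibration:
    """Artificial-methylome FDR curve and threshold choice.

    An artificial methylome with the real per-site depths and null counts
    k* ~ Binomial(depth, p) is called at each threshold of a descending grid
    (default 1e-2 .. 1e-8); FDR(t) = null calls / real calls (NaN when there
    are no real calls). ``chosen_threshold`` is the largest t with
    FDR(t) < fdr_target, or None if no threshold achieves it. With
    n_replicates > 1 the null call counts are averaged over replicates.
    """
    if thresholds is None:
        thresholds = np.logspace(-2, -8, 7)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) >= 0):
        raise ValueError("threshold grid must be strictly descending")

    depths = methylome["depth"].to_numpy()
    real_pv = binom_pvalue(methylome["meth"].to_numpy(), depths, p)
    rng = np.random.default_rng(seed)
    null_counts = np.zeros(thresholds.size)
    for _ in range(n_replicates):
        k_null = simulate_artificial_methylome(depths, p, rng)
        null_pv = binom_pvalue(k_null, depths, p)
        null_counts += np.array([(null_pv < t).sum() for t in thresholds])
    null_counts /= n_replicates
    real_counts = np.array([(real_pv < t).sum() for t in thresholds], dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(real_counts > 0, null_counts / real_counts, np.nan)
    achieves = (real_counts > 0) & (fdr < fdr_target)
    chosen = float(thresholds[np.argmax(achieves)]) if achieves.any() else None
    return FdrCalibration(thresholds, real_counts, null_counts, fdr, chosen, seed=seed)


def estimate_non_conversion(
    table_or_methylome: pd.DataFrame, control_contig: str
) -> float:
    """Mean raw M/t over a designated fully-unmethylated control contig."""
    sub = table_or_methylome[table_or_methylome["chrom"].astype(str) == control_contig]
    if sub.empty:
        raise ValueError(f"no sites on control contig {control_contig!r}")
    t = sub["depth"] if "depth" in sub else sub["total"]
    m = sub["meth"]
    tot = float(t.sum())
    if tot == 0:
        raise ValueError("control contig has zero depth")
    return float(m.sum()) / tot
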