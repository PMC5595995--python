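"""Synthetic WGBS data generator with the statistical structure the analysis assumes.

The generator emulates, per cell-type mode, the joint structure the pipeline
is built to detect:

* bimodal CpG methylation (a high component near 0.9, a low one near 0.05),
  with optional regionally coordinated hemi-methylation (one strand high);
* CpH methylation deposited as a decaying kernel of the distance to the
  *nearest* methylated CpG, scaled by a trinucleotide context weight, a
  cis/trans strand factor, and (inside gene bodies) a per-gene multiplier;
* mode-specific kernel shape: an ESC-like localized boost at -4 bp, a
  neuron-like 8-10 bp cosine modulation, a DNMT1-KO-like nucleosome-scale
  (180 bp) modulation over sparse anchors;
* mode-specific context weights (CAG-centric for ESC / DNMT3b activity,
  CAC-centric for neuron / DNMT3a activity);
* read counts: Poisson depth, binomial non-conversion noise, multinomial
  splits across up to three aligners with mild dropout;
* log-normal expression coupled to H3K36me3-like peak coverage, which in
  turn drives gene-body CpH deposition, so methylation correlates more
  strongly with peak overlap than with expression itself.

The genome is i.i.d. bases at the configured GC content with CpG dinucleotides
thinned to a mammalian-like observed/expected ratio; without the thinning,
methylated-CpG anchors would be so dense that their coupling halos overlap
and the distance structure would be invisible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import codes_to_seq
from .calling import MCPG_LEVEL
from .reference import classify_cytosines, write_fasta

MODES = ("esc", "neuron", "somatic", "d1ko", "d3ko", "d3bko", "setd2ko")

_LN2 = float(np.log(2.0))


@dataclass
class SimulationConfig:
    """All knobs of the generator; mode presets via :meth:`for_mode`."""

    mode: str = "esc"
    seed: int = 0
    # genome
    genome_length: int = 2_000_000
    gc_content: float = 0.42
    cpg_keep_prob: float = 0.12        # CpG observed/expected after thinning
    control_contig_length: int = 20_000  # fully unmethylated spike-in contig
    # genes
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (1000, 20_000)
    # CpG methylation
    mcpg_high_fraction: float = 0.75
    hemi_region_fraction: float = 0.08
    cpg_high_beta: tuple[float, float] = (20.0, 2.0)
    cpg_low_beta: tuple[float, float] = (1.5, 28.0)
    # CpH deposition kernel
    background_cph: float = 0.02
    coupling_amplitude: float = 0.75
    kernel_width: float = 100.0
    peak_offset: int | None = -4       # ESC-like localized boost
    peak_boost: float = 3.0
    peak_sigma: float = 1.0
    period: float | None = None        # neuron-like short periodicity (bp)
    period_mod: float = 0.7
    nucleosome_period: float | None = None  # D1-KO-like long periodicity (bp)
    nucleosome_mod: float = 0.7
    trans_factor: float = 0.3          # kernel scale on the non-anchor strand
    background_shape: float = 2.0      # Gamma shape of the per-site background
    context_weights: dict = field(
        default_factory=lambda: {"CAG": 1.0, "CAA": 0.4, "CAC": 0.25, "CAT": 0.2, "other": 0.1}
    )
    # sequencing
    ncr: float = 0.005
    depth_mean: float = 15.0
    n_aligners: int = 3
    aligner_weights: tuple[float, ...] = (0.4, 0.35, 0.25)
    aligner_dropout: float = 0.05
    # expression / histone coupling
    expression_coupling: float = 0.4   # target Spearman rho(gene mCpH, FPKM)
    overlap_link: float = 0.7          # latent corr(expression, peak coverage)
    peak_scale: float = 1.0            # overall H3K36me3 coverage scale
    fpkm_log_mean: float = 1.0
    fpkm_log_sd: float = 1.5
    gene_mult_sd: float = 0.6

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.ncr < 1:
            raise ValueError("ncr must be in [0, 1)")

    @classmethod
    def for_mode(cls, mode: str, seed: int = 0, **overrides) -> "SimulationConfig":
        presets = {
            "esc": {},
            "neuron": {
                "context_weights": {"CAC": 1.0, "CAT": 0.3, "CAG": 0.25, "CAA": 0.2, "other": 0.1},
                "peak_offset": None,
                "period": 9.0,
                "expression_coupling": -0.3,
            },
            "somatic": {
                "coupling_amplitude": 0.08,
                "background_cph": 0.002,
                "peak_offset": None,
                "expression_coupling": 0.0,
            },
            "d1ko": {
                # DNMT1 loss removes maintenance methylation: sparse mCpG
                # anchors, wide halo with nucleosome-phased deposition
                "mcpg_high_fraction": 0.03,
                "kernel_width": 400.0,
                "peak_offset": None,
                "nucleosome_period": 180.0,
                "context_weights": {"CAG": 0.8, "CAC": 0.6, "CAA": 0.4, "CAT": 0.3, "other": 0.1},
                "expression_coupling": 0.2,
            },
            "d3ko": {
                "coupling_amplitude": 0.02,
                "background_cph": 0.002,
                "peak_offset": None,
                "expression_coupling": 0.0,
            },
            "d3bko": {
                # DNMT3b targets (CAG/CAA) suppressed; DNMT3a-like residue
                "context_weights": {"CAC": 1.0, "CAT": 0.3, "CAG": 0.1, "CAA": 0.08, "other": 0.1},
                "peak_offset": None,
                "period": 9.0,
                "expression_coupling": 0.0,
            },
            "setd2ko": {
                "expression_coupling": 0.0,
                "overlap_link": 0.0,
                "peak_scale": 0.05,
            },
        }
        kw = dict(presets[mode])
        kw.update(overrides)
        return cls(mode=mode, seed=seed, **kw)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    context: pd.DataFrame
    truth: pd.DataFrame                # context + true_m column
    genes: pd.DataFrame                # gene_id, chrom, strand, tss, tts, length,
    #                                    fpkm, overlap_rate, mult (planted values)
    expression: pd.DataFrame           # gene_id, fpkm
    peaks: pd.DataFrame                # chrom, start, end
    reports: dict[str, pd.DataFrame]   # aligner_id -> chrom,pos,strand,total,meth

    def multi_aligner_table(self) -> pd.DataFrame:
        parts = []
        for aid, df in self.reports.items():
            p = df.copy()
            p["aligner"] = aid
            parts.append(p)
        out = pd.concat(parts, ignore_index=True)
        out["chrom"] = pd.Categorical(out["chrom"])
        out["aligner"] = pd.Categorical(out["aligner"])
        out["strand"] = out["strand"].astype(pd.CategoricalDtype(["+", "-"]))
        return out[["chrom", "pos", "strand", "aligner", "total", "meth"]]


# ---------------------------------------------------------------------------
# genome + genes

def generate_genome(cfg: SimulationConfig, rng=None) -> tuple[dict[str, str], pd.DataFrame]:
    """Random CpG-depleted genome plus non-overlapping gene models."""
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    genome = {}
    for name, length in (("chr1", cfg.genome_length), ("chrCtrl", cfg.control_contig_length)):
        if length <= 0:
            continue
        at = (1.0 - cfg.gc_content) / 2.0
        gc = cfg.gc_content / 2.0
        codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.int8)
        cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
        kill = cg[rng.random(cg.size) > cfg.cpg_keep_prob]
        codes[kill] = 3  # C -> T removes the CpG
        genome[name] = codes_to_seq(codes)

    lo, hi = cfg.gene_length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes)).astype(np.int64)
    total = int(lengths.sum())
    slack = cfg.genome_length - total - 2000
    if slack < cfg.n_genes:
        raise ValueError("genes cannot be placed: genome too short for n_genes")
    gaps = rng.multinomial(slack, np.full(cfg.n_genes + 1, 1.0 / (cfg.n_genes + 1)))
    starts = 1000 + np.cumsum(gaps[:-1]) + np.concatenate(([0], np.cumsum(lengths[:-1])))
    ends = starts + lengths
    strand = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(cfg.n_genes)],
            "chrom": "chr1",
            "strand": strand,
            "tss": np.where(strand == "+", starts, ends),
            "tts": np.where(strand == "+", ends, starts),
            "length": lengths,
        }
    )
    return genome, genes


# ---------------------------------------------------------------------------
# expression, peaks, gene multipliers

def _gene_latents(cfg: SimulationConfig, n: int, rng) -> pd.DataFrame:
    """Latent Gaussian chain: expression -> peak coverage -> methylation boost.

    ``expression_coupling`` is the target Spearman rho between the per-gene
    methylation multiplier and FPKM; the copula correlation is back-computed
    through rho_s = (6/pi) asin(r/2) with a fixed 0.95 attenuation allowance
    for anchor-placement noise in finite gene bodies.
    """
    a = cfg.overlap_link
    rho_t = float(np.clip(cfg.expression_coupling, -0.9, 0.9))
    r_needed = 2.0 * np.sin(np.pi * (rho_t / 0.95) / 6.0)
    b = 0.0 if a == 0 else float(np.clip(r_needed / a, -0.99, 0.99))

    x = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    o_lat = a * x + np.sqrt(max(1 - a * a, 0.0)) * e1
    m_lat = b * o_lat + np.sqrt(max(1 - b * b, 0.0)) * e2
    fpkm = np.exp(cfg.fpkm_log_mean + cfg.fpkm_log_sd * x)
    overlap = cfg.peak_scale / (1.0 + np.exp(-1.2 * o_lat))
    mult = np.exp(cfg.gene_mult_sd * m_lat - 0.5 * cfg.gene_mult_sd**2)
    return pd.DataFrame({"fpkm": fpkm, "overlap_rate": overlap, "mult": mult})


def generate_expression_and_peaks(
    genes: pd.DataFrame, cfg: SimulationConfig, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """FPKM table, H3K36me3-like peak intervals, and annotated gene table.

    Peak intervals are placed inside each gene body as 1-3 disjoint pieces
    whose union covers exactly the planted overlap fraction.
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    lat = _gene_latents(cfg, len(genes), rng)
    genes = genes.reset_index(drop=True).join(lat)

    peak_rows = []
    for _, g in genes.iterrows():
        body_s = int(min(g["tss"], g["tts"]))
        body_e = int(max(g["tss"], g["tts"]))
        L = body_e - body_s
        covered = int(round(g["overlap_rate"] * L))
        if covered <= 0:
            continue
        n_pieces = min(int(rng.integers(1, 4)), max(covered // 50, 1))
        seg = L // n_pieces
        piece = covered // n_pieces
        extra = covered - piece * n_pieces
        for j in range(n_pieces):
            plen = piece + (extra if j == 0 else 0)
            plen = min(plen, seg)
            off = int(rng.integers(0, max(seg - plen, 0) + 1))
            s = body_s + j * seg + off
            peak_rows.append({"chrom": g["chrom"], "start": s, "end": s + plen})
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    expression = genes[["gene_id", "fpkm"]].copy()
    return expression, peaks, genes


# ---------------------------------------------------------------------------
# true methylome

def generate_true_methylome(
    genome: dict[str, str],
    genes: pd.DataFrame,
    cfg: SimulationConfig,
    rng=None,
    context: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site true methylation probabilities (context index + ``true_m``).

    ``genes`` must carry the planted ``mult`` column (from
    :func:`generate_expression_and_peaks`); pass ``mult`` = 1 genes for an
    uncoupled methylome.
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    if context is None:
        context = classify_cytosines(genome)
    truth = context.copy()
    truth["true_m"] = 0.0

    w = cfg.context_weights
    tri_w = np.array(
        [w.get(t, w.get("other", 0.0)) for t in truth["trinuc"].cat.categories]
    )

    for chrom in truth["chrom"].cat.categories:
        mask = truth["chrom"] == chrom
        sub = truth[mask]
        if str(chrom) == "chrCtrl":
            continue  # control contig stays fully unmethylated

        is_cpg = (sub["cclass"] == "CpG").to_numpy()
        pos = sub["pos"].to_numpy()
        rev = (sub["strand"] == "-").to_numpy()

        # --- CpG levels, dyad-coordinated, with hemi-methylated regions
        cpg_pos = pos[is_cpg]
        cpg_rev = rev[is_cpg]
        dyad = cpg_pos - cpg_rev.astype(np.int64)
        uniq_dyad, dyad_idx = np.unique(dyad, return_inverse=True)
        n_dyad = uniq_dyad.size
        high = rng.random(n_dyad) < cfg.mcpg_high_fraction
        hi_draw = rng.beta(*cfg.cpg_high_beta, size=n_dyad)
        lo_draw = rng.beta(*cfg.cpg_low_beta, size=n_dyad)
        base_level = np.where(high, hi_draw, lo_draw)

        n_regions = int(pos.max() // 1000) + 1 if pos.size else 1
        hemi_region = rng.random(n_regions) < cfg.hemi_region_fraction
        hemi_fwd = rng.random(n_regions) < 0.5
        dyad_region = (uniq_dyad // 1000).astype(np.int64)
        dyad_hemi = hemi_region[dyad_region]
        dyad_fav_fwd = hemi_fwd[dyad_region]

        lvl_fwd = np.where(dyad_hemi, np.where(dyad_fav_fwd, hi_draw, lo_draw), base_level)
        lvl_rev = np.where(dyad_hemi, np.where(dyad_fav_fwd, lo_draw, hi_draw), base_level)
        cpg_level = np.where(cpg_rev, lvl_rev[dyad_idx], lvl_fwd[dyad_idx])

        # --- CpH deposition from the nearest methylated-CpG anchor
        anch = cpg_level >= MCPG_LEVEL
        apos = cpg_pos[anch]
        arev = cpg_rev[anch]
        alev = cpg_level[anch]
        cph_pos = pos[~is_cpg]
        cph_rev = rev[~is_cpg]
        if apos.size and cph_pos.size:
            order = np.argsort(apos, kind="stable")
            apos, arev, alev = apos[order], arev[order], alev[order]
            right = np.searchsorted(apos, cph_pos)
            left = np.clip(right - 1, 0, apos.size - 1)
            right = np.clip(right, 0, apos.size - 1)
            use_right = np.abs(apos[right] - cph_pos) < np.abs(cph_pos - apos[left])
            nearest = np.where(use_right, right, left)
            off = (cph_pos - apos[nearest]).astype(float)
            off[arev[nearest]] *= -1
            kern = np.exp(-_LN2 * (off / cfg.kernel_width) ** 2)
            if cfg.peak_offset is not None:
                kern *= 1.0 + cfg.peak_boost * np.exp(
                    -((off - cfg.peak_offset) ** 2) / (2.0 * cfg.peak_sigma**2)
                )
            if cfg.period is not None:
                kern *= 1.0 + cfg.period_mod * np.cos(2.0 * np.pi * off / cfg.period)
            if cfg.nucleosome_period is not None:
                kern *= 1.0 + cfg.nucleosome_mod * np.cos(
                    2.0 * np.pi * off / cfg.nucleosome_period
                )
            strand_f = np.where(cph_rev == arev[nearest], 1.0, cfg.trans_factor)
            wts = tri_w[sub["trinuc"].cat.codes.to_numpy()[~is_cpg]]
            signal = cfg.coupling_amplitude * kern * strand_f * wts * alev[nearest]
        else:
            signal = np.zeros(cph_pos.size)

        # per-gene multiplier inside gene bodies
        g = genes[genes["chrom"].astype(str) == str(chrom)]
        mult = np.ones(cph_pos.size)
        if len(g) and "mult" in g:
            gs = np.minimum(g["tss"], g["tts"]).to_numpy()
            ge = np.maximum(g["tss"], g["tts"]).to_numpy()
            gm = g["mult"].to_numpy()
            order = np.argsort(gs)
            gs, ge, gm = gs[order], ge[order], gm[order]
            gi = np.searchsorted(gs, cph_pos, side="right") - 1
            inside = (gi >= 0) & (cph_pos < ge[np.clip(gi, 0, None)])
            mult[inside] = gm[gi[inside]]

        # nonnegative per-site background: Gamma keeps true levels in [0, 1]
        # without lower clipping, so covariance with anchor levels stays
        # proportional to the deposition kernel
        bg = rng.gamma(cfg.background_shape, cfg.background_cph / cfg.background_shape,
                       size=cph_pos.size)
        cph_m = np.minimum(bg + signal * mult, 1.0)

        vals = np.empty(len(sub))
        vals[is_cpg] = cpg_level
        vals[~is_cpg] = cph_m
        truth.loc[mask, "true_m"] = vals
    return truth


# ---------------------------------------------------------------------------
# read counts

def generate_counts(
    truth: pd.DataFrame, cfg: SimulationConfig, rng=None
) -> dict[str, pd.DataFrame]:
    """Per-aligner cytosine count tables from the true methylome.

    Per site: n ~ Poisson(depth_mean); methylated reads
    k ~ Binomial(n, m + (1-m) * ncr); n split multinomially across aligners
    with mild dropout, and k partitioned hypergeometrically consistent with
    the split. Rows with zero reads for an aligner are omitted from that
    aligner's table.
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    m = truth["true_m"].to_numpy()
    n_sites = m.size
    n = rng.poisson(cfg.depth_mean, size=n_sites)
    p_obs = m + (1.0 - m) * cfg.ncr
    k = rng.binomial(n, p_obs)

    weights = np.asarray(cfg.aligner_weights[: cfg.n_aligners], dtype=float)
    weights = weights / weights.sum()
    keep = rng.random((n_sites, cfg.n_aligners)) >= cfg.aligner_dropout
    keep[~keep.any(axis=1), 0] = True
    eff = weights[None, :] * keep
    eff = eff / eff.sum(axis=1, keepdims=True)

    reports = {}
    n_left = n.copy()
    k_left = k.copy()
    w_left = np.ones(n_sites)
    for j in range(cfg.n_aligners):
        if j < cfg.n_aligners - 1:
            frac = np.divide(eff[:, j], w_left, out=np.zeros(n_sites), where=w_left > 0)
            nj = rng.binomial(n_left, np.clip(frac, 0.0, 1.0))
        else:
            nj = n_left
        ngood = np.maximum(k_left, 0)
        nbad = np.maximum(n_left - k_left, 0) + (n_left == 0)  # keep pop size >= 1
        kj = rng.hypergeometric(ngood, nbad, np.maximum(nj, 1))
        kj = np.where(nj > 0, kj, 0)
        sel = nj > 0
        reports[f"aligner{j + 1}"] = pd.DataFrame(
            {
                "chrom": truth["chrom"].astype(str).to_numpy()[sel],
                "pos": truth["pos"].to_numpy()[sel],
                "strand": truth["strand"].astype(str).to_numpy()[sel],
                "total": nj[sel].astype(np.int64),
                "meth": kj[sel].astype(np.int64),
            }
        )
        n_left = n_left - nj
        k_left = k_left - kj
        w_left = w_left - eff[:, j]
    return reports


# ---------------------------------------------------------------------------
# orchestration

def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Run the full generator with stage-wise independent seed streams."""
    ss = np.random.SeedSequence(cfg.seed)
    r_genome, r_expr, r_meth, r_counts = [np.random.default_rng(s) for s in ss.spawn(4)]
    genome, genes = generate_genome(cfg, r_genome)
    expression, peaks, genes = generate_expression_and_peaks(genes, cfg, r_expr)
    context = classify_cytosines(genome)
    truth = generate_true_methylome(genome, genes, cfg, r_meth, context=context)
    reports = generate_counts(truth, cfg, r_counts)
    return SyntheticDataset(cfg, genome, context, truth, genes, expression, peaks, reports)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write a dataset to disk (FASTA, generic-dialect reports, tables)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    write_fasta(ds.genome, out / "genome.fa")
    manifest["genome"] = "genome.fa"
    for aid, df in ds.reports.items():
        rep = df.copy()
        rep["pos"] = rep["pos"] + 1
        path = out / f"{aid}.tsv.gz"
        rep[["chrom", "pos", "strand", "total", "meth"]].to_csv(
            path, sep="\t", header=False, index=False,
            compression={"method": "gzip", "mtime": 0},
        )
        manifest[aid] = path.name
    ds.genes[["gene_id", "chrom", "strand", "tss", "tts", "length"]].to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    ds.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    ds.peaks.to_csv(out / "peaks.bed", sep="\t", header=False, index=False)
    tr = ds.truth.copy()
    tr["pos"] = tr["pos"] + 1
    tr.to_csv(out / "truth.tsv.gz", sep="\t", index=False,
              compression={"method": "gzip", "mtime": 0})
    manifest.update(genes="genes.tsv", expression="expression.tsv",
                    peaks="peaks.bed", truth="truth.tsv.gz")
    return manifest


# ---------------------------------------------------------------------------
# light-weight site-level simulator for FDR calibration experiments

def simulate_call_truth(
    n_sites: int,
    frac_methylated: float = 0.02,
    depth_mean: float = 15.0,
    ncr: float = 0.005,
    level_range: tuple[float, float] = (0.3, 0.9),
    seed=0,
) -> pd.DataFrame:
    """Flat site table for calling/FDR experiments (no genome needed).

    A planted fraction of sites is truly methylated with levels uniform in
    ``level_range``; the rest are unmethylated and only non-conversion noise
    produces methylated reads. Returns chrom/pos/strand/meth/depth/level
    plus the ``true_methylated`` indicator.
    """
    rng = np.random.default_rng(seed)
    depth = rng.poisson(depth_mean, size=n_sites)
    truth = rng.random(n_sites) < frac_methylated
    m = np.where(truth, rng.uniform(*level_range, size=n_sites), 0.0)
    k = rng.binomial(depth, m + (1 - m) * ncr)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.clip(k / np.maximum(depth, 1) - ncr, 0, 1)
    return pd.DataFrame(
        {
            "chrom": "sim",
            "pos": np.arange(n_sites),
            "strand": "+",
            "meth": k,
            "depth": depth,
            "level": level,
            "true_methylated": truth,
        }
    )
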