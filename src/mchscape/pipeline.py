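"""End-to-end orchestration: call -> landscape -> context -> genes.

A :class:`RunConfig` (plain YAML, every threshold dumped with its default so
runs are auditable) drives the stages in dependency order; every output file
is listed in a machine-readable manifest together with input hashes and the
effective configuration, and reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, context_motif, genes as gene_mod, io as mio, landscape, reference

logger = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    sample_id: str
    reports: list
    dialects: list
    ncr: float = 0.005


@dataclass
class Thresholds:
    """Analysis thresholds; defaults are the published operating points."""

    min_depth: int = 5            # sites covered by >= 5 pooled reads
    min_aligners: int = 2         # ... from >= 2 aligners
    pvalue: float = 1e-5          # binomial call threshold
    fdr_target: float = 0.01      # artificial-methylome FDR target
    mcpg_level: float = 0.8
    unmeth_cpg_level: float = 0.2
    hyper_mcph_level: float = 0.5
    profile_radius: int = 500
    profile_binwidth: int = 10
    proximal_radius: int = 100
    block_size: int = 1000
    min_block_cpg: int = 10
    min_block_cph: int = 10
    mcag_cut: float = 0.05
    overlap_cut: float = 0.5
    min_gene_length: int = 1000


@dataclass
class RunConfig:
    samples: list = field(default_factory=list)
    fasta: str | None = None
    context_index: str | None = None
    genes: str | None = None
    expression: str | None = None
    peaks: str | None = None
    output_dir: str = "mchscape_out"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {"call": True, "landscape": True, "context": True, "genes": True}
    )
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        return cls(samples=samples, thresholds=thr, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("call")
def _run_call(cfg: RunConfig, ctx, outdir: Path, manifest: dict) -> dict:
    thr = cfg.thresholds
    methylomes = {}
    for spec in cfg.samples:
        tables = []
        for path, dialect in zip(spec.reports, spec.dialects):
            manifest["inputs"][str(path)] = _sha256(path)
            tab, rep = mio.read_cytosine_report(path, dialect, Path(str(path)).name, None)
            logger.info("%s: %d rows (%d malformed)", path, rep.n_rows, rep.n_malformed)
            tables.append(tab)
        table = pd.concat(tables, ignore_index=True)
        table = mio.coverage_filter(table, thr.min_depth, thr.min_aligners)
        icfg = calling.IntegrationConfig(non_conversion_rate=spec.ncr)
        meth = calling.integrate_methylation(table, icfg, context_index=ctx)
        calib = calling.calibrate_fdr(
            meth, spec.ncr, fdr_target=thr.fdr_target, seed=np.random.SeedSequence(cfg.seed)
        )
        meth = calling.call_methylated(meth, icfg, threshold=thr.pvalue)
        mpath = outdir / f"{spec.sample_id}.methylome.tsv.gz"
        mio.write_methylome(meth, mpath)
        cpath = outdir / f"{spec.sample_id}.calibration.tsv"
        calib.to_frame().to_csv(cpath, sep="\t", index=False)
        manifest["outputs"] += [mpath.name, cpath.name]
        methylomes[spec.sample_id] = meth
    return methylomes


@_stage("landscape")
def _run_landscape(cfg: RunConfig, methylomes: dict, outdir: Path, manifest: dict) -> None:
    thr = cfg.thresholds
    for sid, meth in methylomes.items():
        prof = landscape.distance_level_profile(meth, radius=thr.profile_radius)
        p1 = outdir / f"{sid}.level_profile.tsv"
        prof.table.to_csv(p1, sep="\t", index=False)
        prob = landscape.distance_probability_profile(
            meth, radius=thr.profile_radius, binwidth=thr.profile_binwidth
        )
        p2 = outdir / f"{sid}.probability_profile.tsv"
        prob.table.to_csv(p2, sep="\t", index=False)
        blocks = landscape.bin_genome(meth, block_size=thr.block_size)
        p3 = outdir / f"{sid}.blocks.tsv.gz"
        blocks.to_csv(p3, sep="\t", index=False, compression={"method": "gzip", "mtime": 0})
        manifest["outputs"] += [p1.name, p2.name, p3.name]
    if len(methylomes) >= 2:
        clust = landscape.proximal_pattern_matrix(methylomes, radius=thr.proximal_radius)
        p4 = outdir / "proximal_pcc.tsv"
        clust.pcc.to_csv(p4, sep="\t")
        p5 = outdir / "proximal_dendrogram.nwk"
        p5.write_text(clust.newick + "\n")
        manifest["outputs"] += [p4.name, p5.name]


@_stage("context")
def _run_context(cfg: RunConfig, methylomes: dict, genome, outdir: Path, manifest: dict) -> None:
    for sid, meth in methylomes.items():
        summ = context_motif.context_mean_levels(meth)
        p1 = outdir / f"{sid}.context_summary.tsv"
        context_motif.context_summary_frame(summ).to_csv(p1, sep="\t", index=False)
        manifest["outputs"].append(p1.name)
        if genome is not None:
            try:
                pfm = context_motif.motif_at_hypermethylated(meth, genome)
            except ValueError:
                logger.warning("%s: no hyper-methylated CpH; motif skipped", sid)
                continue
            p2 = outdir / f"{sid}.motif_pfm.tsv"
            pfm.write(p2)
            manifest["outputs"].append(p2.name)


@_stage("genes")
def _run_genes(cfg: RunConfig, methylomes: dict, outdir: Path, manifest: dict) -> None:
    thr = cfg.thresholds
    genes = gene_mod.load_gene_table(cfg.genes)
    manifest["inputs"][str(cfg.genes)] = _sha256(cfg.genes)
    expression = peaks = None
    if cfg.expression:
        expression = pd.read_csv(cfg.expression, sep="\t")
        manifest["inputs"][str(cfg.expression)] = _sha256(cfg.expression)
    if cfg.peaks:
        peaks = pd.read_csv(cfg.peaks, sep="\t", header=None, usecols=[0, 1, 2],
                            names=["chrom", "start", "end"])
        manifest["inputs"][str(cfg.peaks)] = _sha256(cfg.peaks)
    for sid, meth in methylomes.items():
        summ = gene_mod.build_gene_summaries(
            meth, genes, expression, peaks, min_len=thr.min_gene_length
        )
        p1 = outdir / f"{sid}.gene_summaries.tsv"
        summ.round(6).to_csv(p1, sep="\t", index=False)
        manifest["outputs"].append(p1.name)
        if expression is not None:
            prof = gene_mod.metagene_profile(meth, genes, expression, group="all")
            p2 = outdir / f"{sid}.metagene.tsv"
            prof.round(6).to_csv(p2, sep="\t", index=False)
            manifest["outputs"].append(p2.name)
        if peaks is not None:
            selected, quantile = gene_mod.screen_genes(
                summ, thr.mcag_cut, thr.overlap_cut, thr.min_gene_length
            )
            p3 = outdir / f"{sid}.screened_genes.tsv"
            selected.round(6).to_csv(p3, sep="\t", index=False)
            manifest["outputs"].append(p3.name)
            manifest.setdefault("stats", {})[f"{sid}.mcag_cut_quantile"] = quantile


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages and return (and write) the output manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"inputs": {}, "outputs": [], "config": cfg.to_dict(), "seed": cfg.seed}

    genome = ctx = None
    if cfg.fasta:
        genome = reference.load_fasta(cfg.fasta)
        manifest["inputs"][str(cfg.fasta)] = _sha256(cfg.fasta)
        ctx = reference.classify_cytosines(genome)
    elif cfg.context_index:
        ctx = reference.read_context_index(cfg.context_index)
        manifest["inputs"][str(cfg.context_index)] = _sha256(cfg.context_index)

    methylomes = {}
    if cfg.stages.get("call", True):
        methylomes = _run_call(cfg, ctx, outdir, manifest)
    if cfg.stages.get("landscape", True) and methylomes:
        _run_landscape(cfg, methylomes, outdir, manifest)
    if cfg.stages.get("context", True) and methylomes:
        _run_context(cfg, methylomes, genome, outdir, manifest)
    if cfg.stages.get("genes", True) and methylomes and cfg.genes:
        _run_genes(cfg, methylomes, outdir, manifest)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
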