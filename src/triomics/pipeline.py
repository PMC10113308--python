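"""End-to-end orchestration: simulate -> DE -> dominance -> DMR/MLD -> sRNA
-> integration -> segments/CNV, from one declarative config.

Outputs are plain TSV/BED/FASTA files under the run directory, written
once (no stage mutates another stage's inputs), each with a comment header
carrying the tool version and config hash. Re-running with the same config
and seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffexpr, dominance, integration, io, methylation, segments, simulate, srna
from .intervals import GenomicInterval
from .methylation import DmrParams

ROLE_OF_LABEL = {"E": "maternal", "G": "paternal", "F": "hybrid"}
CONTRASTS = [("maternal", "hybrid"), ("paternal", "hybrid"), ("maternal", "paternal")]


@dataclass
class PipelineConfig:
    seed: int = 0
    de_alpha: float = 0.05
    dominance_alpha: float = 0.05
    dmr: DmrParams = field(default_factory=DmrParams)
    island_min_gc: float = 0.5
    island_min_len: int = 201
    island_min_obs_exp: float = 0.6
    island_window: int = 100
    segment_window: int = 500_000
    segment_min_degs: int = 20
    segment_z_range: float = 1.5
    cnv_window: int = 25_000
    cnv_depth_cap: float = 100.0
    flank_bp: int = 5000
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "dmr" in kwargs:
            kwargs["dmr"] = DmrParams(**kwargs["dmr"])
        if "simulation" in kwargs:
            kwargs["simulation"] = simulate.SimulationConfig(**kwargs["simulation"])
        cfg = cls(**kwargs)
        if seed is not None:
            cfg = dataclasses.replace(
                cfg, seed=seed,
                simulation=dataclasses.replace(cfg.simulation, seed=seed),
            )
        for name in ("de_alpha", "dominance_alpha", "segment_z_range", "flank_bp"):
            if getattr(cfg, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        return cfg

    def header(self) -> list[str]:
        return [f"triomics {__version__}", f"config_hash={self.simulation.config_hash()}"]


def _coherent_sim_config(cfg: PipelineConfig) -> simulate.SimulationConfig:
    """Match gene annotation to the count features so IDs line up 1:1."""
    sim = cfg.simulation
    n_feat = sum(sim.n_features_per_class.values())
    per_chrom = -(-n_feat // sim.n_chromosomes)
    spacing = sim.chrom_length_bp // (per_chrom + 1)
    gene_len = min(sim.gene_length_bp, max(600, spacing * 2 // 3))
    return dataclasses.replace(sim, n_genes=n_feat, gene_length_bp=gene_len)


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = cfg.header()
    sim = _coherent_sim_config(cfg)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": sim.config_hash(),
        "outputs": [],
    }

    def emit(name: str):
        manifest["outputs"].append(name)
        return out / name

    # ---- genome + annotation
    genome = simulate.simulate_genome(sim)
    io.write_fasta(genome["seqs"], emit("genome.fa"))
    io.write_gff3(genome["genes"], emit("genes.gff3"), header=hdr)
    io.write_bed(genome["tes"], emit("repeats.bed"), header=hdr)
    io.write_bed(genome["centromeres"], emit("centromeres.bed"), header=hdr)
    io.write_tsv(genome["island_truth"], emit("truth_islands.tsv"), header=hdr)

    # ---- counts + DE + ELD
    matrix, counts_truth = simulate.simulate_trio_counts(sim)
    io.write_counts(matrix.counts, emit("counts.tsv"), header=hdr)
    io.write_sample_sheet(matrix.design, emit("samples.tsv"), header=hdr)
    io.write_tsv(counts_truth, emit("truth_counts.tsv"), header=hdr)
    stage = sim.stage
    counts_f = diffexpr.filter_zero_features(matrix.counts)
    norm = diffexpr.normalized_counts(counts_f)
    de_union, de_tables = diffexpr.de_features_any_contrast(
        matrix, stage, alpha=cfg.de_alpha, norm=norm
    )
    de_all = pd.concat([t.reset_index() for t in de_tables.values()], ignore_index=True)
    io.write_tsv(de_all, emit("de_results.tsv"), header=hdr)

    eld = classify_stage(matrix, norm, de_union, stage, "mRNA", cfg.dominance_alpha)
    io.write_tsv(eld, emit("eld_calls.tsv"), header=hdr)
    io.write_tsv(dominance.dominance_summary(eld), emit("eld_summary.tsv"), header=hdr)

    # ---- methylome + DMR + MLD
    cx_by_sample, meth_design, dmr_truth = simulate.simulate_methylome(sim, genome["seqs"])
    for sample, cx in cx_by_sample.items():
        io.write_cx_report(cx, emit(f"cx_{sample}.tsv"), header=hdr)
    io.write_sample_sheet(meth_design, emit("meth_samples.tsv"), header=hdr)
    io.write_tsv(dmr_truth, emit("truth_dmrs.tsv"), header=hdr)
    genotype_of = {
        s: simulate.GENOTYPES[meth_design.loc[s, "genotype_role"]] for s in meth_design.index
    }
    pooled, per_rep = methylation.methylation_levels(
        cx_by_sample, genotype_of, bin_size=cfg.dmr.bin_size
    )
    dmr_frames = [
        methylation.call_dmrs(pooled, pair, cfg.dmr)
        for pair in (("E", "G"), ("E", "F"), ("F", "G"))
    ]
    non_empty = [d for d in dmr_frames if not d.empty]
    dmrs_all = (
        pd.concat(non_empty, ignore_index=True) if non_empty else dmr_frames[0]
    )
    io.write_tsv(dmrs_all, emit("dmrs.tsv"), header=hdr)
    uniq = dmrs_all.drop_duplicates(subset=["chrom", "start", "end", "context"])[
        ["chrom", "start", "end", "context"]
    ].reset_index(drop=True)
    mld = methylation.classify_mld(
        uniq, per_rep, {"maternal": "E", "paternal": "G", "hybrid": "F"},
        stage=stage, alpha=cfg.dominance_alpha,
    )
    io.write_tsv(mld, emit("mld_calls.tsv"), header=hdr)
    io.write_tsv(dominance.dominance_summary(mld), emit("mld_summary.tsv"), header=hdr)

    # ---- CpG islands
    islands = methylation.find_cpg_islands(
        genome["seqs"], min_gc=cfg.island_min_gc, min_len=cfg.island_min_len,
        min_obs_exp=cfg.island_min_obs_exp, window=cfg.island_window,
    )
    io.write_tsv(islands, emit("cpg_islands.tsv"), header=hdr)

    # ---- sRNA
    clusters, srna_matrix, srna_truth = simulate.simulate_srna_clusters(sim)
    classed = srna.classify_clusters(
        clusters.merge(srna_matrix.counts, left_on="cluster_id", right_index=True),
        list(srna_matrix.counts.columns),
    )
    io.write_tsv(classed, emit("srna_clusters.tsv"), header=hdr)
    io.write_tsv(srna_truth, emit("truth_srna.tsv"), header=hdr)
    srna_norm = diffexpr.normalized_counts(diffexpr.filter_zero_features(srna_matrix.counts))
    srna_de, _ = diffexpr.de_features_any_contrast(srna_matrix, stage, alpha=cfg.de_alpha, norm=srna_norm)
    srna_eld = classify_stage(srna_matrix, srna_norm, srna_de, stage, "sRNA", cfg.dominance_alpha)
    io.write_tsv(srna_eld, emit("srna_eld_calls.tsv"), header=hdr)

    # ---- integration
    genes = genome["genes"]
    epialleles = integration.find_epialleles(eld, uniq, mld, genes)
    io.write_tsv(epialleles, emit("epialleles.tsv"), header=hdr)
    comp, per_dmr = integration.dmr_feature_composition(
        uniq, genes, genome["tes"], flank_bp=cfg.flank_bp
    )
    io.write_tsv(comp, emit("dmr_composition.tsv"), header=hdr)
    io.write_tsv(per_dmr, emit("dmr_annotation.tsv"), header=hdr)

    deg_ids = set(de_union)
    dmr_ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in uniq.itertuples(index=False)]
    non_dmr = _non_dmr_bins(pooled, uniq, cfg.dmr.bin_size)
    assoc = integration.proximity_association(
        {"DMR": (dmr_ivs, non_dmr)}, genes, deg_ids,
        flank_bp=cfg.flank_bp, chrom_lengths=sim.chrom_lengths,
    )
    io.write_tsv(assoc, emit("proximity_association.tsv"), header=hdr)

    corr_rows = []
    expr_means = {
        lab: norm[matrix.samples(ROLE_OF_LABEL[lab], stage)].mean(axis=1)
        for lab in ("E", "F", "G")
    }
    for region in ("gene_body", "promoter"):
        gm = integration.gene_methylation_levels(pooled, genes, region=region)
        if gm.empty:
            continue
        merged_levels = gm.assign(
            expr=[
                expr_means[r.genotype].get(r.gene_id, np.nan)
                for r in gm.itertuples(index=False)
            ]
        ).dropna()
        if len(merged_levels) >= 10:
            res = integration.methylation_expression_correlation(
                merged_levels["expr"].to_numpy(), merged_levels["level"].to_numpy()
            )
            corr_rows.append({"region": region, "stage": stage, **res})
    io.write_tsv(pd.DataFrame(corr_rows), emit("methylation_expression_correlation.tsv"), header=hdr)

    # ---- segments + CNV
    pos_of = {g.gene_id: (g.interval.chrom, (g.interval.start + g.interval.end) // 2) for g in genes}
    deg_rows = []
    for (c1, c2), tab in de_tables.items():
        de_only = tab[tab["is_de"]]
        for fid, row in de_only.iterrows():
            if fid in pos_of:
                chrom, pos = pos_of[fid]
                deg_rows.append(
                    {"chrom": chrom, "pos": pos, "direction": row["direction"],
                     "genotype": f"{c1}_vs_{c2}", "stage": stage}
                )
    deg_df = pd.DataFrame(deg_rows, columns=["chrom", "pos", "direction", "genotype", "stage"])
    seg = segments.find_segments(
        deg_df, sim.chrom_lengths, window=cfg.segment_window,
        min_degs=cfg.segment_min_degs, z_range_thresh=cfg.segment_z_range,
    ) if not deg_df.empty else pd.DataFrame()
    io.write_tsv(seg, emit("segments.tsv"), header=hdr)

    coverage, cnv_truth = simulate.simulate_coverage(sim)
    io.write_tsv(coverage, emit("coverage.tsv"), header=hdr)
    io.write_tsv(cnv_truth, emit("truth_cnv.tsv"), header=hdr)
    cnvs, cnv_stats = segments.call_cnv(
        coverage, window=cfg.cnv_window, depth_cap=cfg.cnv_depth_cap
    )
    io.write_tsv(cnvs, emit("cnv_calls.tsv"), header=hdr)
    manifest["cnv_stats"] = cnv_stats
    if not seg.empty:
        io.write_tsv(segments.segments_vs_cnv(seg, cnvs), emit("segments_vs_cnv.tsv"), header=hdr)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def classify_stage(
    matrix: diffexpr.TrioCountMatrix,
    norm: pd.DataFrame,
    de_union: set[str],
    stage: str,
    omic: str,
    alpha: float,
) -> pd.DataFrame:
    e = norm[matrix.samples("maternal", stage)].to_numpy()
    f = norm[matrix.samples("hybrid", stage)].to_numpy()
    g = norm[matrix.samples("paternal", stage)].to_numpy()
    is_de = norm.index.isin(list(de_union))
    return dominance.classify_trio(
        norm.index, e, f, g, stage=stage, omic=omic, is_differential=is_de,
        alpha=alpha, log_transform=True,
    )


def _non_dmr_bins(pooled: pd.DataFrame, dmrs: pd.DataFrame, bin_size: int) -> list[GenomicInterval]:
    """Covered bins that are not DMRs, as matched non-differential regions."""
    dmr_keys = {
        (r.chrom, b)
        for r in dmrs.itertuples(index=False)
        for b in range(int(r.start) // bin_size, int(r.end) // bin_size)
    }
    bins = pooled[["chrom", "bin_start"]].drop_duplicates()
    out = []
    for r in bins.itertuples(index=False):
        if (r.chrom, int(r.bin_start) // bin_size) not in dmr_keys:
            out.append(GenomicInterval(r.chrom, int(r.bin_start), int(r.bin_start) + bin_size))
    return out
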