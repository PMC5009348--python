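"""End-to-end orchestration: annotation -> target calling -> per-SNP
selection statistics -> staged filter -> enrichment -> reports.

Every stage writes a plain-text TSV, so stages are independently re-runnable
and the stage outputs are the interfaces between modules.  A JSON manifest
records inputs, parameters and seeds; reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cascade import CascadeConfig, cascade_filter
from .enrichment import DensityRecord, group_density_comparison, snp_density
from .popgen import (
    HaplotypePanel,
    SelectionRecord,
    read_vcf,
    records_to_dataframe,
    selection_scan,
)
from .simulate import (
    GenomeSimConfig,
    PopSimConfig,
    SimulatedAnnotation,
    simulate_annotation,
    simulate_balding_nichols,
)
from .targets import (
    AlignmentParams,
    MiRNA,
    align_miranda_like,
    classify_alu_sites,
    consensus_targets,
    find_seed_sites,
    read_mirna_fasta,
    write_sites_tsv,
)

log = logging.getLogger("alusel")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "alusel_out"
    mode: str = "genomewide"              # or "expression"
    seed: int = 0
    window_bp: int = 30_000
    # synthetic inputs (used when explicit paths are not given)
    genome_sim: GenomeSimConfig | None = None
    pop_sim: PopSimConfig | None = None
    # explicit inputs
    utr_fasta: str | None = None
    mirna_fasta: str | None = None
    vcf: str | None = None
    panel_tsv: str | None = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    def alignment_params(self) -> AlignmentParams:
        if self.mode == "expression":
            return AlignmentParams.expression_mode()
        return AlignmentParams.genomewide_mode()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


@_stage("annotate")
def stage_annotate(config: PipelineConfig) -> SimulatedAnnotation:
    gs = config.genome_sim or GenomeSimConfig(seed=config.seed)
    ann = simulate_annotation(gs)
    ann.write(os.path.join(config.outdir, "annotation"))
    return ann


@_stage("targets")
def stage_targets(
    config: PipelineConfig, ann: SimulatedAnnotation, mirnas: Sequence[MiRNA]
):
    params = config.alignment_params()
    seed_sites, align_sites = [], []
    for gene, seq in sorted(ann.utr_seqs.items()):
        for mir in mirnas:
            seed_sites.extend(find_seed_sites(seq, mir, utr_id=gene))
            align_sites.extend(align_miranda_like(seq, mir, params, utr_id=gene))
    consensus = consensus_targets(align_sites, seed_sites)
    classified = classify_alu_sites(consensus, ann.alu_segments())
    write_sites_tsv(classified, os.path.join(config.outdir, "target_sites.tsv"))
    return classified


@_stage("stats")
def stage_stats(config: PipelineConfig, ann: SimulatedAnnotation):
    if config.vcf is not None:
        if not os.path.exists(config.vcf):
            raise FileNotFoundError(config.vcf)
        panel = read_vcf(config.vcf, config.panel_tsv)
    else:
        ps = config.pop_sim or PopSimConfig(seed=config.seed)
        panel = simulate_balding_nichols(ps)
    # assign SNPs to genes cyclically through UTR space so every gene has SNPs
    genes = sorted(ann.utr_seqs)
    gene_of_site = {s: genes[s % len(genes)] for s in range(panel.n_sites)}
    records = selection_scan(
        panel, list(range(panel.n_sites)), gene_of_site, window_bp=config.window_bp
    )
    df = records_to_dataframe(records)
    df.to_csv(os.path.join(config.outdir, "snp_statistics.tsv"), sep="\t", index=False)
    return panel, records, gene_of_site


@_stage("filter")
def stage_filter(config: PipelineConfig, records):
    result = cascade_filter(records, config.cascade)
    lines = ["stage\tn_snps\tn_genes"]
    for k, (ns, ng) in result.stage_counts.items():
        lines.append(f"{k}\t{ns}\t{ng}")
    with open(os.path.join(config.outdir, "cascade_report.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    report_table1_style(
        result.branch_h, os.path.join(config.outdir, "candidates.tsv"), config.cascade
    )
    return result


@_stage("enrich")
def stage_enrich(config: PipelineConfig, ann, sites, panel, records, gene_of_site):
    # per-gene region classes from target calls and Alu segments
    alu = ann.alu_segments()
    snps_of_gene: dict[str, list[int]] = {}
    for s, g in gene_of_site.items():
        snps_of_gene.setdefault(g, []).append(s)
    site_spans: dict[str, list[tuple[int, int]]] = {}
    for t in sites:
        site_spans.setdefault(t.utr_id, []).append((t.start, t.end))
    density_records = []
    rng = np.random.default_rng(config.seed)
    for gene, seq in sorted(ann.utr_seqs.items()):
        L = len(seq)
        snp_idx = snps_of_gene.get(gene, [])
        # map panel positions onto the UTR cyclically (synthetic geometry)
        positions = [int(panel.positions[s]) % L for s in snp_idx]
        spans = site_spans.get(gene, [])
        alu_spans = alu.get(gene, [])
        def clip(regions):
            return [(max(0, a), min(L, b)) for a, b in regions if a < L]
        in_alu_sites = [
            sp for sp in spans
            if any(min(sp[1], b) - max(sp[0], a) > 0 for a, b in alu_spans)
        ]
        nonalu_sites = [sp for sp in spans if sp not in in_alu_sites]
        for cls, regions in (
            ("alu_mirna_target", in_alu_sites),
            ("utr_nonalu_mirna_target", nonalu_sites),
            ("alu_no_target", alu_spans),
            ("full_utr3", [(0, L)]),
        ):
            n, bp, _ = snp_density(clip(regions), positions)
            density_records.append(DensityRecord(gene, cls, bp, n))
    table = group_density_comparison(density_records, metrics=("density",))
    table.to_csv(
        os.path.join(config.outdir, "enrichment_report.tsv"), sep="\t", index=False
    )
    return density_records, table


def report_table1_style(
    records: Sequence[SelectionRecord], path: str, config: CascadeConfig | None = None
) -> pd.DataFrame:
    """Candidate table in the published column order, with pass-flag columns
    standing in for the original's bold highlighting."""
    config = config or CascadeConfig()
    df = records_to_dataframe(
        sorted(records, key=lambda r: (r.gene, r.snp_id))
    )
    cols = ["gene", "snp",
            "fst_yri_chb", "fst_yri_ceu", "fst_ceu_chb",
            "h_ceu", "h_chb", "h_yri",
            "d_ceu", "d_chb", "d_yri",
            "daf_ceu", "daf_chb", "daf_yri"]
    if df.empty:
        df = pd.DataFrame(columns=cols)
    else:
        df = df.rename(columns={})[
            [c for c in ["gene", "snp"] if c in df.columns]
            + [c for c in cols[2:] if c in df.columns]
        ]
    for c in ("fst_yri_chb", "fst_yri_ceu", "fst_ceu_chb"):
        if c in df.columns:
            df[f"{c}_pass"] = df[c] > config.pairwise_fst_min
    for c in ("h_ceu", "h_chb", "h_yri"):
        if c in df.columns:
            df[f"{c}_pass"] = df[c] <= config.h_max + config.boundary_tolerance
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest dict (also written as JSON)."""
    os.makedirs(config.outdir, exist_ok=True)
    if config.mirna_fasta:
        mirnas = read_mirna_fasta(config.mirna_fasta)
    elif config.genome_sim and config.genome_sim.planted_mirnas:
        mirnas = list(config.genome_sim.planted_mirnas)
    else:
        mirnas = [MiRNA("miR-15a-3p", "CAGGCCAUAUUGUGCUGCCUCA")]
        if config.genome_sim is not None:
            config.genome_sim.planted_mirnas = mirnas
    ann = stage_annotate(config)
    sites = stage_targets(config, ann, mirnas)
    panel, records, gene_of_site = stage_stats(config, ann)
    cascade_res = stage_filter(config, records)
    stage_enrich(config, ann, sites, panel, records, gene_of_site)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "window_bp": config.window_bp,
        "n_genes": len(ann.utr_seqs),
        "n_snps": int(panel.n_sites),
        "n_target_sites": len(sites),
        "cascade_counts": {k: list(v) for k, v in cascade_res.stage_counts.items()},
        "mirnas": [m.name for m in mirnas],
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
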