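"""End-to-end pipeline: simulate -> stability -> associate -> compare -> enrich.

Each stage writes its tables into the run directory so any stage can be
re-run from saved intermediates; ``summary.json`` aggregates stage-level
counts plus a provenance block (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from stabilityqtl import __version__, io
from stabilityqtl.assoc import (
    add_bh_q,
    associate_linear,
    cis_pairs,
    genotype_pcs,
    sex_specific_stqtls,
    variant_qc,
)
from stabilityqtl.compare import cross_classify, ld_blocks_and_filter
from stabilityqtl.enrich import (
    annotate_pairs_with_regions,
    binding_site_enrichment,
    count_regions,
    region_enrichment,
)
from stabilityqtl.errors import ConfigError
from stabilityqtl.simdata import SimConfig, simulate_dataset
from stabilityqtl.stability import compute_tpm, infer_stability, transform_expression

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_samples: int = 300
    n_variants: int = 2000
    n_genes: int = 200
    window: int = 100_000
    stringency: float = 0.01
    fdr: float = 0.05
    r2_min: float = 0.9
    profile_bin: int = 2000
    profile_step: int = 50
    sites_bed: Optional[str] = None
    run_sex_qtl: bool = True
    sim_overrides: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ConfigError(f"fdr={self.fdr} outside (0, 1)")
        if not 0 < self.stringency <= 1:
            raise ConfigError(f"stringency={self.stringency} outside (0, 1]")
        if not 0 < self.r2_min <= 1:
            raise ConfigError(f"r2_min={self.r2_min} outside (0, 1]")
        if self.sites_bed is not None and not os.path.exists(self.sites_bed):
            raise ConfigError(f"binding-site BED not found: {self.sites_bed}")


def _config_hash(config: RunConfig) -> str:
    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # analysis parameters only, not paths
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full simulated workflow and return the summary dict."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    summary: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
        }
    }

    stage = "simulate"
    try:
        sim_cfg = SimConfig(
            n_samples=config.n_samples,
            n_variants=config.n_variants,
            n_genes=config.n_genes,
            seed=config.seed,
            **config.sim_overrides,
        )
        data = simulate_dataset(sim_cfg)
        io.write_vcf(data.genotypes, os.path.join(out, "genotypes.vcf"))
        io.write_gtf(data.annotation, os.path.join(out, "annotation.gtf"))
        io.write_segment_bed(data.annotation, os.path.join(out, "segments.bed"))
        io.write_counts_tsv(
            data.counts,
            os.path.join(out, "counts_exon.tsv"),
            os.path.join(out, "counts_intron.tsv"),
        )
        io.write_tsv(data.truth, os.path.join(out, "truth.tsv"))
        io.write_tsv(data.covariates, os.path.join(out, "covariates.tsv"), "sample_id")
        summary["simulate"] = {
            "n_samples": sim_cfg.n_samples,
            "n_variants": sim_cfg.n_variants,
            "n_genes": sim_cfg.n_genes,
            "n_truth_rows": len(data.truth),
        }

        stage = "variant_qc"
        genotypes = variant_qc(data.genotypes)
        summary["variant_qc"] = {"n_pass": genotypes.n_variants}

        stage = "stability"
        stability = infer_stability(data.counts, stringency=config.stringency)
        io.write_tsv(
            stability.values.assign(max_stringency=stability.max_stringency),
            os.path.join(out, "stability.tsv"),
            "gene_id",
        )
        exonic_lengths = pd.Series(
            {g.gene_id: g.exonic_length for g in data.annotation}
        )
        tpm = compute_tpm(data.counts.exon, exonic_lengths)
        expression = transform_expression(tpm)
        summary["stability"] = {
            "n_genes": len(stability.values),
            "n_pass_stringency": int(stability.passed.sum()),
            "n_dropped": len(stability.dropped),
        }

        stage = "cis_pairs"
        pairs = cis_pairs(data.annotation, genotypes, window=config.window)
        summary["cis_pairs"] = {"n_pairs": len(pairs)}

        stage = "associate"
        pcs = genotype_pcs(genotypes)
        covariates = pd.concat(
            [data.covariates, pcs.loc[data.covariates.index]], axis=1
        )
        stab_trait = stability.values.loc[stability.passed[stability.passed].index]
        eqtl = add_bh_q(
            associate_linear(expression, genotypes, covariates, pairs, "expression")
        )
        stqtl = add_bh_q(
            associate_linear(stab_trait, genotypes, covariates, pairs, "stability")
        )
        io.write_tsv(eqtl.sort_values("p"), os.path.join(out, "eqtl.tsv"))
        io.write_tsv(stqtl.sort_values("p"), os.path.join(out, "stqtl.tsv"))
        summary["associate"] = {
            "n_eqtl": int((eqtl["q"] < config.fdr).sum()),
            "n_stqtl": int((stqtl["q"] < config.fdr).sum()),
        }

        stage = "compare"
        shared = stqtl[["variant_id", "gene_id"]].merge(
            eqtl[["variant_id", "gene_id"]]
        )
        e_shared = eqtl.merge(shared, on=["variant_id", "gene_id"])
        s_shared = stqtl.merge(shared, on=["variant_id", "gene_id"])
        cross = cross_classify(e_shared, s_shared, fdr=config.fdr)
        io.write_tsv(cross.table, os.path.join(out, "cross_classification.tsv"))
        summary["compare"] = cross.summary

        stage = "ld_filter"
        stqtl_sig = stqtl[stqtl["q"] < config.fdr]
        if len(stqtl_sig):
            _, representatives = ld_blocks_and_filter(
                genotypes, stqtl_sig, r2_min=config.r2_min
            )
            io.write_tsv(representatives, os.path.join(out, "stqtl_ld_filtered.tsv"))
            summary["ld_filter"] = {"n_representative_stqtl": len(representatives)}
        else:
            summary["ld_filter"] = {"n_representative_stqtl": 0}

        stage = "enrich"
        annotated = annotate_pairs_with_regions(
            stqtl, data.annotation, genotypes, flank=config.window
        )
        annotated["is_stqtl"] = annotated["q"] < config.fdr
        region_table = region_enrichment(
            count_regions(annotated["region"], annotated["is_stqtl"])
        )
        io.write_tsv(region_table, os.path.join(out, "stqtl_region_enrichment.tsv"))
        summary["enrich"] = {
            "regions": region_table.set_index("region")["er"].to_dict()
            if len(region_table)
            else {}
        }

        stage = "rbp_overlap"
        if config.sites_bed is not None:
            sites = io.read_bed_sites(config.sites_bed)
            overlap = binding_site_enrichment(annotated, sites, qtl_flag="is_stqtl")
            io.write_tsv(overlap.per_factor, os.path.join(out, "rbp_enrichment.tsv"))
            summary["rbp_overlap"] = {
                "qtl_overlap_pct": overlap.qtl_overlap_pct,
                "background_overlap_pct": overlap.background_overlap_pct,
                "vs_background_p": overlap.vs_background_p,
            }

        stage = "sex_qtl"
        if config.run_sex_qtl:
            sex = data.covariates["sex"]
            sex_result = sex_specific_stqtls(
                stab_trait,
                genotypes,
                covariates.drop(columns=["sex"]),
                sex,
                expression,
                pairs,
                fdr=config.fdr,
            )
            io.write_tsv(sex_result.calls, os.path.join(out, "sex_specific_stqtl.tsv"))
            summary["sex_qtl"] = {
                "n_calls": len(sex_result.calls),
                "n_genes_tested": len(sex_result.genes_tested),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
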