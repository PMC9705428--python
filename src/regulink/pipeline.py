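"""End-to-end demo pipeline on synthetic cohorts, driven by one YAML config.

Stages run in dependency order: simulate -> genotype QC -> stratified eQTL and
co-expression -> peak partitioning / co-occupancy -> SNP partition enrichment
-> signature derivation and scoring -> survival (KM, log-rank, Cox) and a
two-substudy fixed-effect meta-analysis. Every run directory carries the full
config, its hash and the seed, so deterministic stages rerun byte-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .eqtl import coexpression_rank, qc_genotypes, stratified_eqtl
from .genomic import cooccupancy_fraction, partition_peak_sets, write_bed
from .signatures import derive_coexpression_panel, score_signature
from .snp_enrichment import expand_ld_proxies, partition_snp_enrichment
from .survival import cox_fit, km_curve, logrank_test, median_stratify, meta_fixed_effect
from .synthetic import (
    EQTL_SNP,
    TARGET_GENE,
    SimulationConfig,
    simulate_expression_cohort,
    simulate_genotypes,
    simulate_peak_landscape,
    simulate_survival,
)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_STAGES"]

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "simulate", "qc", "eqtl", "coexpression", "peaks", "snp_enrichment",
    "signatures", "survival",
)


@dataclass
class PipelineConfig:
    """Stage toggles plus all stage parameters, loadable from YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in DEFAULT_STAGES})
    r2_min: float = 0.8
    coexpr_panel_k: int = 25
    n_permutations: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.get("simulation", {}))
        stages = {s: True for s in DEFAULT_STAGES}
        stages.update(raw.get("stages", {}))
        unknown = set(stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages in config: {sorted(unknown)}")
        return cls(
            simulation=sim,
            stages=stages,
            r2_min=float(raw.get("r2_min", 0.8)),
            coexpr_panel_k=int(raw.get("coexpr_panel_k", 25)),
            n_permutations=int(raw.get("n_permutations", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "stages": dict(self.stages),
            "r2_min": self.r2_min,
            "coexpr_panel_k": self.coexpr_panel_k,
            "n_permutations": self.n_permutations,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled stages, writing per-stage TSV/JSON outputs.

    Returns the summary dict also written to ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    summary: dict = {"config_hash": config.hash(), "seed": sim.seed, "stages": {}}

    def stage_on(name: str) -> bool:
        return bool(config.stages.get(name, True))

    if not stage_on("simulate"):
        raise ValueError("the demo pipeline requires the simulate stage (all inputs are synthetic)")

    try:
        geno, variants, ld = simulate_genotypes(sim)
        expr, clinical = simulate_expression_cohort(geno, sim)
        rio.write_genotypes(geno, outdir / "genotypes.tsv")
        rio.write_variants(variants, outdir / "variants.tsv")
        rio.write_ld_table(ld, outdir / "ld_pairs.tsv")
        rio.write_expression(expr, outdir / "expression.tsv")
        rio.write_clinical(clinical, outdir / "clinical.tsv")
        summary["stages"]["simulate"] = {
            "n_samples": len(geno), "n_snps": geno.shape[1], "n_genes": expr.shape[0],
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if stage_on("qc"):
        try:
            geno_qc, report = qc_genotypes(geno)
            report.to_csv(outdir / "qc_report.tsv", sep="\t")
            summary["stages"]["qc"] = {
                "n_snps_in": geno.shape[1], "n_snps_kept": geno_qc.shape[1],
            }
            geno = geno_qc
        except Exception as exc:
            raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    if stage_on("eqtl"):
        try:
            res = stratified_eqtl(
                geno, expr, clinical, strata_by="fusion", pairs=[(EQTL_SNP, TARGET_GENE)]
            )
            res.to_csv(outdir / "eqtl_results.tsv", sep="\t", index=False)
            summary["stages"]["eqtl"] = {
                "pairs": 1,
                "strata": sorted(res["stratum"].unique().tolist()),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'eqtl' failed: {exc}") from exc

    panel = None
    if stage_on("coexpression"):
        try:
            fus_pos = clinical.index[clinical["fusion"] == "positive"]
            ranked = coexpression_rank(expr[fus_pos], TARGET_GENE)
            ranked.to_csv(outdir / "coexpression_rank.tsv", sep="\t", index=False)
            panel = derive_coexpression_panel(ranked, k=config.coexpr_panel_k)
            panel.to_frame().to_csv(outdir / "coexpression_panel.tsv", sep="\t", index=False)
            summary["stages"]["coexpression"] = {
                "n_ranked": len(ranked), "panel_k": len(panel.genes),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'coexpression' failed: {exc}") from exc

    partitions = None
    gwas = None
    if stage_on("peaks"):
        try:
            peaks_a, peaks_b, gwas = simulate_peak_landscape(sim)
            write_bed(peaks_a, outdir / "peaks_a.bed")
            write_bed(peaks_b, outdir / "peaks_b.bed")
            rio.write_variants(gwas, outdir / "gwas_snps.tsv")
            co = cooccupancy_fraction(peaks_a, peaks_b)
            unique_a, common, unique_b = partition_peak_sets(
                peaks_a.normalize(), peaks_b.normalize()
            )
            partitions = {"unique_a": unique_a, "common": common, "unique_b": unique_b}
            for name, ps in partitions.items():
                write_bed(ps, outdir / f"partition_{name}.bed")
            summary["stages"]["peaks"] = {
                "n_cooccupied": co.n_cooccupied, "n_total": co.n_total,
                "cooccupancy_fraction": co.fraction,
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'peaks' failed: {exc}") from exc

    if stage_on("snp_enrichment"):
        try:
            if partitions is None or gwas is None:
                raise ValueError("snp_enrichment requires the peaks stage")
            tags = set(gwas["rsid"].head(max(1, len(gwas) // 10)))
            expanded = expand_ld_proxies(tags, ld.rename(columns=str), r2_min=config.r2_min) \
                if len(ld) else tags
            enr = partition_snp_enrichment(
                gwas, partitions, n_permutations=config.n_permutations, seed=sim.seed,
            )
            enr.table.to_csv(outdir / "snp_enrichment.tsv", sep="\t")
            _dump_json(enr.to_dict(), outdir / "snp_enrichment.json")
            summary["stages"]["snp_enrichment"] = {
                "chi2": enr.chi2, "p": enr.p,
                "fold_common": float(enr.table.loc["common", "fold"]),
                "n_tags_expanded": len(expanded),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'snp_enrichment' failed: {exc}") from exc

    scores = None
    if stage_on("signatures"):
        try:
            if panel is None:
                raise ValueError("signatures stage requires the coexpression stage")
            scoreset = score_signature(expr, panel)
            scoreset.scores.rename("score").to_frame().to_csv(
                outdir / "signature_scores.tsv", sep="\t"
            )
            scores = scoreset.scores
            summary["stages"]["signatures"] = {
                "genes_used": len(scoreset.genes_used),
                "genes_missing": len(scoreset.genes_missing),
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'signatures' failed: {exc}") from exc

    if stage_on("survival"):
        try:
            if scores is None:
                raise ValueError("survival stage requires the signatures stage")
            surv = simulate_survival(scores, sim)
            rio.write_clinical(surv, outdir / "survival.tsv")
            strat = median_stratify(scores)
            surv_g = surv.assign(group=strat.labels)
            km = km_curve(surv)
            pd.DataFrame({"time": km.times, "survival": km.survival}).to_csv(
                outdir / "km_curve.tsv", sep="\t", index=False
            )
            lr = logrank_test(surv_g, "group")
            cox = cox_fit(surv, ["score"])
            # two-substudy fixed-effect meta on a deterministic half split
            half = len(surv) // 2
            halves = [surv.iloc[:half], surv.iloc[half:]]
            fits = [cox_fit(h, ["score"]) for h in halves]
            meta = meta_fixed_effect(
                [(f.summary.loc["score", "lnHR"], f.summary.loc["score", "se"]) for f in fits]
            )
            summary["stages"]["survival"] = {
                "logrank_chi2": lr.chi2, "logrank_p": lr.p,
                "cox_lnHR": float(cox.summary.loc["score", "lnHR"]),
                "cox_p": float(cox.summary.loc["score", "p"]),
                "meta_pooled_lnHR": meta.pooled_lnHR, "meta_i2": meta.i2,
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'survival' failed: {exc}") from exc

    _dump_json(config.to_dict(), outdir / "config.json")
    _dump_json(summary, outdir / "summary.json")
    return summary
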