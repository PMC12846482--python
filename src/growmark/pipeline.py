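"""End-to-end orchestration: simulate/load → filter → diversity → adjust →
GWAS → merge → LD expansion → genotype-class association.

A :class:`PipelineConfig` supplies either real input paths (VCF, phenotype
TSV, GFF3, optional external per-model GWAS result TSVs) or a
:class:`~growmark.simdata.SimulationConfig`; all stage parameters are
explicit.  Each stage writes its outputs under the run directory and the
run ends with a JSON manifest recording parameters, seed, and per-stage
row counts and file checksums, so any stage can be re-run on the recorded
inputs.  No stage mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .assoc import associate_candidates, report_markers
from .linkmap import expand_tags, read_gff3_genes
from .mixedmodel import (
    adjust_phenotypes,
    build_design_matrix,
    compute_grm,
    fit_lmm_reml,
    gwas_mlm,
    merge_model_results,
)
from .popgen import diversity_stats, ibs_distance, neighbor_joining
from .simdata import SimulationConfig, simulate_genotypes, simulate_phenotypes, write_outputs
from .varfilter import (
    FilterConfig,
    apply_filters,
    count_substitution_classes,
    per_chromosome_counts,
    summarize_substitution_classes,
)
from .variants import read_populations, read_vcf, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One pipeline run: exactly one of (real inputs, simulation) supplied."""

    out_dir: str
    vcf: str | None = None
    phenotypes: str | None = None
    gff3: str | None = None
    populations: str | None = None
    external_results: tuple[str, ...] = ()
    simulation: SimulationConfig | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    covariates: tuple[str, ...] = ("population", "age", "location", "season")
    adjust_mode: str = "fixed_only"
    alpha: float = 0.05
    window: int = 50_000
    r2_min: float = 0.5
    min_class_n: int = 3
    run_popgen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        real = self.vcf is not None
        sim = self.simulation is not None
        if real == sim:
            raise ValueError(
                "exactly one of real inputs (vcf/phenotypes/gff3) or a "
                "simulation config must be supplied"
            )
        if real and (self.phenotypes is None or self.gff3 is None):
            raise ValueError("real-input runs need vcf, phenotypes and gff3")
        if self.adjust_mode not in ("fixed_only", "full_residual"):
            raise ValueError(f"unknown adjust_mode {self.adjust_mode!r}")
        if not (0 < self.alpha < 1) or not (0 <= self.r2_min <= 1) or self.window < 0:
            raise ValueError("stage thresholds outside documented ranges")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        filt = raw.pop("filter", None)
        cfg = cls(
            simulation=SimulationConfig(**_tupleize(sim)) if sim else None,
            filter=FilterConfig(**filt) if filt else FilterConfig(),
            **raw,
        )
        return cfg


def _tupleize(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the run manifest (also written as JSON).

    Any stage failure aborts with the stage name attached; outputs of
    completed stages are retained for debugging.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "growmark_version": __version__,
        "seed": config.seed,
        "parameters": {
            "maf_min": config.filter.maf_min,
            "max_missing": config.filter.max_missing,
            "hwe_p_min": config.filter.hwe_p_min,
            "covariates": list(config.covariates),
            "adjust_mode": config.adjust_mode,
            "alpha": config.alpha,
            "window": config.window,
            "r2_min": config.r2_min,
            "min_class_n": config.min_class_n,
        },
        "stages": {},
    }
    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            table = simulate_genotypes(sim)
            pheno = simulate_phenotypes(table, sim)
            sim_dir = os.path.join(config.out_dir, "simulated_inputs")
            paths = write_outputs(table, pheno, sim, sim_dir)
            gff3_path = paths["gff3"]
            manifest["stages"]["inputs"] = {
                "mode": "simulated",
                "n_individuals": table.n_samples,
                "n_loci": table.n_loci,
                "files": {k: _sha256(v) for k, v in paths.items()},
            }
        else:
            pops = read_populations(config.populations) if config.populations else None
            pheno = pd.read_csv(config.phenotypes, sep="\t")
            if pops is None and "population" in pheno.columns:
                pops = dict(zip(pheno["id"].astype(str), pheno["population"]))
            table = read_vcf(config.vcf, populations=pops)
            pheno = pheno.set_index("id").loc[table.samples].reset_index()
            gff3_path = config.gff3
            manifest["stages"]["inputs"] = {
                "mode": "real",
                "n_individuals": table.n_samples,
                "n_loci": table.n_loci,
                "files": {"vcf": _sha256(config.vcf), "gff3": _sha256(gff3_path)},
            }

        stage = "varfilter"
        filtered, audit = apply_filters(table, config.filter)
        audit_path = os.path.join(config.out_dir, "filter_audit.tsv")
        audit.to_csv(audit_path, sep="\t", index=False)
        filtered_vcf = os.path.join(config.out_dir, "filtered.vcf")
        write_vcf(filtered, filtered_vcf)
        subs = summarize_substitution_classes(count_substitution_classes(filtered))
        subs_path = os.path.join(config.out_dir, "substitution_summary.tsv")
        subs.to_csv(subs_path, sep="\t")
        per_chrom = per_chromosome_counts(filtered)
        logger.info(
            "varfilter: %d of %d loci retained", filtered.n_loci, table.n_loci
        )
        manifest["stages"]["varfilter"] = {
            "input_loci": table.n_loci,
            "retained_loci": filtered.n_loci,
            "per_chromosome": {str(k): int(v) for k, v in per_chrom.items()},
            "files": {"filtered_vcf": _sha256(filtered_vcf), "audit": _sha256(audit_path)},
        }

        if config.run_popgen:
            stage = "popgen"
            div = diversity_stats(filtered)
            div_path = os.path.join(config.out_dir, "diversity.tsv")
            div.to_csv(div_path, sep="\t")
            dist = ibs_distance(filtered)
            dist_path = os.path.join(config.out_dir, "ibs_distance.tsv")
            dist.to_csv(dist_path, sep="\t")
            tree = neighbor_joining(dist)
            tree_path = os.path.join(config.out_dir, "nj_tree.nwk")
            with open(tree_path, "w") as fh:
                fh.write(tree + "\n")
            manifest["stages"]["popgen"] = {
                "populations": list(div.index),
                "files": {
                    "diversity": _sha256(div_path),
                    "distance": _sha256(dist_path),
                    "tree": _sha256(tree_path),
                },
            }

        stage = "mixedmodel"
        G = compute_grm(filtered)
        grm_path = os.path.join(config.out_dir, "grm.tsv")
        pd.DataFrame(G, index=filtered.samples, columns=filtered.samples).to_csv(
            grm_path, sep="\t"
        )
        covs = [c for c in config.covariates if c in pheno.columns]
        X, kept, dropped = build_design_matrix(pheno, covs)
        y = pheno["weight_g"].to_numpy(dtype=float)
        fit = fit_lmm_reml(y, X, G, column_names=kept)
        adjusted = adjust_phenotypes(fit, mode=config.adjust_mode)
        adj = pheno[["id", "population"]].copy()
        adj["adjusted_weight"] = adjusted
        adj_path = os.path.join(config.out_dir, "adjusted_phenotypes.tsv")
        adj.to_csv(adj_path, sep="\t", index=False)
        vc_path = os.path.join(config.out_dir, "variance_components.tsv")
        pd.DataFrame(
            {
                "sigma2_a": [fit.sigma2_a],
                "sigma2_e": [fit.sigma2_e],
                "h2": [fit.heritability],
                "reml_loglik": [fit.reml_loglik],
                "adjust_mode": [config.adjust_mode],
                "dropped_columns": [";".join(dropped)],
            }
        ).to_csv(vc_path, sep="\t", index=False)

        stage = "gwas"
        gwas = gwas_mlm(adjusted, filtered, G, alpha=config.alpha)
        gwas_path = os.path.join(config.out_dir, "gwas_mlm.tsv")
        gwas.to_csv(gwas_path, sep="\t", index=False)
        sig = gwas[gwas["significant"]][["snp", "chrom", "pos", "ref", "alt", "method"]]
        results = [sig]
        for ext in config.external_results:
            results.append(pd.read_csv(ext, sep="\t"))
        merged = merge_model_results(results)
        merged_path = os.path.join(config.out_dir, "significant_loci.tsv")
        merged.to_csv(merged_path, sep="\t", index=False)
        logger.info(
            "gwas: %d significant of %d tested loci (%d merged)",
            int(gwas["significant"].sum()),
            gwas.attrs["n_tested"],
            len(merged),
        )
        manifest["stages"]["gwas"] = {
            "n_tested": gwas.attrs["n_tested"],
            "bonferroni_threshold": gwas.attrs["bonferroni_threshold"],
            "sigma2_a": gwas.attrs["sigma2_a"],
            "sigma2_e": gwas.attrs["sigma2_e"],
            "n_significant_mlm": int(gwas["significant"].sum()),
            "n_merged": len(merged),
            "files": {"gwas": _sha256(gwas_path), "merged": _sha256(merged_path)},
        }

        stage = "linkmap"
        genes = read_gff3_genes(gff3_path)
        candidates, annotation = expand_tags(
            merged, filtered, genes, window=config.window, r2_min=config.r2_min
        )
        ann_path = os.path.join(config.out_dir, "tag_gene_annotation.tsv")
        annotation.to_csv(ann_path, sep="\t", index=False)
        cand_path = os.path.join(config.out_dir, "linked_candidates.tsv")
        candidates.to_csv(cand_path, sep="\t", index=False)
        manifest["stages"]["linkmap"] = {
            "n_genes": len(genes),
            "n_tags": len(merged),
            "n_annotated_tags": int((annotation["n_genes"] > 0).sum()),
            "n_candidates": len(candidates),
            "n_linked": int((candidates["source"] == "linked").sum()) if len(candidates) else 0,
            "files": {"annotation": _sha256(ann_path), "candidates": _sha256(cand_path)},
        }

        stage = "assoc"
        calls = associate_candidates(
            candidates,
            filtered,
            adjusted,
            alpha=config.alpha,
            min_class_n=config.min_class_n,
        )
        paths = report_markers(calls, config.out_dir)
        n_growth = sum(c.growth_related for c in calls)
        n_unique = sum(c.population_unique for c in calls)
        logger.info(
            "assoc: %d candidates, %d growth-related, %d population-unique",
            len(calls), n_growth, n_unique,
        )
        manifest["stages"]["assoc"] = {
            "n_candidates": len(calls),
            "n_growth_related": int(n_growth),
            "n_population_unique": int(n_unique),
            "unique_markers": [c.snp for c in calls if c.population_unique],
            "files": {k: _sha256(v) for k, v in paths.items()},
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
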