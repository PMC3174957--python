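"""End-to-end orchestration of the two-stage integrative analysis.

Stage 1 scans the expression cohort for cis-eQTLs (MAF and probe filters,
ancestry PCs, covariate-adjusted linear models, joint FDR). Stage 2 carries
the significant eQTL SNPs into the case-control studies: pooled combined
logistic GWAS, per-study meta-analysis, Bonferroni prioritization over the
reduced SNP set, nominal-candidate union, and the sequential two-cohort
replication screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc_core import PipelineConfig, genotype_pcs, ld_prune, quantile_normalize
from .eqtl_scan import (
    enumerate_cis_pairs,
    filter_probes,
    filter_snps,
    run_cis_scan,
    summarize_eqtls,
)
from .gwas_integration import (
    prioritize_bonferroni,
    replication_screen,
    run_combined_gwas,
    run_gwas,
    run_meta,
    select_nominal_candidates,
)
from .synthetic_data import StudyBundle

__all__ = ["run_eqtl_stage", "run_gwas_stage", "run_full_pipeline"]


def expression_covariate_matrix(
    covariates: pd.DataFrame,
    G,
    n_pcs: int,
    ld_prune_r2: float | None = 0.2,
) -> np.ndarray:
    """Age, sex and the leading genotype ancestry PCs, as one matrix.

    PCs are computed on an LD-pruned SNP panel so they track sample
    structure rather than individual haplotype blocks (with a dense local
    panel, unpruned PCs align with block carriers and would absorb cis
    signal from the association tests).
    """
    base = covariates[["age", "sex"]].to_numpy(dtype=float)
    G_pca = G.subset_snps(ld_prune(G, ld_prune_r2)) if ld_prune_r2 is not None else G
    k = min(n_pcs, G_pca.n_samples - 1, G_pca.n_snps)
    pcs = genotype_pcs(G_pca, k)
    return np.column_stack([base, pcs])


def run_eqtl_stage(
    bundle: StudyBundle,
    cfg: PipelineConfig | None = None,
    apply_quantile_normalization: bool = False,
) -> dict:
    """Filters, cis-pair enumeration, scan and FDR summary."""
    cfg = cfg or PipelineConfig()
    G = bundle.expr_genotypes
    E = bundle.expression
    if apply_quantile_normalization:
        E = type(E)(
            values=quantile_normalize(E.values.T).T,
            probe_ids=list(E.probe_ids),
            sample_ids=list(E.sample_ids),
        )
    probes = filter_probes(bundle.annotation)
    kept_snps = filter_snps(G, cfg.maf_min)
    G_kept = G.subset_snps(kept_snps)
    C = expression_covariate_matrix(
        bundle.expr_covariates, G_kept, cfg.n_pcs, cfg.pca_ld_prune_r2
    )
    pairs = enumerate_cis_pairs(G_kept.snp_meta, probes, cfg.cis_window_bp)
    records = run_cis_scan(G_kept, E, C, pairs, cfg)
    summary = summarize_eqtls(records, cfg.fdr_alpha)
    sig = records[records["fdr_p"].notna() & (records["fdr_p"] < cfg.fdr_alpha)]
    return {
        "kept_snps": kept_snps,
        "probes": probes,
        "pairs": pairs,
        "records": records,
        "summary": summary,
        "eqtl_snps": sorted(sig["snp_id"].unique()),
    }


def _disease_covariates(study) -> pd.DataFrame:
    return study.covariates[["age", "sex", "pack_years"]]


def _screen_frame(study, snp_ids) -> pd.DataFrame:
    recs = run_gwas(
        study.genotypes, study.phenotype, _disease_covariates(study),
        snp_ids=snp_ids, study_label=study.label,
    )
    return recs[["snp_id", "p", "direction", "effect_allele"]]


def run_gwas_stage(
    bundle: StudyBundle,
    eqtl_snps: list[str],
    cfg: PipelineConfig | None = None,
) -> dict:
    """Disease lookup of the eQTL SNP set: combined + meta + prioritization
    + candidate selection + replication screen."""
    cfg = cfg or PipelineConfig()
    empty = {
        "combined": pd.DataFrame(), "per_study": [], "meta": pd.DataFrame(),
        "bonferroni": pd.DataFrame(), "bonferroni_threshold": float("nan"),
        "candidates": pd.DataFrame(columns=["snp_id", "provenance", "p_combined", "p_meta", "direction"]),
        "replication": pd.DataFrame(columns=["snp_id", "replicated"]),
    }
    if not eqtl_snps:
        return empty

    combined = run_combined_gwas(bundle.studies, snp_ids=eqtl_snps)
    per_study = [
        run_gwas(s.genotypes, s.phenotype, _disease_covariates(s),
                 snp_ids=eqtl_snps, study_label=s.label)
        for s in bundle.studies
    ]
    meta = run_meta(per_study, method=cfg.meta_method)
    bonf, threshold = prioritize_bonferroni(eqtl_snps, combined, cfg.fwer_alpha)
    exclude = bonf["snp_id"].tolist() if cfg.exclude_bonferroni_from_replication else []
    candidates = select_nominal_candidates(combined, meta, cfg.nominal_p, exclude=exclude)

    if len(bundle.replication_studies) >= 2 and len(candidates):
        cand_ids = candidates["snp_id"].tolist()
        screen1 = _screen_frame(bundle.replication_studies[0], cand_ids)
        screen2 = _screen_frame(bundle.replication_studies[1], cand_ids)
        replication = replication_screen(
            candidates, screen1, screen2, cfg.replication_p,
            require_direction=cfg.require_direction_consistency,
        )
    else:
        replication = empty["replication"]
    return {
        "combined": combined,
        "per_study": per_study,
        "meta": meta,
        "bonferroni": bonf,
        "bonferroni_threshold": threshold,
        "candidates": candidates,
        "replication": replication,
    }


def run_full_pipeline(bundle: StudyBundle, cfg: PipelineConfig | None = None) -> dict:
    """Both stages; returns the union of their output dictionaries."""
    cfg = cfg or PipelineConfig()
    stage1 = run_eqtl_stage(bundle, cfg)
    stage2 = run_gwas_stage(bundle, stage1["eqtl_snps"], cfg)
    return {**stage1, **stage2}
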