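"""Synthetic cohort generator for the integrative eQTL/GWAS pipeline.

Emulates the statistical structure the analysis assumes, so every
downstream stage can be tested without external data:

* a haplotype pool with block LD structure (two-founder carrier copying
  with per-site mutation), yielding tag-SNP bins with controllable r²;
* an expression cohort (default 131 samples) with additive cis-genetic
  effects on log-scale expression plus age/sex covariate effects and
  homoscedastic Gaussian noise;
* larger case-control cohorts whose disease liability depends on a subset
  of the same SNPs through a logistic model;
* a registry of the planted effects (``SimTruth``) enabling
  parameter-recovery tests.

One master seed determines everything; each component derives a child
stream by stable enumeration, so adding a stage never perturbs earlier
streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc_core import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "HaplotypePool",
    "SimConfig",
    "SimTruth",
    "StudyBundle",
    "simulate_haplotype_pool",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_expression",
    "simulate_case_control",
    "generate_study_bundle",
]

# stable spawn keys: one slot per pipeline component
_POOL, _EXPR_GENO, _EXPR_COV, _EXPR_NOISE = 0, 1, 2, 3
_STUDY_BASE = 100  # study i uses slots _STUDY_BASE + 4*i .. +3


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass
class HaplotypePool:
    """Binary haplotypes (n_haplotypes x n_snps) with block structure.

    ``block_bounds`` are half-open SNP-index intervals partitioning the
    panel; ``subpop`` optionally labels each haplotype's subpopulation
    (ancestry structure), None when the pool is unstructured.
    """

    haplotypes: np.ndarray
    snp_meta: pd.DataFrame
    block_bounds: list[tuple[int, int]]
    subpop: np.ndarray | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        bounds = sorted(self.block_bounds)
        covered = [i for s, e in bounds for i in range(s, e)]
        if covered != list(range(h.shape[1])):
            raise ValueError("block intervals must partition the SNP index range")
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimConfig:
    """Study design of a simulated integrative-genomics dataset.

    Defaults mirror the target study design: a 131-sample expression
    cohort; three discovery case-control studies of (1736, 175),
    (838, 791) and (366, 414) cases/controls; two replication studies.
    Covariate distributions (age ~ N(64.9, 5.5), male fraction 0.664,
    pack-years ~ N(46.8, 28.3) truncated at 0) match the expression
    cohort's reported moments.
    """

    n_snps: int = 300
    n_genes: int = 30
    n_expression_samples: int = 131
    study_sizes: list[tuple[int, int]] = field(
        default_factory=lambda: [(1736, 175), (838, 791), (366, 414)]
    )
    replication_study_sizes: list[tuple[int, int]] = field(
        default_factory=lambda: [(1000, 1000), (496, 498)]
    )
    maf_range: tuple[float, float] = (0.10, 0.50)
    mutation_prob: float = 0.03
    recomb_prob_between_blocks: float = 1.0
    block_sizes: list[int] | None = None
    site_mutation_probs: dict[str, float] = field(default_factory=dict)
    cis_effect_sizes: dict[str, float] = field(default_factory=dict)
    disease_log_odds: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    expr_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.30}
    )
    disease_covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.20, "pack_years": 0.005}
    )
    cis_window_bp: int = 50_000
    ancestry_divergence: float = 0.0
    n_haplotypes: int | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_expression_samples < 1:
            raise ValueError("sample sizes must be >= 1")
        for nc, nk in list(self.study_sizes) + list(self.replication_study_sizes):
            if nc < 1 or nk < 1:
                raise ValueError("sample sizes must be >= 1")
        if self.block_sizes is not None and sum(self.block_sizes) != self.n_snps:
            raise ValueError("block_sizes must sum to n_snps")

    # --- deterministic genome layout -------------------------------------
    def snp_ids(self) -> list[str]:
        return [f"rs{i + 1:05d}" for i in range(self.n_snps)]

    def gene_of_snp(self) -> np.ndarray:
        """Gene-group index of each SNP (SNPs split evenly over genes)."""
        chunks = np.array_split(np.arange(self.n_snps), self.n_genes)
        return np.concatenate([np.full(len(c), g, dtype=int) for g, c in enumerate(chunks)])

    def probe_annotation(self) -> pd.DataFrame:
        """One probe per gene; genes spaced 200 kb apart on chromosome 1,
        alternating strand to exercise strand-aware TSS handling."""
        rows = []
        for g in range(self.n_genes):
            rows.append(
                {
                    "probe_id": f"{200000 + g}_at",
                    "gene_symbol": f"GENE{g + 1:03d}",
                    "chrom": "1",
                    "tss": 150_000 + g * 200_000,
                    "strand": "+" if g % 2 == 0 else "-",
                }
            )
        return pd.DataFrame(rows)

    def snp_meta(self) -> pd.DataFrame:
        ann = self.probe_annotation()
        gene_of = self.gene_of_snp()
        rows = []
        for i, sid in enumerate(self.snp_ids()):
            g = gene_of[i]
            group = np.where(gene_of == g)[0]
            k = int(np.where(group == i)[0][0])
            tss = int(ann.loc[g, "tss"])
            span = 80_000
            pos = tss - span // 2 + (k + 1) * span // (len(group) + 1)
            rows.append({"snp_id": sid, "chrom": "1", "pos": int(pos), "ref": "A", "alt": "G"})
        meta = pd.DataFrame(rows)
        if meta["pos"].duplicated().any():  # cramped layout: fall back to unique spacing
            meta["pos"] = np.sort(meta["pos"]) + np.arange(len(meta))
        return meta

    def default_blocks(self) -> list[tuple[int, int]]:
        if self.block_sizes is not None:
            bounds, s = [], 0
            for b in self.block_sizes:
                bounds.append((s, s + b))
                s += b
            return bounds
        gene_of = self.gene_of_snp()
        bounds = []
        for g in range(self.n_genes):
            idx = np.where(gene_of == g)[0]
            if idx.size:
                bounds.append((int(idx[0]), int(idx[-1]) + 1))
        return bounds


@dataclass
class SimTruth:
    """Registry of planted effects for parameter-recovery tests."""

    planted_cis: list[tuple[str, str, float]]  # (snp_id, probe_id, beta)
    planted_disease: list[tuple[str, float]]  # (snp_id, gamma)
    covariate_effects: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "cis", "snp_id": s, "probe_id": p, "effect": b}
            for s, p, b in self.planted_cis
        ] + [
            {"kind": "disease", "snp_id": s, "probe_id": "", "effect": g}
            for s, g in self.planted_disease
        ]
        return pd.DataFrame(rows, columns=["kind", "snp_id", "probe_id", "effect"])


# ---------------------------------------------------------------------------


def simulate_haplotype_pool(cfg: SimConfig, n_haplotypes: int | None = None) -> HaplotypePool:
    """Generate a block-structured haplotype pool.

    Within each block one latent carrier haplotype segregates at a
    frequency drawn from ``cfg.maf_range``; every SNP in the block copies
    the carrier state with per-site mutation probability
    ``cfg.mutation_prob`` (overridable per SNP), giving within-block
    r² ~ (1 - 2*eps)² and independence between blocks. With
    ``recomb_prob_between_blocks < 1`` a haplotype keeps its carrier
    state across a block boundary with the complementary probability.
    """
    if n_haplotypes is None:
        n_haplotypes = cfg.n_haplotypes
    if n_haplotypes is None:
        need = max(
            [cfg.n_expression_samples]
            + [a + b for a, b in cfg.study_sizes]
            + [a + b for a, b in cfg.replication_study_sizes]
        )
        n_haplotypes = max(2 * need, 2000)
    rng = _rng(cfg.master_seed, _POOL)
    meta = cfg.snp_meta()
    bounds = cfg.default_blocks()
    snp_ids = meta["snp_id"].tolist()

    subpop = None
    if cfg.ancestry_divergence > 0:
        subpop = (np.arange(n_haplotypes) % 2).astype(int)

    H = np.zeros((n_haplotypes, cfg.n_snps), dtype=np.int8)
    carrier = None
    for start, end in bounds:
        f = rng.uniform(*cfg.maf_range)
        if subpop is None:
            new_carrier = rng.random(n_haplotypes) < f
        else:
            d = cfg.ancestry_divergence / 2.0
            f_pop = np.clip(np.where(subpop == 0, f - d, f + d), 0.01, 0.99)
            new_carrier = rng.random(n_haplotypes) < f_pop
        if carrier is None or cfg.recomb_prob_between_blocks >= 1.0:
            carrier = new_carrier
        else:
            switch = rng.random(n_haplotypes) < cfg.recomb_prob_between_blocks
            carrier = np.where(switch, new_carrier, carrier)
        for j in range(start, end):
            eps = cfg.site_mutation_probs.get(snp_ids[j], cfg.mutation_prob)
            flips = rng.random(n_haplotypes) < eps
            H[:, j] = np.where(flips, 1 - carrier.astype(np.int8), carrier.astype(np.int8))
    return HaplotypePool(haplotypes=H, snp_meta=meta, block_bounds=bounds, subpop=subpop)


def simulate_genotypes(
    pool: HaplotypePool,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    sample_prefix: str = "S",
) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Diploid genotypes: each sample is the sum of two haplotypes drawn
    with replacement from the pool.

    For a stratified pool each sample is first assigned a subpopulation
    (fair coin) and draws both haplotypes within it; the per-sample
    labels are returned alongside (None for an unstructured pool).
    """
    if pool.n_haplotypes == 0:
        raise ValueError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    labels = None
    if pool.subpop is None:
        idx = rng.integers(0, pool.n_haplotypes, size=(n_samples, 2))
    else:
        labels = rng.integers(0, 2, size=n_samples)
        members = [np.where(pool.subpop == s)[0] for s in (0, 1)]
        idx = np.empty((n_samples, 2), dtype=int)
        for s in (0, 1):
            rows = labels == s
            idx[rows] = members[s][rng.integers(0, members[s].size, size=(rows.sum(), 2))]
    dosages = (pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]).astype(float)
    G = GenotypeMatrix(
        dosages=dosages,
        snp_meta=pool.snp_meta.copy(),
        sample_ids=[f"{sample_prefix}{i + 1:05d}" for i in range(n_samples)],
    )
    return G, labels


def simulate_covariates(
    n_samples: int,
    seed: int | np.random.SeedSequence,
    sample_ids: list[str],
) -> pd.DataFrame:
    """Age, sex and pack-years with the expression cohort's moments:
    age ~ N(64.9, 5.5), sex ~ Bernoulli(0.664) (1 = male),
    pack-years ~ N(46.8, 28.3) truncated at 0."""
    rng = np.random.default_rng(seed)
    age = rng.normal(64.9, 5.5, size=n_samples)
    sex = (rng.random(n_samples) < 0.664).astype(float)
    pack = np.maximum(rng.normal(46.8, 28.3, size=n_samples), 0.0)
    return pd.DataFrame(
        {"sample_id": sample_ids, "age": age, "sex": sex, "pack_years": pack}
    )


def _resolve_probe(annotation: pd.DataFrame, snp_pos: int, chrom: str) -> pd.Series:
    """Probe whose TSS is closest to the SNP on the same chromosome."""
    cand = annotation[annotation["chrom"] == chrom]
    if cand.empty:
        raise ValueError(f"no probe on chromosome {chrom}")
    return cand.loc[(cand["tss"] - snp_pos).abs().idxmin()]


def simulate_expression(
    G: GenotypeMatrix,
    annotation: pd.DataFrame,
    cis_effects: dict[str, float],
    covariates: pd.DataFrame,
    covariate_effects: dict[str, float],
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    cis_window_bp: int = 50_000,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Expression = baseline + beta * dosage + covariate terms + N(0, sd²).

    Each planted SNP acts on the probe whose TSS is nearest; a planted SNP
    farther than ``cis_window_bp`` from that TSS is rejected (it would be
    undetectable by the scan's design).
    """
    rng = np.random.default_rng(seed)
    n = G.n_samples
    probes = annotation["probe_id"].tolist()
    baseline = rng.normal(7.0, 0.5, size=len(probes))
    E = np.tile(baseline, (n, 1)) + rng.normal(0.0, noise_sd, size=(n, len(probes)))

    cov_term = np.zeros(n)
    for name, coef in covariate_effects.items():
        cov_term = cov_term + coef * covariates[name].to_numpy()
    E += cov_term[:, None]

    meta_idx = {s: i for i, s in enumerate(G.snp_meta["snp_id"])}
    planted: list[tuple[str, str, float]] = []
    for snp_id, beta in cis_effects.items():
        if snp_id not in meta_idx:
            raise ValueError(f"planted SNP {snp_id!r} absent from genotype panel")
        row = G.snp_meta.iloc[meta_idx[snp_id]]
        probe = _resolve_probe(annotation, int(row["pos"]), str(row["chrom"]))
        if abs(int(row["pos"]) - int(probe["tss"])) > cis_window_bp:
            raise ValueError(
                f"planted SNP {snp_id!r} lies outside the {cis_window_bp} bp cis window "
                f"of its nearest probe {probe['probe_id']!r}"
            )
        j = probes.index(probe["probe_id"])
        E[:, j] += beta * G.dosages[:, meta_idx[snp_id]]
        planted.append((snp_id, str(probe["probe_id"]), float(beta)))

    expr = ExpressionMatrix(values=E, probe_ids=probes, sample_ids=list(G.sample_ids))
    truth = SimTruth(
        planted_cis=planted,
        planted_disease=[],
        covariate_effects={"expression": dict(covariate_effects)},
    )
    return expr, truth


def simulate_case_control(
    G: GenotypeMatrix,
    disease_log_odds: dict[str, float],
    covariates: pd.DataFrame,
    covariate_effects: dict[str, float],
    baseline_log_odds: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Binary phenotype with P(case) = logistic(baseline + Σ γ·dosage + covariates)."""
    rng = np.random.default_rng(seed)
    eta = np.full(G.n_samples, baseline_log_odds, dtype=float)
    meta_idx = {s: i for i, s in enumerate(G.snp_meta["snp_id"])}
    for snp_id, gamma in disease_log_odds.items():
        if snp_id not in meta_idx:
            raise ValueError(f"planted disease SNP {snp_id!r} absent from genotype panel")
        eta += gamma * G.dosages[:, meta_idx[snp_id]]
    for name, coef in covariate_effects.items():
        eta += coef * covariates[name].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(G.n_samples) < p).astype(float)


@dataclass
class Study:
    """One simulated case-control cohort."""

    label: str
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    phenotype: np.ndarray


@dataclass
class StudyBundle:
    """Everything one pipeline run consumes, drawn from a shared SNP panel."""

    config: SimConfig
    pool: HaplotypePool
    annotation: pd.DataFrame
    expr_genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    expr_covariates: pd.DataFrame
    studies: list[Study]
    replication_studies: list[Study]
    truth: SimTruth


def _centered_baseline(
    G: GenotypeMatrix,
    disease_log_odds: dict[str, float],
    covariates: pd.DataFrame,
    covariate_effects: dict[str, float],
    target_fraction: float,
) -> float:
    """Baseline log-odds so the realized case fraction tracks the design's."""
    eta = np.zeros(G.n_samples)
    meta_idx = {s: i for i, s in enumerate(G.snp_meta["snp_id"])}
    for snp_id, gamma in disease_log_odds.items():
        eta += gamma * G.dosages[:, meta_idx[snp_id]]
    for name, coef in covariate_effects.items():
        eta += coef * covariates[name].to_numpy()
    return float(np.log(target_fraction / (1 - target_fraction)) - eta.mean())


def _make_study(
    cfg: SimConfig,
    pool: HaplotypePool,
    label: str,
    n_cases: int,
    n_controls: int,
    slot: int,
) -> Study:
    n = n_cases + n_controls
    seq = np.random.SeedSequence(cfg.master_seed, spawn_key=(slot,))
    geno_seed, cov_seed, pheno_seed = seq.spawn(3)
    G, _ = simulate_genotypes(pool, n, geno_seed, sample_prefix=f"{label}_")
    cov = simulate_covariates(n, cov_seed, G.sample_ids)
    baseline = _centered_baseline(
        G, cfg.disease_log_odds, cov, cfg.disease_covariate_effects, n_cases / n
    )
    y = simulate_case_control(
        G, cfg.disease_log_odds, cov, cfg.disease_covariate_effects, baseline, pheno_seed
    )
    return Study(label=label, genotypes=G, covariates=cov, phenotype=y)


def generate_study_bundle(cfg: SimConfig) -> StudyBundle:
    """Simulate the full study: one shared SNP panel, an expression cohort,
    the discovery case-control studies and the replication studies."""
    pool = simulate_haplotype_pool(cfg)
    annotation = cfg.probe_annotation()

    G_expr, _ = simulate_genotypes(
        pool,
        cfg.n_expression_samples,
        np.random.SeedSequence(cfg.master_seed, spawn_key=(_EXPR_GENO,)),
        sample_prefix="EXPR_",
    )
    cov_expr = simulate_covariates(
        cfg.n_expression_samples,
        np.random.SeedSequence(cfg.master_seed, spawn_key=(_EXPR_COV,)),
        G_expr.sample_ids,
    )
    expr, truth = simulate_expression(
        G_expr,
        annotation,
        cfg.cis_effect_sizes,
        cov_expr,
        cfg.expr_covariate_effects,
        cfg.noise_sd,
        np.random.SeedSequence(cfg.master_seed, spawn_key=(_EXPR_NOISE,)),
        cis_window_bp=cfg.cis_window_bp,
    )
    truth.planted_disease = [(s, float(g)) for s, g in cfg.disease_log_odds.items()]
    truth.covariate_effects["disease"] = dict(cfg.disease_covariate_effects)

    studies = [
        _make_study(cfg, pool, f"DISC{i + 1}", nc, nk, _STUDY_BASE + i)
        for i, (nc, nk) in enumerate(cfg.study_sizes)
    ]
    replication = [
        _make_study(cfg, pool, f"REPL{i + 1}", nc, nk, _STUDY_BASE + 50 + i)
        for i, (nc, nk) in enumerate(cfg.replication_study_sizes)
    ]
    return StudyBundle(
        config=cfg,
        pool=pool,
        annotation=annotation,
        expr_genotypes=G_expr,
        expression=expr,
        expr_covariates=cov_expr,
        studies=studies,
        replication_studies=replication,
        truth=truth,
    )
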