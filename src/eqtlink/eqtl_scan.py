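"""Stage 1: probe/SNP filtering, cis-pair enumeration, the covariate-adjusted
cis-eQTL scan, and FDR-based significance summaries.

The scan regresses each probe set's expression on each nearby SNP's additive
dosage, adjusted for age, sex and genotype-derived ancestry principal
components, then applies a single Benjamini-Hochberg adjustment jointly over
all tested SNP-probe pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc_core import (
    ExpressionMatrix,
    GenotypeMatrix,
    PipelineConfig,
    bh_adjust,
    compute_maf,
    ols_assoc,
)

__all__ = [
    "filter_probes",
    "filter_snps",
    "enumerate_cis_pairs",
    "run_cis_scan",
    "summarize_eqtls",
]

EQTL_COLUMNS = [
    "snp_id", "chrom", "pos", "probe_id", "gene_symbol",
    "beta", "se", "t", "p", "df", "n_used", "flag", "fdr_p",
]

_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24"}


def filter_probes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop probes without a gene symbol and probes on the X or Y chromosome.

    Mirrors standard microarray probe filtering before eQTL analysis;
    order is preserved.
    """
    sym = annotation["gene_symbol"]
    has_gene = sym.notna() & (sym.astype(str).str.strip() != "")
    autosomal = ~annotation["chrom"].astype(str).isin(_SEX_CHROMS)
    return annotation[has_gene & autosomal].reset_index(drop=True)


def filter_snps(G: GenotypeMatrix, maf_min: float = 0.05) -> list[str]:
    """SNP ids with MAF >= maf_min in this cohort (boundary inclusive:
    only MAF < maf_min is excluded)."""
    kept = []
    for j, snp_id in enumerate(G.snp_meta["snp_id"]):
        col = G.dosages[:, j]
        if np.isnan(col).all():
            continue
        if compute_maf(col) >= maf_min:
            kept.append(str(snp_id))
    return kept


def enumerate_cis_pairs(
    snp_meta: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int,
) -> pd.DataFrame:
    """All SNP-probe pairs with |pos - TSS| <= window_bp on the same
    chromosome (boundary inclusive).

    Distance is signed and strand-oriented: positive means downstream of
    the TSS in the gene's direction of transcription. Output order is
    (chrom, tss, probe_id, pos, snp_id) for determinism.
    """
    rows = []
    snp_by_chrom = dict(tuple(snp_meta.groupby(snp_meta["chrom"].astype(str))))
    for probe in annotation.itertuples(index=False):
        snps = snp_by_chrom.get(str(probe.chrom))
        if snps is None:
            continue
        delta = snps["pos"].to_numpy() - int(probe.tss)
        near = np.abs(delta) <= window_bp
        sign = 1 if probe.strand != "-" else -1
        for snp_id, pos, d in zip(
            snps["snp_id"].to_numpy()[near], snps["pos"].to_numpy()[near], delta[near]
        ):
            rows.append(
                {
                    "snp_id": snp_id,
                    "probe_id": probe.probe_id,
                    "gene_symbol": probe.gene_symbol,
                    "chrom": str(probe.chrom),
                    "tss": int(probe.tss),
                    "pos": int(pos),
                    "distance": int(sign * d),
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["snp_id", "probe_id", "gene_symbol", "chrom", "tss", "pos", "distance"]
    )
    if len(pairs):
        pairs = pairs.sort_values(
            ["chrom", "tss", "probe_id", "pos", "snp_id"], kind="stable"
        ).reset_index(drop=True)
    return pairs


def _scan_dense(
    Y: np.ndarray, Gd: np.ndarray, C: np.ndarray, probe_idx: np.ndarray, snp_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized per-pair OLS via Frisch-Waugh when no data are missing.

    Residualizes expression and dosage on [1, C] once, then computes each
    pair's genotype coefficient, SE and t with df = n - n_columns of the
    full design. Equivalent to per-pair ``ols_assoc`` (tested property).
    """
    n = Y.shape[0]
    X = np.column_stack([np.ones(n), C]) if C.size else np.ones((n, 1))
    Q, _ = np.linalg.qr(X)
    Yr = Y - Q @ (Q.T @ Y)
    Gr = Gd - Q @ (Q.T @ Gd)
    df = n - X.shape[1] - 1
    gg = np.einsum("ij,ij->j", Gr, Gr)
    yy = np.einsum("ij,ij->j", Yr, Yr)
    gy_pairs = np.einsum("ij,ij->j", Gr[:, snp_idx], Yr[:, probe_idx])
    gg_p = gg[snp_idx]
    yy_p = yy[probe_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy_pairs / gg_p
        rss = yy_p - beta * gy_pairs
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / gg_p)
        t = beta / se
    return beta, se, t, gg_p, df


def run_cis_scan(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    covariates: np.ndarray | pd.DataFrame,
    pairs: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted linear association for every cis pair.

    Returns one row per pair with the genotype coefficient, SE, t, p and
    the jointly BH-adjusted p-value; degenerate tests (e.g. zero-variance
    dosage) are carried with a flag and excluded from the FDR input.
    """
    from scipy import stats as _st

    cfg = cfg or PipelineConfig()
    if len(pairs) == 0:
        return pd.DataFrame(columns=EQTL_COLUMNS)
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]

    snp_pos = {s: i for i, s in enumerate(G.snp_meta["snp_id"])}
    probe_pos = {p: i for i, p in enumerate(E.probe_ids)}
    snp_idx = pairs["snp_id"].map(snp_pos).to_numpy()
    probe_idx = pairs["probe_id"].map(probe_pos).to_numpy()

    complete = (
        not np.isnan(G.dosages).any()
        and not np.isnan(E.values).any()
        and not np.isnan(C).any()
    )
    records = pairs[["snp_id", "chrom", "pos", "probe_id", "gene_symbol"]].copy()
    if complete:
        beta, se, t, gg, df = _scan_dense(E.values, G.dosages, C, probe_idx, snp_idx)
        ok = gg > 1e-12
        with np.errstate(invalid="ignore"):
            p = 2.0 * _st.t.sf(np.abs(t), df)
        records["beta"] = np.where(ok, beta, np.nan)
        records["se"] = np.where(ok, se, np.nan)
        records["t"] = np.where(ok, t, np.nan)
        records["p"] = np.where(ok, p, np.nan)
        records["df"] = df
        records["n_used"] = G.n_samples
        records["flag"] = np.where(ok, "", "degenerate")
    else:
        stats_rows = []
        for si, pi in zip(snp_idx, probe_idx):
            st = ols_assoc(E.values[:, pi], G.dosages[:, si], C)
            stats_rows.append((st.effect, st.se, st.statistic, st.p, st.df, st.n_used, st.flag))
        arr = pd.DataFrame(
            stats_rows, columns=["beta", "se", "t", "p", "df", "n_used", "flag"]
        )
        records = pd.concat([records.reset_index(drop=True), arr], axis=1)

    tested = records["flag"].isin(["", "underflow"]) & records["p"].notna()
    fdr = np.full(len(records), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = bh_adjust(records.loc[tested, "p"].to_numpy())
    records["fdr_p"] = fdr
    return records[EQTL_COLUMNS]


def summarize_eqtls(
    records: pd.DataFrame,
    fdr_alpha: float = 0.05,
    gene_column: str = "gene_symbol",
) -> dict:
    """Counts of significant cis associations at FDR < fdr_alpha.

    Returns n_tests, n_significant_pairs, unique SNP/probe/gene counts and
    the maximum raw p among significant pairs (the implied raw-p cutoff;
    NaN when nothing is significant).
    """
    tested = records[records["fdr_p"].notna()]
    sig = tested[tested["fdr_p"] < fdr_alpha]
    return {
        "n_tests": int(len(tested)),
        "n_significant_pairs": int(len(sig)),
        "n_unique_snps": int(sig["snp_id"].nunique()),
        "n_unique_probes": int(sig["probe_id"].nunique()),
        "n_unique_genes": int(sig[gene_column].nunique()),
        "max_raw_p_among_significant": float(sig["p"].max()) if len(sig) else float("nan"),
    }
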