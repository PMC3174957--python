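"""Statistical primitives shared by every pipeline stage.

Covariate-adjusted linear and logistic association on additive SNP dosages,
multiple-testing corrections (Benjamini-Hochberg step-up, Bonferroni),
fixed-effects inverse-variance meta-analysis, composite (genotype) LD r²,
minor allele frequency, genotype-based ancestry principal components, and
quantile normalization of expression matrices.

All functions are pure and operate on in-memory numpy/pandas objects; file
I/O lives in :mod:`eqtlink.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "AssocStats",
    "PipelineConfig",
    "compute_maf",
    "ols_assoc",
    "logistic_assoc",
    "bh_adjust",
    "bonferroni_threshold",
    "fixed_effects_meta",
    "weighted_z_meta",
    "ld_r2",
    "ld_prune",
    "genotype_pcs",
    "quantile_normalize",
]

#: smallest positive double; p-values are floored here, never reported as 0
P_FLOOR = np.nextafter(0.0, 1.0)

SNP_META_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")


class DegenerateTestError(ValueError):
    """Raised when an association test cannot be computed (rank deficiency,
    missing data, monomorphic genotype)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with SNP metadata.

    Dosages count copies of the alt allele: values in {0, 1, 2}, with NaN
    for missing. ``snp_meta`` is a DataFrame with columns
    (snp_id, chrom, pos, ref, alt); positions are 1-based.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x snps)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["snp_id"].tolist()

    def column(self, snp_id: str) -> np.ndarray:
        idx = self._index().get(snp_id)
        if idx is None:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return self.dosages[:, idx]

    def _index(self) -> dict[str, int]:
        cache = getattr(self, "_idx_cache", None)
        if cache is None or len(cache) != self.n_snps:
            cache = {s: i for i, s in enumerate(self.snp_meta["snp_id"])}
            self._idx_cache = cache
        return cache

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self._index()
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(
            dosages=self.dosages[:, cols],
            snp_meta=self.snp_meta.iloc[cols].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            dosages=self.dosages[rows, :],
            snp_meta=self.snp_meta.copy(),
            sample_ids=[self.sample_ids[i] for i in rows],
        )


@dataclass
class ExpressionMatrix:
    """Samples x probe sets matrix of normalized log2-scale expression."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.probe_ids) != m:
            raise ValueError("expression dimensions do not match ids")
        if len(set(self.probe_ids)) != m:
            raise ValueError("duplicate probe ids")

    def column(self, probe_id: str) -> np.ndarray:
        return self.values[:, self.probe_ids.index(probe_id)]


@dataclass
class AssocStats:
    """One association test result.

    ``effect`` is the per-allele coefficient (expression units for linear
    models, log-odds for logistic); ``statistic`` is t (with ``df``) or z
    (``df`` is None). ``flag`` is empty for clean fits, otherwise one of
    ``degenerate`` / ``separation`` / ``underflow``; flagged fits carry
    NaN for the undefined fields.
    """

    effect: float
    se: float
    statistic: float
    p: float
    df: int | None
    n_used: int
    flag: str = ""

    @property
    def ok(self) -> bool:
        return self.flag in ("", "underflow")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.effect))


@dataclass
class PipelineConfig:
    """Thresholds and window sizes driving the full pipeline."""

    cis_window_bp: int = 50_000
    expanded_window_bp: int = 200_000
    maf_min: float = 0.05
    fdr_alpha: float = 0.05
    fwer_alpha: float = 0.05
    nominal_p: float = 0.01
    replication_p: float = 0.1
    n_pcs: int = 6
    pca_ld_prune_r2: float | None = 0.2
    ld_bin_r2_min: float = 0.80
    moderate_ld_range: tuple[float, float] = (0.50, 0.80)
    meta_method: str = "ivw"  # "ivw" (on effects) or "weighted_z"
    require_direction_consistency: bool = True
    exclude_bonferroni_from_replication: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "fdr_alpha", "fwer_alpha", "nominal_p", "replication_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.cis_window_bp <= 0 or self.expanded_window_bp <= 0:
            raise ValueError("windows must be positive")
        if not 0 < self.ld_bin_r2_min <= 1:
            raise ValueError("ld_bin_r2_min must lie in (0, 1]")
        lo, hi = self.moderate_ld_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("moderate_ld_range must be an increasing pair in [0, 1]")
        if self.meta_method not in ("ivw", "weighted_z"):
            raise ValueError("meta_method must be 'ivw' or 'weighted_z'")


# ---------------------------------------------------------------------------
# allele frequency


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of a dosage vector, ignoring missing values.

    maf = min(f, 1-f) with f = sum(dosage) / (2 * n_nonmissing).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise DegenerateTestError("MAF undefined: all dosages missing")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


# ---------------------------------------------------------------------------
# linear association


def _design(g: np.ndarray | None, C: np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    if g is not None:
        cols.append(g)
    if C is not None and C.size:
        cols.append(C if C.ndim == 2 else C[:, None])
    return np.column_stack(cols)


def _complete_rows(*arrays: np.ndarray | None) -> np.ndarray:
    mask = None
    for a in arrays:
        if a is None:
            continue
        m = ~np.isnan(a) if a.ndim == 1 else ~np.isnan(a).any(axis=1)
        mask = m if mask is None else (mask & m)
    return mask


def ols_assoc(
    y: np.ndarray,
    g: np.ndarray | None,
    C: np.ndarray | None = None,
) -> AssocStats:
    """Ordinary least squares of y on [1, g, C]; reports the genotype term.

    Pairwise-complete: samples missing any of y, g or a covariate are
    dropped. The p-value is two-sided from the t distribution with
    df = n_used - n_columns. With ``g=None`` the intercept is reported
    (used for degenerate-case bookkeeping and tests).
    """
    y = np.asarray(y, dtype=float)
    g = None if g is None else np.asarray(g, dtype=float)
    C = None if C is None else np.asarray(C, dtype=float)
    mask = _complete_rows(y, g, C)
    y = y[mask]
    g = None if g is None else g[mask]
    Cm = None if C is None else (C[mask] if C.ndim == 2 else C[mask])
    n = y.size
    X = _design(g, Cm, n)
    k = X.shape[1]
    if n <= k:
        return AssocStats(np.nan, np.nan, np.nan, np.nan, None, n, flag="degenerate")
    if np.linalg.matrix_rank(X) < k:
        return AssocStats(np.nan, np.nan, np.nan, np.nan, None, n, flag="degenerate")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    j = 1 if g is not None else 0
    eff = float(beta[j])
    se = float(np.sqrt(sigma2 * XtX_inv[j, j]))
    if se == 0.0:
        # exact fit: coefficient defined, inference degenerate
        return AssocStats(eff, 0.0, np.inf if eff else 0.0, P_FLOOR if eff else 1.0,
                          df, n, flag="underflow" if eff else "")
    t = eff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    flag = ""
    if p <= 0.0:
        p, flag = P_FLOOR, "underflow"
    return AssocStats(eff, se, float(t), float(p), df, n, flag=flag)


# ---------------------------------------------------------------------------
# logistic association


def logistic_assoc(
    y: np.ndarray,
    g: np.ndarray | None,
    C: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> AssocStats:
    """Maximum-likelihood logistic regression of a binary outcome on
    [1, g, C] via iteratively reweighted least squares.

    Reports the genotype log-odds coefficient with its Wald SE, z and
    two-sided normal p; OR = exp(effect). Non-convergence or a coefficient
    running past |15| raises the ``separation`` flag with p missing.
    """
    y = np.asarray(y, dtype=float)
    g = None if g is None else np.asarray(g, dtype=float)
    C = None if C is None else np.asarray(C, dtype=float)
    mask = _complete_rows(y, g, C)
    y = y[mask]
    g = None if g is None else g[mask]
    Cm = None if C is None else (C[mask] if C.ndim == 2 else C[mask])
    n = y.size
    if n == 0 or len(np.unique(y)) < 2:
        return AssocStats(np.nan, np.nan, np.nan, np.nan, None, n, flag="degenerate")
    X = _design(g, Cm, n)
    k = X.shape[1]
    if n <= k or np.linalg.matrix_rank(X) < k:
        return AssocStats(np.nan, np.nan, np.nan, np.nan, None, n, flag="degenerate")

    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z_work = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z_work))
        except np.linalg.LinAlgError:
            return AssocStats(np.nan, np.nan, np.nan, np.nan, None, n, flag="separation")
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    j = 1 if g is not None else 0
    if not converged or abs(beta[j]) > 15.0:
        return AssocStats(float(beta[j]), np.nan, np.nan, np.nan, None, n, flag="separation")
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    eff = float(beta[j])
    se = float(np.sqrt(cov[j, j]))
    z = eff / se
    p = 2.0 * stats.norm.sf(abs(z))
    flag = ""
    if p <= 0.0:
        p, flag = P_FLOOR, "underflow"
    return AssocStats(eff, se, float(z), float(p), None, n, flag=flag)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; adjusted >= raw.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("test count must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# meta-analysis


@dataclass
class MetaRecord:
    """Fixed-effects combined association for one SNP."""

    effect: float
    se: float
    z: float
    p: float
    n_studies: int


def fixed_effects_meta(effects: Sequence[float], ses: Sequence[float]) -> MetaRecord:
    """Inverse-variance-weighted fixed-effects combination.

    w_i = 1/se_i^2; combined effect = sum(w*b)/sum(w); se = sum(w)^(-1/2).
    """
    eff = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    keep = ~(np.isnan(eff) | np.isnan(se)) & (se > 0)
    eff, se = eff[keep], se[keep]
    if eff.size == 0:
        raise DegenerateTestError("no usable studies for meta-analysis")
    w = 1.0 / se**2
    effect = float((w * eff).sum() / w.sum())
    se_meta = float(1.0 / np.sqrt(w.sum()))
    z = effect / se_meta
    p = max(2.0 * stats.norm.sf(abs(z)), P_FLOOR)
    return MetaRecord(effect, se_meta, float(z), float(p), int(eff.size))


def weighted_z_meta(
    effects: Sequence[float], ses: Sequence[float], ns: Sequence[float] | None = None
) -> MetaRecord:
    """Stouffer combination of per-study z-scores weighted by 1/se.

    Alternative reading of "combined using Z-scores for weighting by the
    inverse variance"; the combined effect/se are back-formed on the IVW
    scale so downstream consumers see a common record shape.
    """
    eff = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    keep = ~(np.isnan(eff) | np.isnan(se)) & (se > 0)
    eff, se = eff[keep], se[keep]
    if eff.size == 0:
        raise DegenerateTestError("no usable studies for meta-analysis")
    z_i = eff / se
    w = 1.0 / se  # weight proportional to precision^(1/2) -> z scale
    z = float((w * z_i).sum() / np.sqrt((w**2).sum()))
    ivw = fixed_effects_meta(eff, se)
    p = max(2.0 * stats.norm.sf(abs(z)), P_FLOOR)
    return MetaRecord(ivw.effect, ivw.se, z, float(p), int(eff.size))


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosages.

    Computed on pairwise-complete samples; requires >= 3 of them and both
    SNPs polymorphic among them. Symmetric and invariant to allele flips
    (g -> 2-g).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[mask], g2[mask]
    if a.size < 3:
        raise DegenerateTestError("LD undefined: fewer than 3 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateTestError("LD undefined: monomorphic SNP")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


# ---------------------------------------------------------------------------
# ancestry principal components


def genotype_pcs(G: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k genotype principal-component scores (samples x k).

    Missing dosages are mean-imputed per SNP; each SNP is centered and
    scaled by sqrt(2 p (1-p)) with p its alt-allele frequency; scores are
    the left singular vectors scaled by their singular values. Monomorphic
    SNPs are dropped. Signs of the columns are arbitrary.
    """
    D = G.dosages.copy()
    col_mean = np.nanmean(D, axis=0)
    nan_r, nan_c = np.where(np.isnan(D))
    D[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateTestError("no polymorphic SNPs for PCA")
    D = D[:, poly]
    p = p[poly]
    if k > min(G.n_samples - 1, D.shape[1]):
        raise ValueError("k exceeds the available rank")
    Z = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z = Z - Z.mean(axis=0)  # guard against residual column means after imputation
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return U[:, :k] * s[:k]


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.2) -> list[str]:
    """Greedy LD pruning: walk SNPs in genomic order, keep a SNP only if
    its r² with every previously kept SNP stays below ``r2_max``.

    Ancestry PCA is computed on a pruned panel so the leading components
    reflect sample structure rather than local haplotype blocks.
    Monomorphic SNPs are dropped.
    """
    order = G.snp_meta.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    kept_cols: list[int] = []
    for j in order:
        g = G.dosages[:, j]
        nm = g[~np.isnan(g)]
        if nm.size < 3 or np.ptp(nm) == 0:
            continue
        try:
            if all(ld_r2(g, G.dosages[:, k]) < r2_max for k in kept_cols):
                kept_cols.append(int(j))
        except DegenerateTestError:
            continue
    ids = G.snp_meta["snp_id"]
    return [str(ids.iloc[k]) for k in kept_cols]


# ---------------------------------------------------------------------------
# normalization


def quantile_normalize(E: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a values-by-sample layout.

    Accepts samples-in-columns: every column's values are replaced by the
    mean order-statistic profile at that column's ranks; ties receive the
    mean of their target values. Afterwards all columns share one sorted
    value multiset. A single column is returned unchanged.
    """
    E = np.asarray(E, dtype=float)
    if np.isnan(E).any():
        raise ValueError("quantile normalization requires complete data")
    n_rows, n_cols = E.shape
    if n_cols < 2:
        return E.copy()
    target = np.sort(E, axis=0).mean(axis=1)
    out = np.empty_like(E)
    for j in range(n_cols):
        ranks = stats.rankdata(E[:, j], method="average")  # 1-based, ties averaged
        # interpolate the target profile at (possibly fractional) tie ranks
        out[:, j] = np.interp(ranks, np.arange(1, n_rows + 1), target)
    return out
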