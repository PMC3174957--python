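"""Unit and property tests for the statistical primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eqtlink.assoc_core import (
    DegenerateTestError,
    GenotypeMatrix,
    PipelineConfig,
    bh_adjust,
    bonferroni_threshold,
    compute_maf,
    fixed_effects_meta,
    genotype_pcs,
    ld_prune,
    ld_r2,
    logistic_assoc,
    ols_assoc,
    quantile_normalize,
    weighted_z_meta,
)


def _geno(rng, n, m, maf_lo=0.1, maf_hi=0.5):
    p = rng.uniform(maf_lo, maf_hi, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(float)
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(d, meta, [f"I{i}" for i in range(n)])


# ---------------------------------------------------------------------- MAF


@pytest.mark.parametrize(
    "dosages, expected",
    [
        ([0, 0, 1, 1], 0.25),
        ([2, 2, 2, 2], 0.0),
        ([0, 1, 2, np.nan], 0.5),
        ([0, 0, 0, 0], 0.0),
    ],
)
def test_maf_counts_minor_allele(dosages, expected):
    assert compute_maf(np.array(dosages, dtype=float)) == pytest.approx(expected)


def test_maf_all_missing_is_an_error():
    with pytest.raises(DegenerateTestError):
        compute_maf(np.array([np.nan, np.nan]))


# ---------------------------------------------------------------------- OLS


def test_ols_intercept_only_returns_mean():
    st_ = ols_assoc(np.array([1.0, 2.0, 3.0]), None)
    assert st_.effect == pytest.approx(2.0)


def test_ols_exact_fit_recovers_slope():
    g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
    st_ = ols_assoc(2.0 * g, g)
    assert st_.effect == pytest.approx(2.0)


def test_ols_zero_variance_genotype_flagged():
    st_ = ols_assoc(np.array([1.0, 2.0, 3.0, 4.0]), np.zeros(4))
    assert st_.flag == "degenerate" and np.isnan(st_.p)


def test_ols_pairwise_complete_drops_missing_rows(rng):
    y = rng.normal(size=30)
    g = rng.binomial(2, 0.3, size=30).astype(float)
    C = rng.normal(size=(30, 2))
    y_miss = y.copy()
    y_miss[:5] = np.nan
    full = ols_assoc(y[5:], g[5:], C[5:])
    part = ols_assoc(y_miss, g, C)
    assert part.n_used == 25
    assert part.effect == pytest.approx(full.effect)
    assert part.p == pytest.approx(full.p)


def test_ols_null_pvalues_are_uniform(rng):
    """Under the null with Gaussian noise, OLS p-values are U(0,1)."""
    n, reps = 40, 5000
    pvals = np.empty(reps)
    for i in range(reps):
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.3, size=n).astype(float)
        while np.ptp(g) == 0:
            g = rng.binomial(2, 0.3, size=n).astype(float)
        pvals[i] = ols_assoc(y, g).p
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ----------------------------------------------------------------- logistic


def test_logistic_intercept_only_is_log_odds():
    st_ = logistic_assoc(np.array([1.0, 1.0, 1.0, 0.0]), None)
    assert st_.effect == pytest.approx(np.log(3.0), abs=1e-6)


def test_logistic_matches_closed_form_2x2():
    y = np.concatenate([np.ones(100), np.zeros(100)])
    g = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
    st_ = logistic_assoc(y, g)
    assert st_.effect == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-7)
    assert st_.se == pytest.approx(np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90), abs=1e-7)


def test_logistic_flags_perfect_separation():
    y = np.array([0.0, 0, 0, 1, 1, 1])
    g = np.array([0.0, 0, 0, 2, 2, 2])
    st_ = logistic_assoc(y, g)
    assert st_.flag == "separation" and np.isnan(st_.p)


def test_logistic_single_class_degenerate():
    assert logistic_assoc(np.ones(10), np.arange(10, dtype=float)).flag == "degenerate"


# ----------------------------------------------------------- multiple testing


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.03], [0.03]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ],
)
def test_bh_adjust_examples(p, expected):
    np.testing.assert_allclose(bh_adjust(np.array(p)), expected)


def test_bh_adjust_empty():
    assert bh_adjust(np.array([])).size == 0


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=40)
)
def test_bh_adjust_matches_statsmodels_and_dominates_raw(ps):
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(ps)
    adj = bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(adj, ref, rtol=1e-12, atol=1e-15)
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


def test_bh_controls_false_discovery_proportion(rng):
    """Realized FDP over replicates of a null/signal mixture stays near alpha."""
    alpha, reps = 0.05, 200
    fdp = []
    for _ in range(reps):
        z = np.concatenate([rng.normal(0, 1, 150), rng.normal(4, 1, 50)])
        is_null = np.arange(200) < 150
        p = 2 * stats.norm.sf(np.abs(z))
        rej = bh_adjust(np.clip(p, 1e-300, 1)) < alpha
        fdp.append(rej[is_null].sum() / max(rej.sum(), 1))
    fdp = np.asarray(fdp)
    se = fdp.std(ddof=1) / np.sqrt(reps)
    assert fdp.mean() <= alpha + 3 * se


@pytest.mark.parametrize(
    "alpha, m, expected", [(0.05, 1, 0.05), (0.05, 5, 0.01), (0.05, 3309, 1.5e-5)]
)
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=0.05)


def test_bonferroni_rejects_zero_tests():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


# ------------------------------------------------------------- meta-analysis


def test_meta_single_study_passthrough():
    rec = fixed_effects_meta([0.3], [0.1])
    assert (rec.effect, rec.se) == (pytest.approx(0.3), pytest.approx(0.1))
    assert rec.z == pytest.approx(3.0)


def test_meta_self_duplication_shrinks_se_by_sqrt2():
    one = fixed_effects_meta([0.3], [0.1])
    two = fixed_effects_meta([0.3, 0.3], [0.1, 0.1])
    assert two.effect == pytest.approx(one.effect)
    assert two.se == pytest.approx(one.se / np.sqrt(2))
    assert two.z == pytest.approx(one.z * np.sqrt(2))


def test_meta_weight_formula():
    rec = fixed_effects_meta([0.2, 0.4], [0.1, 0.2])
    assert rec.effect == pytest.approx(0.24)
    assert rec.se == pytest.approx(1 / np.sqrt(125))
    assert rec.z == pytest.approx(2.683, abs=1e-3)


def test_meta_skips_degenerate_studies():
    rec = fixed_effects_meta([0.2, np.nan], [0.1, np.nan])
    assert rec.n_studies == 1
    with pytest.raises(DegenerateTestError):
        fixed_effects_meta([np.nan], [np.nan])


def test_weighted_z_equal_ses_matches_stouffer():
    rec = weighted_z_meta([0.2, 0.4], [0.1, 0.1])
    assert rec.z == pytest.approx((2.0 + 4.0) / np.sqrt(2))


# ----------------------------------------------------------------------- LD


def test_ld_r2_self_and_flip(rng):
    g = rng.binomial(2, 0.3, 100).astype(float)
    assert ld_r2(g, g) == pytest.approx(1.0)
    assert ld_r2(g, 2.0 - g) == pytest.approx(1.0)


def test_ld_r2_monomorphic_is_undefined():
    with pytest.raises(DegenerateTestError):
        ld_r2(np.zeros(10), np.arange(10, dtype=float) % 3)


def test_ld_prune_output_is_mutually_unlinked(rng):
    G = _geno(rng, 200, 30)
    # duplicate a column to force pruning
    G.dosages[:, 1] = G.dosages[:, 0]
    kept = ld_prune(G, 0.2)
    cols = [G.column(s) for s in kept]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            assert ld_r2(cols[i], cols[j]) < 0.2


# ----------------------------------------------------------------------- PCA


def test_pcs_require_polymorphic_snps():
    meta = pd.DataFrame(
        {"snp_id": ["a"], "chrom": "1", "pos": [1], "ref": "A", "alt": "G"}
    )
    G = GenotypeMatrix(np.zeros((5, 1)), meta, [f"I{i}" for i in range(5)])
    with pytest.raises(DegenerateTestError):
        genotype_pcs(G, 1)


def test_pcs_columns_are_centered(rng):
    G = _geno(rng, 80, 40)
    scores = genotype_pcs(G, 4)
    assert np.abs(scores.mean(axis=0)).max() < 1e-8


def test_pcs_match_full_svd_oracle(rng):
    G = _geno(rng, 50, 20)
    scores = genotype_pcs(G, 5)
    # independent oracle: explicit standardization + full SVD
    D = G.dosages
    p = D.mean(axis=0) / 2
    Z = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Z)
    ref = U[:, :5] * s[:5]
    for k in range(5):
        sign = np.sign(scores[:, k] @ ref[:, k]) or 1.0
        np.testing.assert_allclose(scores[:, k], sign * ref[:, k], atol=1e-8)


def test_pc1_separates_divergent_subpopulations(rng):
    n, m, div = 200, 200, 0.3
    labels = rng.integers(0, 2, n)
    base = rng.uniform(0.2, 0.5, m)
    freq = np.where(labels[:, None] == 0, base - div / 2, base + div / 2)
    D = rng.binomial(2, np.clip(freq, 0.01, 0.99)).astype(float)
    meta = pd.DataFrame(
        {"snp_id": [f"s{i}" for i in range(m)], "chrom": "1",
         "pos": np.arange(m) + 1, "ref": "A", "alt": "G"}
    )
    G = GenotypeMatrix(D, meta, [f"I{i}" for i in range(n)])
    pc1 = genotype_pcs(G, 1)[:, 0]
    assert abs(np.corrcoef(pc1, labels)[0, 1]) > 0.9


# -------------------------------------------------------------- quantile norm


def test_quantile_normalize_identical_columns_unchanged():
    E = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
    np.testing.assert_allclose(quantile_normalize(E), E)


def test_quantile_normalize_two_column_example():
    E = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
    out = quantile_normalize(E)
    np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
    np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])


def test_quantile_normalize_equalizes_sorted_columns(rng):
    E = rng.normal(size=(5, 4))
    out = quantile_normalize(E)
    ref = np.sort(out[:, 0])
    for j in range(1, 4):
        np.testing.assert_allclose(np.sort(out[:, j]), ref)


def test_quantile_normalize_ties_get_mean_target(rng):
    E = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
    out = quantile_normalize(E)
    # tied pair shares the mean of the two smallest target values
    assert out[0, 0] == pytest.approx(out[1, 0])


def test_quantile_normalize_single_column_is_identity(rng):
    E = rng.normal(size=(6, 1))
    np.testing.assert_allclose(quantile_normalize(E), E)


# --------------------------------------------------------------------- config


def test_pipeline_config_validates_thresholds():
    with pytest.raises(ValueError):
        PipelineConfig(fdr_alpha=0.0)
    with pytest.raises(ValueError):
        PipelineConfig(moderate_ld_range=(0.8, 0.5))
    with pytest.raises(ValueError):
        PipelineConfig(cis_window_bp=0)
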