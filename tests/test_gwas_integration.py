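"""Tests for the disease-association stage: combined/meta GWAS, Bonferroni
prioritization, candidate selection and the replication screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlink.assoc_core import GenotypeMatrix, bonferroni_threshold, logistic_assoc
from eqtlink.examples import replication_screen_example, screen_frames_from_example
from eqtlink.gwas_integration import (
    prioritize_bonferroni,
    replication_screen,
    run_combined_gwas,
    run_gwas,
    run_meta,
    select_nominal_candidates,
)
from eqtlink.synthetic_data import simulate_covariates, simulate_haplotype_pool, simulate_genotypes


def _geno(rng, n, m, maf=(0.1, 0.5)):
    p = rng.uniform(*maf, size=m)
    meta = pd.DataFrame(
        {"snp_id": [f"s{i}" for i in range(m)], "chrom": "1",
         "pos": (np.arange(m) + 1) * 100, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(rng.binomial(2, p, size=(n, m)).astype(float), meta,
                          [f"I{i}" for i in range(n)])


# ----------------------------------------------------------------- run_gwas


def test_gwas_null_pvalues_uniform(rng):
    n, m = 300, 2000
    G = _geno(rng, n, m)
    y = rng.integers(0, 2, n).astype(float)
    C = rng.normal(size=(n, 2))
    recs = run_gwas(G, y, C)
    ok = recs[recs.flag == ""]
    assert stats.kstest(ok["p"], "uniform").pvalue > 0.01


def test_gwas_recovers_planted_effect(rng):
    n = 4000
    G = _geno(rng, n, 3, maf=(0.3, 0.5))
    g = G.column("s1")
    eta = -0.5 + 0.8 * g
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    recs = run_gwas(G, y, np.empty((n, 0)))
    rec = recs[recs.snp_id == "s1"].iloc[0]
    assert abs(rec["effect"] - 0.8) < 2 * rec["se"]


def test_gwas_flags_monomorphic_snp(rng):
    G = _geno(rng, 100, 2)
    G.dosages[:, 1] = 0.0
    y = rng.integers(0, 2, 100).astype(float)
    recs = run_gwas(G, y, np.empty((100, 0)))
    assert recs[recs.snp_id == "s1"].iloc[0]["flag"] == "degenerate"


def test_gwas_reports_minor_allele_effect(rng):
    """When the alt allele is the major one, the sign flips and the effect
    allele becomes ref, so directions are cohort-comparable."""
    n = 2000
    G = _geno(rng, n, 1, maf=(0.8, 0.8))  # alt freq ~0.8 -> ref is minor
    g = G.column("s0")
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.5 * g)))).astype(float)
    rec = run_gwas(G, y, np.empty((n, 0))).iloc[0]
    assert rec["effect_allele"] == "A"  # the ref allele
    assert rec["effect"] < 0  # protective for the minor (ref) allele
    st = logistic_assoc(y, g)
    assert rec["effect"] == pytest.approx(-st.effect)


# ----------------------------------------------------------------- run_meta


def _assoc_frame(snp_ids, effects, ses, study="st", allele="G"):
    eff = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    return pd.DataFrame(
        {
            "snp_id": snp_ids, "study": study, "effect": eff, "se": se,
            "z": eff / se, "p": 2 * stats.norm.sf(np.abs(eff / se)),
            "odds_ratio": np.exp(eff), "effect_allele": allele,
            "direction": np.sign(eff).astype(int), "maf": 0.3,
            "n_used": 100, "flag": "",
        }
    )


def test_meta_single_study_passthrough():
    recs = run_meta([_assoc_frame(["a"], [0.3], [0.1])])
    assert recs.iloc[0]["effect"] == pytest.approx(0.3)
    assert recs.iloc[0]["se"] == pytest.approx(0.1)


def test_meta_two_identical_studies_inflate_z_by_sqrt2():
    f = _assoc_frame(["a"], [0.3], [0.1])
    recs = run_meta([f, f.assign(study="st2")])
    assert recs.iloc[0]["z"] == pytest.approx(3.0 * np.sqrt(2))


def test_meta_matches_ivw_oracle(rng):
    snps = [f"s{i}" for i in range(10)]
    frames = [
        _assoc_frame(snps, rng.normal(0, 0.3, 10), rng.uniform(0.05, 0.3, 10), study=f"st{k}")
        for k in range(3)
    ]
    recs = run_meta(frames).set_index("snp_id")
    for i, snp in enumerate(snps):
        effs = np.array([f.iloc[i]["effect"] for f in frames])
        ses = np.array([f.iloc[i]["se"] for f in frames])
        w = 1 / ses**2
        assert recs.loc[snp, "effect"] == pytest.approx((w * effs).sum() / w.sum(), abs=1e-10)
        assert recs.loc[snp, "se"] == pytest.approx(w.sum() ** -0.5, abs=1e-10)


def test_meta_harmonizes_flipped_effect_alleles():
    f1 = _assoc_frame(["a"], [0.3], [0.1], study="st1", allele="G")
    f2 = _assoc_frame(["a"], [-0.3], [0.1], study="st2", allele="A")  # same signal, flipped
    flipped = run_meta([f1, f2])
    same = run_meta([f1, _assoc_frame(["a"], [0.3], [0.1], study="st2", allele="G")])
    assert flipped.iloc[0]["z"] == pytest.approx(same.iloc[0]["z"])


def test_meta_omits_snps_degenerate_everywhere():
    f = _assoc_frame(["a"], [0.3], [0.1])
    f.loc[0, "flag"] = "separation"
    assert len(run_meta([f])) == 0


# -------------------------------------------------------------- prioritize


def test_prioritize_threshold_and_passing():
    eqtl_snps = [f"s{i}" for i in range(3309)]
    recs = _assoc_frame(["s0", "s1", "s2"], [0.3, -0.25, 0.1], [0.07, 0.06, 0.1])
    recs.loc[:, "p"] = [6.8e-6, 2.8e-6, 0.5]
    passing, thr = prioritize_bonferroni(eqtl_snps, recs, 0.05)
    assert thr == pytest.approx(1.5e-5, rel=0.05)
    assert set(passing["snp_id"]) == {"s0", "s1"}


def test_prioritize_nothing_passes_flat_pvalues():
    recs = _assoc_frame(["s0", "s1"], [0.1, 0.1], [0.1, 0.1])
    recs.loc[:, "p"] = 0.5
    passing, _ = prioritize_bonferroni(["s0", "s1"], recs, 0.05)
    assert len(passing) == 0


def test_prioritize_requires_nonempty_snp_set():
    with pytest.raises(ValueError):
        prioritize_bonferroni([], _assoc_frame(["a"], [0.1], [0.1]), 0.05)


def test_reduced_testing_threshold_is_more_permissive():
    """The eQTL-set Bonferroni threshold dominates the genome-wide one,
    and a moderate planted effect passes only the former in most trials."""
    n_eqtl, n_genome = 50, 5000
    thr_eqtl = bonferroni_threshold(0.05, n_eqtl)
    thr_genome = bonferroni_threshold(0.05, n_genome)
    assert thr_eqtl > thr_genome
    rng = np.random.default_rng(21)
    wins = 0
    for _ in range(50):
        G = _geno(rng, 2000, 1, maf=(0.3, 0.4))
        g = G.column("s0")
        y = (rng.random(2000) < 1 / (1 + np.exp(-(-0.2 + 0.25 * g)))).astype(float)
        p = logistic_assoc(y, g).p
        if p < thr_eqtl and not p < thr_genome:
            wins += 1
    assert wins > 25


# -------------------------------------------------------------- candidates


def test_candidate_union_arithmetic():
    comb = _assoc_frame([f"c{i}" for i in range(64)], [0.2] * 64, [0.05] * 64)
    comb["p"] = 0.005
    meta_ids = [f"c{i}" for i in range(44)] + [f"m{i}" for i in range(12)]
    meta = pd.DataFrame({"snp_id": meta_ids, "effect": 0.2, "se": 0.05,
                         "z": 4.0, "p": 0.005, "n_studies": 3, "effect_allele": "G"})
    cand = select_nominal_candidates(comb, meta, 0.01)
    assert len(cand) == 76
    assert (cand["provenance"] == "both").sum() == 44
    assert (cand["provenance"] == "combined").sum() == 20
    assert (cand["provenance"] == "meta").sum() == 12


def test_candidate_union_disjoint_and_empty():
    a = _assoc_frame(["a", "b"], [0.2, 0.2], [0.05, 0.05]); a["p"] = 0.005
    m = pd.DataFrame({"snp_id": ["c", "d", "e"], "effect": 0.2, "se": 0.05,
                      "z": 4.0, "p": 0.005, "n_studies": 1, "effect_allele": "G"})
    assert len(select_nominal_candidates(a, m, 0.01)) == 5
    empty = a.iloc[:0]
    assert len(select_nominal_candidates(empty, m.iloc[:0], 0.01)) == 0


def test_candidate_exclusion_list():
    a = _assoc_frame(["a", "b"], [0.2, 0.2], [0.05, 0.05]); a["p"] = 0.005
    cand = select_nominal_candidates(a, a.iloc[:0], 0.01, exclude=["a"])
    assert cand["snp_id"].tolist() == ["b"]


# -------------------------------------------------------------- replication


def test_replication_screen_on_worked_example():
    """Eight candidates screened sequentially at p<0.1 / p<0.1 + direction:
    exactly one SNP survives, and it is the PSORS1C1 variant."""
    candidates, screen1, screen2 = screen_frames_from_example()
    out = replication_screen(candidates, screen1, screen2, 0.1)
    assert int(out["replicated"].sum()) == 1
    assert out.loc[out["replicated"], "snp_id"].iloc[0] == "rs1265098"


def test_replication_direction_inconsistency_fails_pass2():
    cand = pd.DataFrame({"snp_id": ["x"], "direction": [1]})
    s1 = pd.DataFrame({"snp_id": ["x"], "p": [0.042], "direction": [1]})
    s2 = pd.DataFrame({"snp_id": ["x"], "p": [0.05], "direction": [-1]})
    out = replication_screen(cand, s1, s2, 0.1)
    assert not out.iloc[0]["replicated"]
    # without the direction requirement it would pass
    out2 = replication_screen(cand, s1, s2, 0.1, require_direction=False)
    assert out2.iloc[0]["replicated"]


def test_replication_reorients_screen_to_discovery_allele():
    """A screen cohort whose minor allele is the complementary choice has
    its direction flipped before the consistency check."""
    cand = pd.DataFrame({"snp_id": ["x"], "direction": [1], "effect_allele": ["G"]})
    s1 = pd.DataFrame({"snp_id": ["x"], "p": [0.01], "direction": [-1],
                       "effect_allele": ["A"]})  # same signal, other allele
    s2 = pd.DataFrame({"snp_id": ["x"], "p": [0.01], "direction": [1],
                       "effect_allele": ["G"]})
    out = replication_screen(cand, s1, s2, 0.1)
    assert out.iloc[0]["consistent_direction"] and out.iloc[0]["replicated"]


def test_replication_fails_pass1_regardless_of_screen2():
    cand = pd.DataFrame({"snp_id": ["x"], "direction": [1]})
    s1 = pd.DataFrame({"snp_id": ["x"], "p": [0.5], "direction": [1]})
    s2 = pd.DataFrame({"snp_id": ["x"], "p": [1e-8], "direction": [1]})
    out = replication_screen(cand, s1, s2, 0.1)
    assert not out.iloc[0]["pass1"] and not out.iloc[0]["replicated"]


def test_replication_absent_candidates_reported_untested():
    cand = pd.DataFrame({"snp_id": ["x", "y"], "direction": [1, 1]})
    s1 = pd.DataFrame({"snp_id": ["x"], "p": [0.01], "direction": [1]})
    s2 = pd.DataFrame({"snp_id": ["x"], "p": [0.01], "direction": [1]})
    out = replication_screen(cand, s1, s2, 0.1).set_index("snp_id")
    assert not out.loc["y", "tested"]
    assert not out.loc["y", "replicated"]
    assert out.loc["x", "replicated"]


def test_worked_example_table_shape():
    t = replication_screen_example()
    assert len(t) == 8
    assert (t["screen1_p"] < 0.1).all()


# ----------------------------------------------------------- combined GWAS


def test_combined_gwas_pools_studies(small_bundle):
    snp, _ = small_bundle.truth.planted_disease[0]
    recs = run_combined_gwas(small_bundle.studies, snp_ids=[snp])
    rec = recs.iloc[0]
    n_total = sum(len(s.phenotype) for s in small_bundle.studies)
    assert rec["n_used"] == n_total
    gamma = small_bundle.truth.planted_disease[0][1]
    assert abs(rec["effect"] * rec["direction"] - gamma) < 3 * rec["se"] or \
        abs(rec["effect"] - gamma) < 3 * rec["se"]
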