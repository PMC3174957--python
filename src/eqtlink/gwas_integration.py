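"""Stage 2: disease association of the eQTL SNP set.

Implements the reduced-multiple-testing lookup: the significant cis-eQTL
SNPs (thousands instead of ~500k genome-wide) are tested for disease
association in a pooled "combined" logistic regression (mega-analysis of
individual-level data with study indicators) and in a per-study
fixed-effects meta-analysis; Bonferroni prioritization is applied over the
eQTL SNP count only; nominal candidates (p < 0.01 in either analysis) go
to a sequential two-cohort replication screen at p < 0.1 with
effect-direction consistency.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assoc_core import (
    GenotypeMatrix,
    PipelineConfig,
    bonferroni_threshold,
    compute_maf,
    fixed_effects_meta,
    logistic_assoc,
    weighted_z_meta,
)

__all__ = [
    "run_gwas",
    "run_combined_gwas",
    "run_meta",
    "prioritize_bonferroni",
    "select_nominal_candidates",
    "replication_screen",
]

ASSOC_COLUMNS = [
    "snp_id", "study", "effect", "se", "z", "p", "odds_ratio",
    "effect_allele", "direction", "maf", "n_used", "flag",
]


def run_gwas(
    G: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
    snp_ids: Sequence[str] | None = None,
    study_label: str = "study",
) -> pd.DataFrame:
    """Per-SNP logistic case-control association, adjusted for covariates.

    Effects are reported for the minor allele in this cohort: when the alt
    allele is the major one, the sign is flipped and ``effect_allele`` is
    set to the ref allele, so directions are comparable across cohorts.
    Degenerate fits are flagged, never dropped.
    """
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ids = list(snp_ids) if snp_ids is not None else G.snp_ids
    rows = []
    for snp_id in ids:
        g = G.column(snp_id)
        meta = G.snp_meta.iloc[G._index()[snp_id]]
        nonmiss = g[~np.isnan(g)]
        if nonmiss.size == 0 or np.ptp(nonmiss) == 0:
            rows.append(
                dict(snp_id=snp_id, study=study_label, effect=np.nan, se=np.nan,
                     z=np.nan, p=np.nan, odds_ratio=np.nan, effect_allele=str(meta["alt"]),
                     direction=0, maf=np.nan if nonmiss.size == 0 else compute_maf(g),
                     n_used=int(nonmiss.size), flag="degenerate")
            )
            continue
        st = logistic_assoc(y, g, C)
        alt_freq = nonmiss.sum() / (2 * nonmiss.size)
        if alt_freq > 0.5:
            effect = -st.effect
            allele = str(meta["ref"])
        else:
            effect = st.effect
            allele = str(meta["alt"])
        z = -st.statistic if (alt_freq > 0.5 and st.ok) else st.statistic
        rows.append(
            dict(
                snp_id=snp_id,
                study=study_label,
                effect=effect if st.ok else np.nan,
                se=st.se,
                z=z if st.ok else np.nan,
                p=st.p,
                odds_ratio=float(np.exp(effect)) if st.ok else np.nan,
                effect_allele=allele,
                direction=int(np.sign(effect)) if st.ok and effect != 0 else 0,
                maf=min(alt_freq, 1 - alt_freq),
                n_used=st.n_used,
                flag=st.flag,
            )
        )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def _pool_studies(studies) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Stack genotypes, phenotypes and covariates (+ study indicators)."""
    dosages = np.vstack([s.genotypes.dosages for s in studies])
    sample_ids = [sid for s in studies for sid in s.genotypes.sample_ids]
    G = GenotypeMatrix(dosages, studies[0].genotypes.snp_meta.copy(), sample_ids)
    y = np.concatenate([s.phenotype for s in studies])
    cov_cols = [c for c in studies[0].covariates.columns if c != "sample_id"]
    C = np.vstack([s.covariates[cov_cols].to_numpy(dtype=float) for s in studies])
    # study indicator columns (reference = first study)
    for k in range(1, len(studies)):
        ind = np.concatenate(
            [np.full(len(s.phenotype), 1.0 if i == k else 0.0) for i, s in enumerate(studies)]
        )
        C = np.column_stack([C, ind])
    return G, y, C


def run_combined_gwas(studies, snp_ids=None, label: str = "combined") -> pd.DataFrame:
    """Mega-analysis: one logistic regression on pooled individual-level
    data with study-indicator covariates."""
    G, y, C = _pool_studies(studies)
    return run_gwas(G, y, C, snp_ids=snp_ids, study_label=label)


def run_meta(
    study_records: Iterable[pd.DataFrame],
    method: str = "ivw",
) -> pd.DataFrame:
    """Fixed-effects combination of per-study association records per SNP.

    Effect alleles are harmonized to the first study reporting each SNP
    (sign flipped when a study oriented to the complementary allele).
    SNPs degenerate in every study are omitted.
    """
    frames = [df for df in study_records]
    if not frames:
        return pd.DataFrame(columns=["snp_id", "effect", "se", "z", "p", "n_studies", "effect_allele"])
    combine = fixed_effects_meta if method == "ivw" else weighted_z_meta
    all_recs = pd.concat(frames, ignore_index=True)
    rows = []
    for snp_id, grp in all_recs.groupby("snp_id", sort=False):
        usable = grp[grp["flag"].isin(["", "underflow"]) & grp["se"].notna()]
        if usable.empty:
            continue
        ref_allele = usable.iloc[0]["effect_allele"]
        effects = np.where(
            usable["effect_allele"] == ref_allele, usable["effect"], -usable["effect"]
        )
        rec = combine(effects, usable["se"].to_numpy())
        rows.append(
            dict(snp_id=snp_id, effect=rec.effect, se=rec.se, z=rec.z, p=rec.p,
                 n_studies=rec.n_studies, effect_allele=ref_allele)
        )
    return pd.DataFrame(rows, columns=["snp_id", "effect", "se", "z", "p", "n_studies", "effect_allele"])


def prioritize_bonferroni(
    eqtl_snps: Sequence[str],
    combined_records: pd.DataFrame,
    fwer_alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Bonferroni prioritization over the reduced eQTL SNP set.

    The family-wise threshold is alpha divided by the number of eQTL SNPs
    (not the genome-wide SNP count); returns the passing association
    records sorted by p, plus the threshold.
    """
    eqtl_snps = list(eqtl_snps)
    if not eqtl_snps:
        raise ValueError("empty eQTL SNP set")
    threshold = bonferroni_threshold(fwer_alpha, len(eqtl_snps))
    recs = combined_records[combined_records["snp_id"].isin(eqtl_snps)]
    passing = recs[recs["p"].notna() & (recs["p"] < threshold)]
    return passing.sort_values("p", kind="stable").reset_index(drop=True), threshold


def select_nominal_candidates(
    combined_records: pd.DataFrame,
    meta_records: pd.DataFrame,
    nominal_p: float = 0.01,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Union of SNPs at p < nominal_p in the combined analysis or the
    meta-analysis, with provenance (combined | meta | both).

    ``exclude`` removes SNPs not to be re-tested (e.g. those already
    established at the Bonferroni stage).
    """
    comb = combined_records[combined_records["p"].notna() & (combined_records["p"] < nominal_p)]
    meta = meta_records[meta_records["p"].notna() & (meta_records["p"] < nominal_p)]
    comb_p = dict(zip(comb["snp_id"], comb["p"]))
    meta_p = dict(zip(meta["snp_id"], meta["p"]))
    comb_dir = dict(zip(comb["snp_id"], comb.get("direction", pd.Series(dtype=int))))
    comb_allele = dict(zip(comb["snp_id"], comb.get("effect_allele", pd.Series(dtype=str))))
    rows = []
    for snp_id in sorted(set(comb_p) | set(meta_p)):
        if snp_id in set(exclude):
            continue
        in_c, in_m = snp_id in comb_p, snp_id in meta_p
        direction = comb_dir.get(snp_id)
        allele = comb_allele.get(snp_id)
        if direction is None and in_m:
            mrow = meta[meta["snp_id"] == snp_id].iloc[0]
            direction = int(np.sign(mrow["effect"]))
            allele = mrow.get("effect_allele")
        rows.append(
            dict(
                snp_id=snp_id,
                provenance="both" if (in_c and in_m) else ("combined" if in_c else "meta"),
                p_combined=comb_p.get(snp_id, np.nan),
                p_meta=meta_p.get(snp_id, np.nan),
                direction=int(direction) if direction is not None else 0,
                effect_allele=allele if allele is not None else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "provenance", "p_combined", "p_meta", "direction", "effect_allele"],
    )


def replication_screen(
    candidates: pd.DataFrame,
    screen1: pd.DataFrame,
    screen2: pd.DataFrame,
    replication_p: float = 0.1,
    require_direction: bool = True,
) -> pd.DataFrame:
    """Sequential two-cohort replication screen.

    Pass 1 requires screen1 p < replication_p; pass 2 requires screen2
    p < replication_p and (optionally) an effect direction consistent with
    screen1 and with the discovery analysis. Candidates absent from a
    screen are reported as untested, never as failures.

    ``candidates`` needs columns (snp_id, direction); each screen frame
    needs (snp_id, p, direction) with direction in {-1, 0, +1}. When both
    a frame and the candidates carry an ``effect_allele`` column, screen
    directions are re-oriented to the discovery effect allele before the
    consistency check (a cohort whose minor allele is the complementary
    choice would otherwise report a spuriously flipped sign).
    """
    s1 = screen1.set_index("snp_id")
    s2 = screen2.set_index("snp_id")

    def _direction(frame, snp_id, disc_allele):
        d = int(frame.loc[snp_id, "direction"])
        if disc_allele and "effect_allele" in frame.columns:
            if str(frame.loc[snp_id, "effect_allele"]) != str(disc_allele):
                d = -d
        return d

    rows = []
    for cand in candidates.itertuples(index=False):
        snp_id = cand.snp_id
        disc_dir = int(getattr(cand, "direction", 0))
        disc_allele = getattr(cand, "effect_allele", "")
        tested = snp_id in s1.index and snp_id in s2.index
        if not tested:
            rows.append(dict(snp_id=snp_id, tested=False, screen1_p=np.nan,
                             screen1_direction=0, screen2_p=np.nan, screen2_direction=0,
                             pass1=False, consistent_direction=False, replicated=False))
            continue
        p1 = float(s1.loc[snp_id, "p"])
        d1 = _direction(s1, snp_id, disc_allele)
        p2 = float(s2.loc[snp_id, "p"])
        d2 = _direction(s2, snp_id, disc_allele)
        pass1 = bool(np.isfinite(p1) and p1 < replication_p)
        consistent = d1 != 0 and d1 == d2 and (disc_dir == 0 or d1 == disc_dir)
        pass2 = bool(np.isfinite(p2) and p2 < replication_p)
        replicated = pass1 and pass2 and (consistent or not require_direction)
        rows.append(dict(snp_id=snp_id, tested=True, screen1_p=p1, screen1_direction=d1,
                         screen2_p=p2, screen2_direction=d2, pass1=pass1,
                         consistent_direction=consistent, replicated=replicated))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "tested", "screen1_p", "screen1_direction", "screen2_p",
                 "screen2_direction", "pass1", "consistent_direction", "replicated"],
    )
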