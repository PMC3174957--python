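"""Stage 3: LD structure of a candidate locus.

Pairwise genotype r² matrices, tag-SNP bin assignment with moderate-LD
sub-bins, and per-SNP summary rows joining eQTL evidence per gene, bin
membership and disease association — the machinery for asking whether two
genes' eQTL signals at one locus are carried by the same or by distinct
haplotype groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc_core import DegenerateTestError, GenotypeMatrix, PipelineConfig, ld_r2

__all__ = ["LdBinTable", "pairwise_r2", "assign_ld_bins", "locus_summary_table"]


@dataclass
class LdBinTable:
    """Tag-SNP bin assignment for a locus.

    ``assignments`` has one row per SNP with columns
    (snp_id, bin, r2_to_tag, is_sub_bin); unbinned SNPs carry bin ``""``.
    Core members have r2_to_tag >= the core threshold; sub-bin members
    (bin label suffixed ``a``) fall inside the moderate-LD range. Tags are
    always assigned to their own bin with r² = 1.
    """

    tags: list[tuple[str, str]]  # (bin_label, tag_snp_id)
    assignments: pd.DataFrame

    def members(self, bin_label: str, include_sub: bool = False) -> list[str]:
        a = self.assignments
        mask = a["bin"] == bin_label
        if include_sub:
            mask |= a["bin"] == f"{bin_label}a"
        return a.loc[mask, "snp_id"].tolist()


def pairwise_r2(G: GenotypeMatrix, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Symmetric matrix of composite-LD r² values between the given SNPs.

    Monomorphic SNPs get NaN rows/columns (undefined LD) rather than an
    error, so a locus with a failed SNP still produces a table.
    """
    ids = list(snp_ids)
    cols = [G.column(s) for s in ids]
    m = len(ids)
    out = np.full((m, m), np.nan)
    for i in range(m):
        gi = cols[i]
        defined_i = np.ptp(gi[~np.isnan(gi)]) > 0 if (~np.isnan(gi)).any() else False
        if defined_i:
            out[i, i] = 1.0
        for j in range(i + 1, m):
            try:
                out[i, j] = out[j, i] = ld_r2(gi, cols[j])
            except DegenerateTestError:
                pass
    return pd.DataFrame(out, index=ids, columns=ids)


def assign_ld_bins(
    r2: pd.DataFrame,
    tags: Sequence[tuple[str, str]],
    cfg: PipelineConfig | None = None,
    positions: dict[str, int] | None = None,
) -> LdBinTable:
    """Assign each SNP to the tag it is in strongest LD with.

    A non-tag SNP joins the core bin of the tag with maximal r² when that
    r² >= ``ld_bin_r2_min``; otherwise, if its best tag r² falls inside
    ``moderate_ld_range``, it joins that tag's sub-bin (label suffixed
    ``a``); otherwise it is unbinned. Ties break toward the tag with the
    smaller genomic position (requires ``positions``), else toward the
    earlier tag in ``tags``.
    """
    cfg = cfg or PipelineConfig()
    labels = [lab for lab, _ in tags]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tag bin labels")
    tag_ids = [sid for _, sid in tags]
    for sid in tag_ids:
        if sid not in r2.index:
            raise ValueError(f"tag SNP {sid!r} not in the r² matrix")

    def tag_order(k: int) -> tuple:
        sid = tag_ids[k]
        return (positions.get(sid, 0), k) if positions else (k,)

    rows = []
    lo, hi = cfg.moderate_ld_range
    for snp_id in r2.index:
        if snp_id in tag_ids:
            lab = labels[tag_ids.index(snp_id)]
            rows.append(dict(snp_id=snp_id, bin=lab, r2_to_tag=1.0, is_sub_bin=False))
            continue
        vals = np.array([r2.loc[snp_id, t] for t in tag_ids], dtype=float)
        if np.isnan(vals).all():
            rows.append(dict(snp_id=snp_id, bin="", r2_to_tag=np.nan, is_sub_bin=False))
            continue
        best = np.nanmax(vals)
        ties = [k for k in range(len(tag_ids)) if np.isclose(vals[k], best, atol=1e-12)]
        k = min(ties, key=tag_order)
        if best >= cfg.ld_bin_r2_min:
            rows.append(dict(snp_id=snp_id, bin=labels[k], r2_to_tag=float(best), is_sub_bin=False))
        elif lo <= best < hi:
            rows.append(dict(snp_id=snp_id, bin=f"{labels[k]}a", r2_to_tag=float(best), is_sub_bin=True))
        else:
            rows.append(dict(snp_id=snp_id, bin="", r2_to_tag=float(best), is_sub_bin=False))
    return LdBinTable(tags=list(tags), assignments=pd.DataFrame(rows))


def locus_summary_table(
    interval: tuple[str, int, int],
    G: GenotypeMatrix,
    eqtl_records: pd.DataFrame,
    assoc_records: pd.DataFrame,
    bin_table: LdBinTable,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP locus table: position, per-gene eQTL p, LD bin, GWAS p.

    One row per SNP inside ``interval`` (chrom, start, end; 1-based
    inclusive), ordered by position. ``genes`` selects which genes get an
    eQTL p-value column (default: all genes present in the records);
    genes with no tested probe are omitted with a warning column absent.
    When a gene has several probes the smallest p per SNP is shown.
    """
    chrom, start, end = interval
    meta = G.snp_meta
    in_iv = (meta["chrom"].astype(str) == str(chrom)) & meta["pos"].between(start, end)
    locus = meta[in_iv].sort_values("pos", kind="stable")
    if locus.empty:
        return pd.DataFrame(columns=["snp_id", "pos", "bin", "r2_to_tag", "gwas_p"])

    gene_list = list(genes) if genes is not None else sorted(
        eqtl_records["gene_symbol"].dropna().unique()
    )
    assign = bin_table.assignments.set_index("snp_id")
    gwas_p = assoc_records.set_index("snp_id")["p"] if len(assoc_records) else pd.Series(dtype=float)

    rows = []
    for snp in locus.itertuples(index=False):
        row = {"snp_id": snp.snp_id, "pos": int(snp.pos)}
        for gene in gene_list:
            sub = eqtl_records[
                (eqtl_records["snp_id"] == snp.snp_id)
                & (eqtl_records["gene_symbol"] == gene)
            ]
            row[f"eqtl_p_{gene}"] = float(sub["p"].min()) if len(sub) else np.nan
        if snp.snp_id in assign.index:
            row["bin"] = assign.loc[snp.snp_id, "bin"]
            row["r2_to_tag"] = float(assign.loc[snp.snp_id, "r2_to_tag"])
        else:
            row["bin"], row["r2_to_tag"] = "", np.nan
        row["gwas_p"] = float(gwas_p.get(snp.snp_id, np.nan))
        rows.append(row)
    out = pd.DataFrame(rows)
    # drop gene columns that were never tested at this locus
    for gene in gene_list:
        col = f"eqtl_p_{gene}"
        if col in out and out[col].isna().all():
            out = out.drop(columns=col)
    return out
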