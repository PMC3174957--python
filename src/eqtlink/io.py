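"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCF (GT fields, biallelic) or as a dosage TSV dialect
(header row of sample ids; one SNP per row with id, chrom, pos, ref, alt,
dosages). Expression, annotation, covariates and all stage outputs are
plain TSV. Coordinates are 1-based inclusive everywhere (VCF convention).
Each pipeline output directory carries one JSON run manifest recording the
config snapshot, input checksums and master seed.

All writers use full-precision formatting so write -> read round trips are
lossless and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc_core import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_covariates",
    "write_covariates",
    "write_table",
    "read_table",
    "RunManifest",
    "write_bundle",
    "read_bundle",
]

_FLOAT_FMT = "%.17g"


def _fmt(v) -> str:
    if isinstance(v, float):
        return _FLOAT_FMT % v
    return str(v)


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCFv4.2 with GT fields.

    Dosage 0/1/2 becomes 0/0, 0/1, 1/1; missing becomes ./.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(G.snp_meta["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in enumerate(G.snp_meta.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in G.dosages[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref}\t{snp.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, metas = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"{path.name}:{var.CHROM}:{var.POS}: non-biallelic record treated as missing"
            )
            rows.append(np.full(len(sample_ids), np.nan))
            metas.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS,
                          var.REF, ",".join(var.ALT) or "."))
            continue
        dos = np.full(len(sample_ids), np.nan)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if len(alleles) != 2:  # missing or haploid
                continue
            dos[i] = float(sum(alleles))
        rows.append(dos)
        metas.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS,
                      var.REF, var.ALT[0]))
    meta = pd.DataFrame(metas, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = np.vstack(rows).T if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=sample_ids)


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV dialect: columns (snp_id, chrom, pos, ref, alt, <samples...>)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("snp_id\tchrom\tpos\tref\talt\t" + "\t".join(G.sample_ids) + "\n")
        for j, snp in enumerate(G.snp_meta.itertuples(index=False)):
            vals = [
                "NA" if np.isnan(d) else str(int(d)) for d in G.dosages[:, j]
            ]
            fh.write(
                f"{snp.snp_id}\t{snp.chrom}\t{snp.pos}\t{snp.ref}\t{snp.alt}\t"
                + "\t".join(vals) + "\n"
            )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage TSV missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(
        dosages=dosages, snp_meta=df[meta_cols].copy(), sample_ids=sample_ids
    )


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or dosage TSV (format inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "dosage-tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# expression / annotation / covariates


def write_expression(E: ExpressionMatrix, path: str | Path) -> None:
    """Expression TSV: probe sets in rows, samples in columns."""
    with Path(path).open("w") as fh:
        fh.write("probe_id\t" + "\t".join(E.sample_ids) + "\n")
        for j, probe in enumerate(E.probe_ids):
            fh.write(probe + "\t" + "\t".join(_FLOAT_FMT % v for v in E.values[:, j]) + "\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    probe_ids = df["probe_id"].astype(str).tolist()
    if len(set(probe_ids)) != len(probe_ids):
        raise ValueError("duplicate probe ids in expression file")
    sample_ids = [c for c in df.columns if c != "probe_id"]
    return ExpressionMatrix(
        values=df[sample_ids].to_numpy(dtype=float).T,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
    )


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Probe annotation TSV: (probe_id, gene_symbol, chrom, tss, strand);
    tss is 1-based."""
    annotation.to_csv(path, sep="\t", index=False, na_rep="")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "gene_symbol": str, "chrom": str, "strand": str},
        keep_default_na=False, na_values=[],
    )
    df["tss"] = df["tss"].astype(int)
    if df["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in annotation")
    return df


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    """Covariate TSV: (sample_id, age, sex, pack_years[, status, study]);
    sex is coded 0 = female, 1 = male."""
    out = cov.copy()
    for c in out.columns:
        if out[c].dtype == float:
            out[c] = out[c].map(lambda v: _FLOAT_FMT % v if pd.notna(v) else "NA")
    out.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"],
                     float_precision="round_trip")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in covariates")
    return df


def check_sample_alignment(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix | None = None,
    covariates: pd.DataFrame | None = None,
) -> list[str]:
    """Sample ids in expression/covariates that do not resolve against the
    genotype cohort. Unmatched ids are warned about and returned so callers
    can record an exclusion list in the run manifest."""
    known = set(genotypes.sample_ids)
    unmatched: list[str] = []
    if expression is not None:
        unmatched += [s for s in expression.sample_ids if s not in known]
    if covariates is not None:
        unmatched += [s for s in covariates["sample_id"] if s not in known]
    if unmatched:
        warnings.warn(f"{len(unmatched)} sample id(s) not in the genotype cohort: "
                      f"{sorted(set(unmatched))[:5]}...")
    return sorted(set(unmatched))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic stage-output TSV with full-precision scientific floats."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")


# ---------------------------------------------------------------------------
# run manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one pipeline run: the config snapshot,
    checksums of every file the run read or wrote, stage versions and the
    master seed. Replaying a manifest's config and seed reproduces the
    stage outputs bitwise (the manifest's own timestamp excepted)."""

    config: dict
    master_seed: int
    checksums: dict[str, str] = dataclasses.field(default_factory=dict)
    stage_versions: dict[str, str] = dataclasses.field(default_factory=dict)
    timestamp: str | None = None

    def add_file(self, path: str | Path) -> None:
        p = Path(path)
        self.checksums[p.name] = _sha256(p)

    def stamp(self) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# bundle serialization


def write_bundle(bundle, outdir: str | Path, manifest: RunManifest | None = None) -> Path:
    """Serialize a simulated study bundle to a directory.

    Expression-cohort genotypes go out as VCF (exercising the VCF path);
    the larger case-control studies as dosage TSV. Returns the directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes_vcf(bundle.expr_genotypes, outdir / "expr_genotypes.vcf")
    write_expression(bundle.expression, outdir / "expression.tsv")
    write_annotation(bundle.annotation, outdir / "annotation.tsv")
    write_covariates(bundle.expr_covariates, outdir / "expr_covariates.tsv")
    for study in list(bundle.studies) + list(bundle.replication_studies):
        write_genotypes_tsv(study.genotypes, outdir / f"{study.label}_genotypes.tsv")
        cov = study.covariates.copy()
        cov["status"] = study.phenotype.astype(int)
        cov["study"] = study.label
        write_covariates(cov, outdir / f"{study.label}_covariates.tsv")
    write_table(bundle.truth.to_frame(), outdir / "truth.tsv")
    if manifest is None:
        manifest = RunManifest(
            config=dataclasses.asdict(bundle.config),
            master_seed=bundle.config.master_seed,
        )
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.add_file(f)
    manifest.write(outdir / "manifest.json")
    return outdir


def read_bundle(outdir: str | Path) -> dict:
    """Read back a serialized bundle into plain in-memory objects."""
    outdir = Path(outdir)
    out = {
        "expr_genotypes": read_genotypes(outdir / "expr_genotypes.vcf"),
        "expression": read_expression(outdir / "expression.tsv"),
        "annotation": read_annotation(outdir / "annotation.tsv"),
        "expr_covariates": read_covariates(outdir / "expr_covariates.tsv"),
        "truth": read_table(outdir / "truth.tsv"),
        "manifest": RunManifest.read(outdir / "manifest.json"),
        "studies": {},
    }
    for f in sorted(outdir.glob("*_genotypes.tsv")):
        label = f.name.replace("_genotypes.tsv", "")
        cov = read_covariates(outdir / f"{label}_covariates.tsv")
        out["studies"][label] = {
            "genotypes": read_genotypes(f),
            "covariates": cov.drop(columns=[c for c in ("status", "study") if c in cov]),
            "phenotype": cov["status"].to_numpy(dtype=float) if "status" in cov else None,
        }
    return out
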