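"""Simulate the study's cohorts and write them to results/data/.

Generates one shared SNP panel and, from it: a 131-sample expression cohort
with a planted cis-eQTL that also carries disease risk, three discovery
case-control studies matching the design's sizes (1736/175, 838/791,
366/414 cases/controls), and two replication studies. Prints what was
planted so later stages can be judged against the truth.
"""

from pathlib import Path

from eqtlink.io import write_bundle
from eqtlink.synthetic_data import SimConfig, generate_study_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

CONFIG = SimConfig(
    n_snps=600,
    n_genes=60,
    block_sizes=[1, 9] + [10] * 59,
    maf_range=(0.2, 0.5),
    cis_effect_sizes={"rs00001": 1.2},
    disease_log_odds={"rs00001": 0.5},
    master_seed=20260922,
)


def main() -> None:
    bundle = generate_study_bundle(CONFIG)
    write_bundle(bundle, OUT)
    print(f"wrote bundle to {OUT}")
    print(f"expression cohort: {bundle.expression.values.shape[0]} samples, "
          f"{bundle.expression.values.shape[1]} probe sets, "
          f"{bundle.expr_genotypes.n_snps} SNPs")
    for s in bundle.studies + bundle.replication_studies:
        print(f"{s.label}: n={len(s.phenotype)}, cases={int(s.phenotype.sum())}")
    for snp, probe, beta in bundle.truth.planted_cis:
        print(f"planted cis effect: {snp} -> {probe}, beta={beta}")
    for snp, gamma in bundle.truth.planted_disease:
        print(f"planted disease effect: {snp}, log-odds={gamma}")


if __name__ == "__main__":
    main()
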