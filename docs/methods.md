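# Methods

## Statistical model

**cis-eQTL scan.** For probe set *j* and SNP *k* within the cis window of
its TSS, ordinary least squares on

  y_ij = β₀ + β g_ik + a·age_i + s·sex_i + Σ_m c_m PC_im + ε_i,  ε ~ N(0, σ²)

with g the additive alt-allele dosage (0/1/2) and PC₁…PC₆ genotype-derived
ancestry components. The reported statistic is the genotype coefficient's
t with df = n − p; two-sided p from the t distribution. Significance is
Benjamini–Hochberg FDR < 0.05 over **all** SNP–probe tests jointly (one
step-up pass, not per probe), which yields a single implied raw-p cutoff —
the maximum raw p among significant pairs.

**Disease lookup.** Logistic regression of case status on dosage, adjusted
for age, sex and pack-years (plus study indicators in the pooled
"combined" analysis), fit by iteratively reweighted least squares
(tolerance 1e-8, ≤ 50 iterations); Wald z and two-sided normal p.
Per-study fits are combined by fixed-effects inverse-variance weighting on
the log-odds scale (w = 1/se², combined se = (Σw)^(−1/2)); a
weighted-Stouffer alternative (`meta_method="weighted_z"`) is provided
because the verbal description of such analyses — z-scores weighted by
inverse variance — is ambiguous between the two; IVW on effects is the
default. Effects are reported for the cohort's minor allele; cross-cohort
comparisons re-orient to a common effect allele before comparing signs
(without this, a SNP near MAF 0.5 can flip its reported direction between
cohorts purely by sampling).

**Prioritization and replication.** The Bonferroni threshold is
α / (number of significant eQTL SNPs). Candidates at p < 0.01 in the
combined or meta analysis enter a sequential screen: p < 0.1 in
replication cohort 1, then p < 0.1 in cohort 2 with effect direction
consistent with cohort 1 and with discovery. Direction consistency is a
hard requirement by default (config switch `require_direction_consistency`);
candidates absent from a replication panel are reported as untested, never
as failures. Bonferroni-significant SNPs are retested by default;
`exclude_bonferroni_from_replication=True` reproduces the design in which
already-established SNPs are not re-screened.

**LD bins.** LD is composite (genotype) r² — the squared Pearson
correlation of dosages — because the data model carries no phase; no EM
haplotype estimation. A non-tag SNP joins the core bin of the tag with
maximal r² when that r² ≥ 0.80, a moderate sub-bin when the best r² lies
in [0.50, 0.80), and is otherwise unbinned; ties break toward the
lower-position tag. The 0.80 core threshold is configurable (published
bin definitions mix thresholds, with additions at r² 0.79–0.99 and
original memberships down to 0.72), and externally supplied memberships
can override computed ones.

## Conventions and numerical choices

- Coordinates 1-based inclusive everywhere (VCF convention); the cis
  window boundary is inclusive (|pos − TSS| ≤ window).
- Distance to the TSS is strand-oriented (positive = downstream in the
  direction of transcription); windows are symmetric so strand affects
  only the sign.
- MAF filtering (MAF ≥ 0.05 kept, computed in the expression cohort)
  precedes pair enumeration; PCs are computed on the post-filter matrix.
- Missing data: pairwise-complete per test; mean imputation only inside
  PCA standardization. Genotype PCs scale each SNP by sqrt(2p(1−p)).
- Ancestry PCs are computed on an LD-pruned panel (greedy r² < 0.2 in
  position order). With a dense local panel, unpruned PCs align with
  individual haplotype blocks and absorb cis signal from the very SNPs
  being tested; pruning plus a sufficiently many-block panel keeps the
  6 components from collapsing onto any single locus. This matters at
  simulation scale (tens of blocks) far more than at genome scale.
- p-values are floored at the smallest positive double and flagged
  `underflow`, never reported as 0. Degenerate fits (rank deficiency,
  monomorphic dosage, separation with |logit effect| > 15) carry flags and
  are excluded from FDR input rather than silently dropped.
- Quantile normalization maps each sample's ranks onto the mean
  order-statistic profile, ties receiving the mean of their target values;
  the pipeline does not re-normalize by default because the generator
  emits already-normalized values.

## The synthetic-data generator

The generator emulates the *statistical* structure the analysis assumes,
not microarray physics:

- **Haplotype pool.** SNPs are partitioned into blocks. Each block has one
  latent carrier haplotype segregating at a frequency drawn from
  `maf_range`; every SNP in the block copies the carrier state with
  per-site mutation probability ε (default 0.03, per-SNP overridable).
  Within-block haplotype correlation is ≈ (1−2ε)² at intermediate
  frequency (lower at rare frequencies); blocks are independent unless
  `recomb_prob_between_blocks < 1`. This two-founder copying model gives
  exact marginal frequencies and controllable tag-SNP r² — sufficient for
  LD-bin structure — but no recombination gradients or allele-age effects.
- **Genotypes.** Each diploid sample sums two haplotypes drawn with
  replacement; Hardy–Weinberg holds by construction. An optional
  two-subpopulation mode shifts block carrier frequencies by
  ±`ancestry_divergence`/2 so PC adjustment can be exercised; off by
  default.
- **Expression.** baseline + β·dosage + covariate terms + N(0, noise_sd²),
  homoscedastic Gaussian noise on the log2 scale. The noise model of real
  probe-level data is unknown; Gaussian homoscedasticity is a stated
  stand-in, so passing tests demonstrate correctness of the inference
  machinery, not robustness to heavy-tailed or variance-dependent
  expression noise. Planted SNPs act on the probe with the nearest TSS
  and must lie inside the cis window (enforced).
- **Disease.** P(case) = logistic(baseline + Σγ·dosage + covariate terms);
  the baseline is centered so each study's realized case fraction tracks
  its design. Covariates: age ~ N(64.9, 5.5), sex ~ Bernoulli(0.664),
  pack-years ~ N(46.8, 28.3) truncated at 0 — the reported moments of the
  131-subject expression cohort this design emulates.
- **Study sizes.** Defaults mirror the emulated design: a 131-sample
  expression cohort; discovery case-control studies of (1736, 175),
  (838, 791), (366, 414); replication studies of (1000, 1000) and
  (496, 498). The first replication cohort stands in for a family-based
  study analyzed externally; the pipeline consumes only per-study
  association records, so a case-control stand-in of comparable size is
  used rather than a pedigree engine (family-based testing is out of
  scope).
- **Seeding.** One master seed; every component derives a child stream via
  `SeedSequence(master, spawn_key=(slot,))` with fixed slots, so adding a
  downstream stage never perturbs earlier streams, and identical seeds
  give byte-identical serialized bundles.

## Problem sizes used in tests and the acceptance script

Null calibration uses a 5000-pair scan at n = 131 plus 100 null
case-control replicates (120 SNPs, 600 samples each); parameter recovery
uses 50 seeds at n = 131 (cis) and n = 4000 (disease); the end-to-end run
uses a 600-SNP, 60-block panel with one isolated planted cis+disease SNP
(β = 1.2, γ = 0.5) and full-size discovery and replication cohorts over
50 seeds; locus dissection uses a 24-SNP, 3-block locus at n = 2000 with
ε = 0.005 so core-bin r² sits near 0.9. These sizes make every property
measurable with conventional Monte-Carlo error on a desktop.

Note on the null raw-p rate: the 5000 cis tests are clustered (block-mates
test the same probe against correlated dosages), so the effective number
of independent tests is closer to the block count than the pair count; the
p < 0.05 fraction is unbiased at 0.05 but its replicate-to-replicate
spread is wider than the independent-test binomial SE.

## Known limitations

- No trans-eQTL scanning, no per-gene permutation p-values, no mixed
  models or kinship correction, no conditional fine-mapping or
  colocalization, no haplotype phasing.
- The combined analysis assumes a shared covariate scheme across pooled
  studies; real mega-analyses face per-study missingness patterns not
  modeled here.
- The generator does not simulate batch effects, probe-level intensity
  distributions, genotyping error, or realistic recombination maps; LD is
  block-diagonal by construction.
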