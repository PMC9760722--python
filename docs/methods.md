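# Methods

## Interaction model and cohort-level estimation

Each simulated cohort draws `n` individuals with hard-call genotypes
`G ~ Binomial(2, eaf)`, a binary exposure `L ~ Bernoulli(prev)`, independent
standard-normal covariates, and phenotype

    Y = β₀ + β_G G + β_C C + β_L L + β_GL G·L + ε,   ε ~ N(0, σ²).

Cohort summary statistics are obtained by ordinary least squares on the
design `[1, G, L, G·L, C]` with model-based (non-robust) standard errors and
the estimated covariance of `(β̂_G, β̂_GL)` taken from the OLS parameter
covariance. Rationale: at cohort level the generating model is exactly the
fitted model, so model-based SEs are correct by construction; the test suite
verifies calibration empirically (type-I error of the 1df interaction test
within [0.03, 0.07] at nominal 0.05 over 1,000 null replicates, and KS
uniformity of null p-values). Genotypes are hard calls, not dosages; dosage
uncertainty is outside the generator's remit.

Degenerate designs (constant genotype or exposure, rank-deficient design,
fewer than p+10 rows) are rejected rather than silently fitted.

## Meta-analysis

Fixed-effect inverse-variance combination per coefficient: weights
`w_i = 1/se_i²`, pooled `β = Σwβ/Σw`, `se = (Σw)^(-1/2)`. The 2df joint test
uses the multivariate analogue — per-cohort 2×2 precision matrices
`C_i⁻¹` are summed, the pooled vector is `(ΣC_i⁻¹)⁻¹ ΣC_i⁻¹ b_i`, and the
Wald statistic `bᵀ(ΣC_i⁻¹)b` is χ² on 2 df. Both schemes are associative,
so the two-stage combination (within ancestry, then across ancestry-level
estimates) is algebraically identical to one-stage pooling; a test asserts
this to 1e-10 relative tolerance rather than offering it as a toggle.

Scalar marginal estimates (β_GL,meta, se_GL,meta) come from the scalar
inverse-variance path, not the multivariate one, matching the standard
meta-analysis convention and preserving the convex-hull and SE-contraction
invariants; the multivariate path feeds only the joint χ².

Heterogeneity is Cochran's Q on the interaction coefficient β_GL — the
object of every downstream step — across contributing cohorts
(`df = k − 1`); trans-ancestry records measure Q across all cohorts, not
across the four ancestry-level estimates, since the filter is about cohort
consistency. Single-cohort groups have undefined Q (df = 0) and skip the
heterogeneity filter.

QC thresholds are strict inequalities: pooled MAF < 0.01 excluded
(MAF = min(f, 1−f) of the N-weighted pooled effect-allele frequency — the
pooling is a design choice, as is N-weighting), heterogeneity p < 10⁻⁶
excluded. Values exactly at a threshold are retained.

Allele harmonization negates both coefficients and complements the
frequency when a cohort's alleles are swapped relative to the canonical
pair; the (β_G, β_GL) covariance is unchanged because both signs flip.
Strand-ambiguous pairs (A/T, C/G) are flagged but retained — the synthetic
generator is strand-consistent, so dropping them would only lose signal
here; on real data the flag is the hook for a frequency-based strand check.

## Variant screening

Records with 1df interaction p strictly below α = 5×10⁻⁵ are kept, per
analysis context (trait × exposure × ancestry group); a variant passing in
several contexts is retained once per context. α = 1 is accepted as the
degenerate keep-everything screen. Tallies by exposure class, trait class
and ancestry group deduplicate variant ids within each class; the per-model
(row) count is reported alongside because share-of-total statements differ
between the two conventions.

## Locus windows

A gene's locus spans from the start of its first exon to the end of its
last exon pooled over all transcripts, extended by 500,000 bp (exactly) on
both sides; a DNAm site's locus is ±500,000 bp around the probe.
Coordinates are 1-based inclusive internally; BED-like annotation (0-based
half-open) is converted at I/O. The flank boundary is inclusive — a variant
exactly 500 kb from a CpG is "within 500 kb" — and configurable via the
`flank` argument. Windows are clamped to [1, chromosome length]; clamping
is physically necessary at chromosome ends. Overlap queries run on one
interval tree per chromosome and are property-tested against a linear scan.

## Evidence cascade

Tier definitions (per context; locus key = gene × ancestry group × trait ×
exposure):

- **pairing**: significant DMe CpG within the flank of a screened variant,
  CpG context equal to the variant's trait OR exposure. The OR reading is
  the default; an AND mode (probe significant for both) is exposed as
  `context_mode="and"`.
- **candidate**: gene window contains a screened variant and a qualifying
  in-window CpG. The alternative convention — gene window contains a
  variant that has a qualifying CpG anywhere within the flank — is computed
  and reported side by side (`candidate_genes_gene_window` vs
  `candidate_genes_cpg_window`), since the intersection stage can be read
  either way.
- **prioritized**: significant eQTL (variant → gene, any tissue qualifies;
  tissues recorded for reporting) AND significant eQTM (CpG → gene). The
  eQTM table's own CpG–gene linkage is trusted as-is; no additional
  same-window constraint is imposed on the eQTM gene.
- **further prioritized**: significant DExpr record for the gene at the
  locus's exposure class. DExpr sources are exposure-class studies, so
  matching is class-level (smoking vs alcohol), and absent a class's table
  (e.g. no alcohol expression study) its loci can never reach this tier.

Each locus row carries the highest tier reached. Significance is always the
source table's own boolean flag, never re-derived from p-values. The
`joint2df_flag` marks loci where any supporting variant has 2df joint
p < 5×10⁻⁸ (genome-wide; the flag's source names no threshold, so the
conventional one is used). Output ordering is deterministic: ancestry
group, trait, exposure, descending variant count, gene id.

Correctness is checked against a brute-force triple-nested-loop join on
random instances and on planted-truth scenarios.

## Synthetic scenarios

The default scenario plants 3 causal genes (all four evidence links
significant, interaction signal present) and 4 decoys, each withholding one
of {DMe, eQTM, eQTL, GLI-signal} — the four links that gate the prioritized
tier, so a correct cascade returns exactly the causal genes; a
DExpr-withholding decoy (prioritized but never further-prioritized) is
exercised separately in unit tests. Withheld links are emitted as
non-significant rows rather than omitted rows, so the cascade is shown to
filter on the significance flag, not on row absence. Noise rows
(non-significant DMe/DExpr, wrong-context significant CpGs) exercise the
filters.

The synthetic genome is two 10 Mb chromosomes; genes are spaced 1.5 Mb
apart so 500 kb windows never overlap across genes, each gene has two exons
(20 kb span), its variant inside the first exon, and its CpG a seeded
10–400 kb away — always inside the flank. Default generating parameters:
eaf 0.3, exposure prevalence 0.5, noise SD 1, β_GL 0.5 with per-cohort
n = 2,000 and 2 cohorts in each of 2 ancestries — a strong, cleanly
detectable interaction (|z| ≈ 20 at the meta level), appropriate for a
pipeline whose job is bookkeeping correctness rather than borderline power.
Calibration and recovery experiments use the sizes stated with them
(1,000 null cohorts of n = 1,000; 200 replicates of 5 cohorts × n = 4,000,
β_GL = 0.15).

What the generator does **not** emulate: linkage disequilibrium (one
variant per gene, no correlated variants), imputation uncertainty,
population stratification, shared samples between cohorts, realistic
methylation/expression effect-size distributions, or miscalibrated source
studies (significance flags are taken at face value). Passing tests
therefore demonstrate the correctness of the harmonization, meta-analysis
and join logic under the declared model — not robustness of the published
evidence streams themselves.

## Randomness and determinism

A single run seed feeds every stream through labelled substreams:
`SeedSequence([seed, crc32(labels)])`, truncated below 2³¹. Keying by label
(cohort id, variant id, replicate index) means adding a cohort or variant
to a configuration leaves all other draws unchanged. Identical configs
produce byte-identical outputs; the config echo written to each run
directory reproduces the run exactly.

## Numerical notes and limitations

- The 1df p-value is normal-based (consistent with large-sample
  meta-analysis practice), not t-based; at cohort sizes ≥ 50 the difference
  is negligible and the calibration test bounds it empirically.
- Per-cohort covariance matrices are inverted directly (2×2); a singular
  matrix raises rather than being pseudo-inverted.
- Percentages in summaries are rounded to one decimal; a partition can
  therefore sum to 100 ± 0.1.
- The heterogeneity filter is applied to the interaction coefficient only;
  heterogeneity of the main effect is not tested.
- No LD clumping, random-effects models, sample-size-weighted meta-analysis,
  colocalization statistics or mQTL gating are implemented; these are out
  of scope by design.
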