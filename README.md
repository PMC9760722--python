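# gliprio

Summary-level multi-omics prioritization of gene-by-lifestyle interaction
(GLI) loci.

Genome-wide interaction studies report variants whose effect on a
cardiometabolic trait (serum lipids: HDL, LDL, TG; blood pressure: SBP, DBP,
MAP, PP) is modified by a lifestyle exposure (cigarette smoking or alcohol
consumption). Individual-level follow-up of those signals is hard: genetic,
methylation and expression data on the same people are controlled-access and
rarely co-located. `gliprio` implements the alternative: triangulate
*summary-level* evidence streams — differential methylation (DMe), CpG-to-gene
expression links (eQTM), variant-to-gene expression links (eQTL), and
differential expression by exposure (DExpr) — onto 500 kb locus windows
around interaction signals, and rank genes by how many independent molecular
data types support the statistical interaction.

It is written for statistical geneticists and genetic epidemiologists who
have METAL-style interaction summary statistics and published evidence
tables, and for methodologists who want a fully simulated, planted-truth
test bed for evidence-triangulation cascades.

## The model and the cascade

Each contributing cohort fits, per variant, the interaction model

```
Y = β₀ + β_G·G + β_C·C + β_L·L + β_GL·G×L + ε
```

with additive allele coding G ∈ {0,1,2}, binary exposure L, and covariates C.
Cohort estimates (β_G, β_GL) with SEs and covariance are combined by
fixed-effect inverse-variance meta-analysis (weights w_i = 1/se_i²), first
within ancestry groups (EA, AA, HA, ASA), then across ancestry-level
estimates into a trans-ancestry record — an associative scheme, so two-stage
equals one-stage exactly. Each meta record carries:

- the 1df interaction test: two-sided normal test of β_GL,meta / se_GL,meta;
- the 2df joint Wald test of β_G = β_GL = 0 from the summed 2×2 precision
  matrices;
- Cochran's Q heterogeneity on β_GL across cohorts.

QC drops variants with pooled MAF < 1% or heterogeneity p < 10⁻⁶ (strict
inequalities). Variants with interaction p < 5×10⁻⁵ in an analysis context
(trait × exposure × ancestry group) enter the cascade:

1. **pairing** — significant DMe CpGs within 500 kb of the variant, for the
   variant's trait *or* exposure;
2. **candidate** — genes (exon span ± 500 kb, pooled over transcripts) whose
   window contains the variant plus a qualifying CpG;
3. **prioritized** — the variant is a significant eQTL for the gene in ≥ 1
   tissue *and* the CpG is a significant eQTM for the same gene;
4. **further prioritized** — the gene is additionally differentially
   expressed for the locus's exposure class (current/ever smoking → smoking
   DExpr; the drinking exposures → alcohol DExpr).

A synthetic-data module simulates cohorts under the model and fabricates
evidence tables with planted causal genes (all four links) and decoy genes
(exactly one link withheld), so the whole pipeline is testable without any
external download.

## Worked example

```python
from gliprio.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=1, out_dir="runs/demo")   # 3 causal genes, 4 decoys,
result = run_pipeline(cfg)                     # 2 ancestries x 2 cohorts of 2000
print(result["counts"])
```

prints

```
{'n_selected_variants': 6, 'n_variant_cpg_pairs': 15,
 'candidate_genes_gene_window': 5, 'candidate_genes_cpg_window': 5,
 'candidate_loci': 15, 'prioritized_loci': 9,
 'further_prioritized_loci': 9, 'prioritized_genes': 3,
 'further_prioritized_genes': 3}
```

Six variants survive the interaction screen (the three causal genes plus the
three decoys that kept their GLI signal); five genes reach the candidate
tier (the decoy without a matching DMe site drops out); and exactly the
three planted causal genes are prioritized — once per ancestry context (AA,
EA, trans-ancestry), hence 9 locus rows — and all three carry differential
expression, so they are further prioritized. The run directory contains
every stage output (`cohorts.tsv`, `meta.tsv`, `selected.tsv`, `loci.tsv`),
a count summary (`summary.json`), a formatted locus report (`table2.txt`)
whose rows look like

```
[African Ancestry HDL]
Curr Smk	GENE_C1*+	Artery Aorta, Esophagus Mucosa	1
```

(`*` = differential expression by the exposure class, `+` = 2df joint
association), a stage ledger (`log.json`) and an exact config echo
(`run.cfg`) that reproduces the run byte-for-byte.

The same stages are exposed on the command line:

```
gliprio run --config run.cfg
gliprio simulate --config run.cfg --out sim/
gliprio meta --cohorts 'sim/cohorts.tsv' --out meta.tsv
gliprio select --meta meta.tsv --alpha 5e-5 --out selected.tsv
gliprio prioritize --selected selected.tsv --dme sim/dme.tsv \
    --eqtm sim/eqtm.tsv --eqtl sim/eqtl.tsv --dexpr sim/dexpr.tsv \
    --genes sim/genes.bed --out loci.tsv
gliprio report --loci loci.tsv --out report/
```

The package also ships a transcription of a published 48-row
prioritized-locus table (`gliprio.reporting.load_table2_fixture()`), used as
a regression surface for the counting logic: `gliprio report --fixture --out
report/` summarizes it (48 loci; 30 from African-ancestry analyses, 62.5%;
37 smoking-linked; 28 lipid-linked; 5 distinct differentially expressed
genes).

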