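"""Synthetic cohorts and omics evidence with planted truth.

The generator serves two purposes. First, it draws individual-level cohort
data under the interaction model

    Y = b0 + bG*G + bC*C + bL*L + bGL*G*L + e,    e ~ N(0, sigma^2)

with hard-call genotypes G ~ Binomial(2, eaf), a Bernoulli lifestyle exposure
L, and independent standard-normal covariates, then recovers per-cohort
summary statistics by ordinary least squares — the same quantities a
participating cohort would contribute to a meta-analysis (betaG, betaGL,
their SEs and covariance, allele frequency, N).

Second, it fabricates the four downstream evidence streams (differential
methylation, eQTM, eQTL, differential expression) over a small declared
genome, controlled by a :class:`ScenarioTruth`: causal genes receive all four
significant links; each decoy gene withholds exactly one, so the
prioritization cascade has a known right answer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from gliprio import vocab
from gliprio.errors import (
    ConsistencyError,
    DegenerateDesignError,
    InvalidParameterError,
)
from gliprio.harmonize_meta import CohortGliStat

#: Links a decoy gene may withhold. "GLI-signal" means the gene's variant is
#: simulated with betaGL = 0 so it never survives the interaction screen.
WITHHOLDABLE_LINKS = ("DMe", "eQTM", "eQTL", "DExpr", "GLI-signal")

#: Desk-scale synthetic genome: two chromosomes of 10 Mb.
DEFAULT_GENOME: dict[str, int] = {"chr1": 10_000_000, "chr2": 10_000_000}

_TISSUES = (
    "Artery Aorta",
    "Lung",
    "Thyroid",
    "Whole Blood",
    "Muscle Skeletal",
    "Esophagus Mucosa",
)


@dataclass(frozen=True)
class GliModelParams:
    """Parameters of the generating interaction model."""

    beta0: float = 0.0
    beta_G: float = 0.0
    beta_L: float = 0.0
    beta_GL: float = 0.0
    beta_C: tuple[float, ...] = ()
    noise_sd: float = 1.0
    eaf: float = 0.3
    exposure_prev: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise InvalidParameterError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 < self.eaf < 1.0:
            raise InvalidParameterError(f"eaf must be in (0, 1), got {self.eaf}")
        if not 0.0 < self.exposure_prev < 1.0:
            raise InvalidParameterError(
                f"exposure_prev must be in (0, 1), got {self.exposure_prev}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Identity and size of a simulated cohort."""

    cohort_id: str
    n: int
    ancestry: str
    trait: str
    exposure: str
    seed: int

    def __post_init__(self) -> None:
        if self.n < 50:
            raise InvalidParameterError(f"cohort n must be >= 50, got {self.n}")
        vocab.check_ancestry(self.ancestry)
        vocab.check_trait(self.trait)
        vocab.check_exposure(self.exposure)


@dataclass(frozen=True)
class ScenarioTruth:
    """Planted causal and decoy genes for cascade testing.

    ``decoy_genes`` maps each decoy to the single evidence link it withholds;
    ``variant_gene_assignments`` maps every planted variant to its gene.
    """

    causal_genes: frozenset[str]
    decoy_genes: Mapping[str, str]
    variant_gene_assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        overlap = self.causal_genes & set(self.decoy_genes)
        if overlap:
            raise ConsistencyError(f"genes both causal and decoy: {sorted(overlap)}")
        bad = {l for l in self.decoy_genes.values() if l not in WITHHOLDABLE_LINKS}
        if bad:
            raise ConsistencyError(f"unknown withheld links: {sorted(bad)}")
        known = self.causal_genes | set(self.decoy_genes)
        orphans = set(self.variant_gene_assignments.values()) - known
        if orphans:
            raise ConsistencyError(
                f"variants assigned to unknown genes: {sorted(orphans)}"
            )

    @property
    def all_genes(self) -> list[str]:
        return sorted(self.causal_genes) + sorted(self.decoy_genes)


def derive_seed(base_seed: int, *labels: str) -> int:
    """Stable per-stream substream seed (< 2^31) from a base seed and labels.

    Keyed by a CRC of the labels so adding a cohort or variant never perturbs
    the draws of the others.
    """
    crc = zlib.crc32("|".join(labels).encode())
    return int(np.random.SeedSequence([base_seed, crc]).generate_state(1)[0] % (2**31))


def simulate_cohort(
    params: GliModelParams, spec: CohortSpec, n_covariates: int | None = None
) -> pd.DataFrame:
    """Draw one cohort's individual-level table under the interaction model.

    Columns: genotype (0/1/2), exposure (0/1), cov_1..cov_k, phenotype.
    Fully reproducible from ``spec.seed``.
    """
    if n_covariates is None:
        n_covariates = len(params.beta_C)
    if n_covariates < len(params.beta_C):
        raise InvalidParameterError(
            "n_covariates smaller than the number of covariate effects"
        )
    rng = np.random.default_rng(spec.seed)
    g = rng.binomial(2, params.eaf, size=spec.n)
    l = rng.binomial(1, params.exposure_prev, size=spec.n)
    covs = rng.standard_normal(size=(spec.n, n_covariates))
    beta_c = np.zeros(n_covariates)
    beta_c[: len(params.beta_C)] = params.beta_C
    lin = (
        params.beta0
        + params.beta_G * g
        + params.beta_L * l
        + params.beta_GL * g * l
        + covs @ beta_c
    )
    y = lin + rng.normal(0.0, params.noise_sd, size=spec.n)
    data = {"genotype": g, "exposure": l}
    for j in range(n_covariates):
        data[f"cov_{j + 1}"] = covs[:, j]
    data["phenotype"] = y
    return pd.DataFrame(data)


def fit_gli(
    data: pd.DataFrame,
    spec: CohortSpec | None = None,
    variant_meta: Mapping[str, object] | None = None,
) -> CohortGliStat:
    """OLS fit of the interaction model to one cohort's table.

    The design is [1, G, L, G*L, covariates]; returns the cohort summary
    record with betaG, betaGL, their model-based SEs and covariance, the
    empirical effect-allele frequency and sample size. Variant identity and
    context default to placeholders when not supplied.
    """
    cov_cols = [c for c in data.columns if c.startswith("cov_")]
    n, p = len(data), 4 + len(cov_cols)
    if n < p + 10:
        raise DegenerateDesignError(
            f"need at least {p + 10} rows to fit {p} parameters, got {n}"
        )
    g = data["genotype"].to_numpy(dtype=float)
    l = data["exposure"].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise DegenerateDesignError("genotype is constant; betaG not estimable")
    if np.ptp(l) == 0:
        raise DegenerateDesignError("exposure is constant; betaGL not estimable")
    X = np.column_stack(
        [np.ones(n), g, l, g * l] + [data[c].to_numpy(dtype=float) for c in cov_cols]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("collinear design matrix")
    fit = sm.OLS(data["phenotype"].to_numpy(dtype=float), X).fit()
    cov = fit.cov_params()
    meta = dict(variant_meta or {})
    return CohortGliStat(
        variant_id=str(meta.get("variant_id", "var1")),
        chrom=str(meta.get("chrom", "chr1")),
        pos=int(meta.get("pos", 1)),
        effect_allele=str(meta.get("effect_allele", "A")),
        other_allele=str(meta.get("other_allele", "G")),
        eaf=float(g.mean() / 2.0),
        n=n,
        beta_G=float(fit.params[1]),
        se_G=float(fit.bse[1]),
        beta_GL=float(fit.params[3]),
        se_GL=float(fit.bse[3]),
        cov_G_GL=float(cov[1, 3]),
        ancestry=spec.ancestry if spec else "EA",
        trait=spec.trait if spec else "HDL",
        exposure=spec.exposure if spec else "current smoking",
        cohort_id=spec.cohort_id if spec else "cohort",
    )


# ---------------------------------------------------------------------------
# Evidence-table generation


@dataclass(frozen=True)
class GeneLayout:
    gene_id: str
    chrom: str
    exon1: tuple[int, int]  # 1-based inclusive
    exon2: tuple[int, int]
    variant_id: str
    variant_pos: int
    cpg_id: str
    cpg_pos: int


@dataclass
class EvidenceBundle:
    """Evidence tables plus the annotation and variant map behind them."""

    dme: pd.DataFrame
    eqtm: pd.DataFrame
    eqtl: pd.DataFrame
    dexpr: pd.DataFrame
    annotation: pd.DataFrame  # chrom, start, end (1-based), gene_id, transcript_id
    variants: pd.DataFrame  # variant_id, chrom, pos, gene_id, has_gli_signal


def layout_genes(
    truth: ScenarioTruth,
    genome: Mapping[str, int] = DEFAULT_GENOME,
    seed: int = 0,
) -> list[GeneLayout]:
    """Place genes, their variant and their CpG on the synthetic genome.

    Genes are spaced 1.5 Mb apart (round-robin over chromosomes) so their
    500 kb windows never overlap; the CpG sits a seeded 10-400 kb from the
    variant, always within the flank.
    """
    rng = np.random.default_rng(derive_seed(seed, "layout"))
    chroms = sorted(genome)
    gene_to_variant = {g: v for v, g in truth.variant_gene_assignments.items()}
    layouts = []
    per_chrom_counter: dict[str, int] = {c: 0 for c in chroms}
    for i, gene in enumerate(truth.all_genes):
        chrom = chroms[i % len(chroms)]
        slot = per_chrom_counter[chrom]
        per_chrom_counter[chrom] += 1
        start = 1_000_000 + slot * 1_500_000
        if start + 600_000 > genome[chrom]:
            raise ConsistencyError(
                f"synthetic genome too small for {len(truth.all_genes)} genes"
            )
        exon1 = (start, start + 5_000)
        exon2 = (start + 15_000, start + 20_000)
        variant_pos = start + int(rng.integers(0, 5_000))
        cpg_offset = int(rng.integers(10_000, 400_000)) * int(rng.choice([-1, 1]))
        cpg_pos = max(1, min(genome[chrom], variant_pos + cpg_offset))
        layouts.append(
            GeneLayout(
                gene_id=gene,
                chrom=chrom,
                exon1=exon1,
                exon2=exon2,
                variant_id=gene_to_variant.get(gene, f"rs_{gene}"),
                variant_pos=variant_pos,
                cpg_id=f"cg_{gene}",
                cpg_pos=cpg_pos,
            )
        )
    return layouts


def generate_evidence_tables(
    truth: ScenarioTruth,
    genome: Mapping[str, int] = DEFAULT_GENOME,
    seed: int = 0,
    trait: str = "HDL",
    exposure: str = "current smoking",
    n_noise_rows: int = 3,
) -> EvidenceBundle:
    """Fabricate the four evidence streams consistent with the planted truth.

    Every causal gene gets a significant DMe CpG within 500 kb of its
    variant (context = the scenario exposure), a significant eQTM link from
    that CpG, a significant eQTL in >= 1 tissue, and a significant DExpr
    record for the exposure class. Each decoy withholds exactly its declared
    link (the withheld stream carries a non-significant row instead, so the
    cascade is filtering on the significance flag, not on row absence).
    Additional non-significant / wrong-context noise rows are appended.
    """
    vocab.check_trait(trait)
    vocab.check_exposure(exposure)
    rng = np.random.default_rng(derive_seed(seed, "evidence"))
    layouts = layout_genes(truth, genome, seed)
    expo_class = vocab.exposure_class(exposure)
    # a significant-but-irrelevant context exercises the context filter
    off_context = "SBP" if trait != "SBP" else "DBP"

    dme_rows, eqtm_rows, eqtl_rows, dexpr_rows = [], [], [], []
    var_rows, ann_rows = [], []
    for lay in layouts:
        gene = lay.gene_id
        withheld = truth.decoy_genes.get(gene)
        ann_rows.append((lay.chrom, lay.exon1[0], lay.exon1[1], gene, "t1"))
        ann_rows.append((lay.chrom, lay.exon2[0], lay.exon2[1], gene, "t1"))
        var_rows.append(
            (
                lay.variant_id,
                lay.chrom,
                lay.variant_pos,
                gene,
                withheld != "GLI-signal",
            )
        )
        dme_rows.append(
            (
                lay.cpg_id,
                lay.chrom,
                lay.cpg_pos,
                exposure,
                rng.choice(["+", "-"]),
                float(rng.uniform(1e-10, 1e-7)),
                withheld != "DMe",
            )
        )
        eqtm_rows.append(
            (lay.cpg_id, gene, float(rng.uniform(1e-9, 1e-6)), withheld != "eQTM")
        )
        for tissue in sorted(rng.choice(_TISSUES, size=2, replace=False)):
            eqtl_rows.append(
                (
                    lay.variant_id,
                    gene,
                    tissue,
                    float(rng.normal(0, 0.5)),
                    float(rng.uniform(1e-12, 1e-8)),
                    withheld != "eQTL",
                )
            )
        dexpr_rows.append(
            (
                gene,
                expo_class,
                rng.choice(["up", "down"]),
                float(rng.uniform(1e-8, 1e-5)),
                withheld != "DExpr",
            )
        )
        # wrong-context significant CpG near the same variant
        off_pos = max(1, min(genome[lay.chrom], lay.variant_pos + 123_456))
        dme_rows.append(
            (
                f"cg_off_{gene}",
                lay.chrom,
                off_pos,
                off_context,
                "+",
                float(rng.uniform(1e-10, 1e-7)),
                True,
            )
        )
    chroms = sorted(genome)
    for j in range(n_noise_rows):
        chrom = chroms[j % len(chroms)]
        pos = int(rng.integers(1, genome[chrom]))
        dme_rows.append(
            (
                f"cg_noise_{j}",
                chrom,
                pos,
                exposure,
                "-",
                float(rng.uniform(0.2, 0.9)),
                False,
            )
        )
        dexpr_rows.append(
            (f"GENE_NOISE_{j}", expo_class, "up", float(rng.uniform(0.2, 0.9)), False)
        )

    dme = pd.DataFrame(
        dme_rows,
        columns=["cpg_id", "chrom", "pos", "context", "effect_direction", "p", "significant"],
    )
    eqtm = pd.DataFrame(eqtm_rows, columns=["cpg_id", "gene_id", "p", "significant"])
    eqtl = pd.DataFrame(
        eqtl_rows, columns=["variant_id", "gene_id", "tissue", "slope", "p", "significant"]
    )
    dexpr = pd.DataFrame(
        dexpr_rows, columns=["gene_id", "exposure", "direction", "p", "significant"]
    )
    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "gene_id", "transcript_id"]
    )
    variants = pd.DataFrame(
        var_rows, columns=["variant_id", "chrom", "pos", "gene_id", "has_gli_signal"]
    )
    return EvidenceBundle(dme, eqtm, eqtl, dexpr, annotation, variants)


def default_truth(
    n_causal: int = 3,
    withheld_links: Sequence[str] = ("DMe", "eQTM", "eQTL", "GLI-signal"),
) -> ScenarioTruth:
    """Standard study scenario: causal genes plus one decoy per withheld link.

    The default decoys withhold the four links that gate the 'prioritized'
    tier, so a correct cascade returns exactly the causal genes.
    """
    causal = frozenset(f"GENE_C{i + 1}" for i in range(n_causal))
    decoys = {
        f"GENE_D{i + 1}_{link.replace('-', '')}": link
        for i, link in enumerate(withheld_links)
    }
    assignments = {f"rs_{g}": g for g in sorted(set(causal) | set(decoys))}
    return ScenarioTruth(
        causal_genes=causal,
        decoy_genes=decoys,
        variant_gene_assignments=assignments,
    )
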