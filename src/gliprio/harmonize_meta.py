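"""Harmonization and inverse-variance fixed-effect meta-analysis of GLI summary statistics.

Per-cohort records carry the main genetic effect betaG, the gene-by-lifestyle
interaction effect betaGL, their standard errors and covariance. Meta-analysis
is performed first within ancestry groups and the ancestry-level estimates are
then combined into a trans-ancestry (TRANS) record with the same
inverse-variance scheme; because inverse-variance weights are additive this
two-stage combination is algebraically identical to pooling all cohorts at
once, which the test suite verifies.

Two test statistics are produced per meta record:

* the 1df interaction test — two-sided normal test of betaGL_meta / seGL_meta;
* the 2df joint test of betaG = betaGL = 0 — Wald chi-square from the
  multivariate inverse-variance combination (sum of per-cohort 2x2 precision
  matrices).

QC follows the harmonized-pipeline rules: exclude variants with pooled
MAF < 1% or interaction-effect heterogeneity p < 1e-6 (both strict
inequalities). Heterogeneity is Cochran's Q on betaGL across contributing
cohorts; single-cohort groups skip the filter (Q undefined at df = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gliprio.errors import (
    AlleleMismatchError,
    EmptyInputError,
    InsufficientCohortsError,
    InvalidParameterError,
    SingularPrecisionError,
)

#: Base pairs per allele; pairs whose complement equals their reverse cannot be
#: strand-resolved from summary data alone.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

COHORT_TSV_COLUMNS = {
    "MarkerName": "variant_id",
    "Chrom": "chrom",
    "Pos": "pos",
    "Allele1": "effect_allele",
    "Allele2": "other_allele",
    "Freq1": "eaf",
    "N": "n",
    "Effect_G": "beta_G",
    "StdErr_G": "se_G",
    "Effect_GL": "beta_GL",
    "StdErr_GL": "se_GL",
    "Cov_G_GL": "cov_G_GL",
    "P_int": "p_int",
    "Ancestry": "ancestry",
    "Trait": "trait",
    "Exposure": "exposure",
    "Cohort": "cohort_id",
}

META_TSV_COLUMNS = {
    "MarkerName": "variant_id",
    "Chrom": "chrom",
    "Pos": "pos",
    "Allele1": "effect_allele",
    "Allele2": "other_allele",
    "Freq1": "pooled_eaf",
    "MAF": "pooled_maf",
    "N": "n_total",
    "K": "k_cohorts",
    "Beta_meta_G": "beta_G_meta",
    "SE_meta_G": "se_G_meta",
    "Beta_meta_GL": "beta_GL_meta",
    "SE_meta_GL": "se_GL_meta",
    "Cov_meta_G_GL": "cov_G_GL_meta",
    "P_int": "p_int",
    "Chi2_joint": "chi2_joint",
    "P_joint": "p_joint",
    "HetQ": "het_Q",
    "HetDf": "het_df",
    "HetP": "het_p",
    "AncestryGroup": "ancestry_group",
    "Trait": "trait",
    "Exposure": "exposure",
}


@dataclass(frozen=True)
class CohortGliStat:
    """One cohort's GLI estimates for a variant in a trait-by-exposure context."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    n: int
    beta_G: float
    se_G: float
    beta_GL: float
    se_GL: float
    cov_G_GL: float
    ancestry: str
    trait: str
    exposure: str
    cohort_id: str
    strand_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.se_G <= 0 or self.se_GL <= 0:
            raise InvalidParameterError("standard errors must be positive")
        if abs(self.cov_G_GL) > self.se_G * self.se_GL * (1 + 1e-12):
            raise InvalidParameterError(
                "cov_G_GL implies |correlation| > 1 between betaG and betaGL"
            )
        if not 0.0 <= self.eaf <= 1.0:
            raise InvalidParameterError(f"eaf out of [0, 1]: {self.eaf}")

    @property
    def cov_matrix(self) -> np.ndarray:
        """2x2 covariance of (betaG, betaGL)."""
        return np.array(
            [
                [self.se_G**2, self.cov_G_GL],
                [self.cov_G_GL, self.se_GL**2],
            ]
        )


@dataclass(frozen=True)
class MetaGliRecord:
    """Meta-analyzed variant record for one analysis context and ancestry group."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    pooled_eaf: float
    n_total: int
    k_cohorts: int
    beta_GL_meta: float
    se_GL_meta: float
    p_int: float
    beta_G_meta: float
    se_G_meta: float
    cov_G_GL_meta: float
    chi2_joint: float
    p_joint: float
    het_Q: float  # NaN when k_cohorts == 1
    het_df: int
    het_p: float  # NaN when k_cohorts == 1
    ancestry_group: str
    trait: str
    exposure: str

    @property
    def pooled_maf(self) -> float:
        return min(self.pooled_eaf, 1.0 - self.pooled_eaf)


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def align_alleles(stat: CohortGliStat, canonical: tuple[str, str]) -> CohortGliStat:
    """Orient a cohort record to the canonical (effect, other) allele pair.

    If the record's alleles are swapped relative to canonical, both effect
    estimates are negated and the effect-allele frequency complemented; the
    covariance is unchanged because both coefficients flip sign. Strand
    ambiguous pairs (A/T, C/G) pass through with ``strand_ambiguous`` set.
    """
    eff, oth = (a.upper() for a in canonical)
    a1, a2 = stat.effect_allele.upper(), stat.other_allele.upper()
    ambiguous = is_strand_ambiguous(a1, a2)
    if (a1, a2) == (eff, oth):
        return replace(stat, strand_ambiguous=ambiguous)
    if (a1, a2) == (oth, eff):
        return replace(
            stat,
            effect_allele=eff,
            other_allele=oth,
            beta_G=-stat.beta_G,
            beta_GL=-stat.beta_GL,
            eaf=1.0 - stat.eaf,
            strand_ambiguous=ambiguous,
        )
    raise AlleleMismatchError(
        f"{stat.variant_id} in {stat.cohort_id}: alleles ({a1},{a2}) do not "
        f"match canonical ({eff},{oth}) in either order"
    )


def inverse_variance_meta(
    estimates: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Fixed-effect inverse-variance pooling of (beta, se) pairs.

    Weights are w_i = 1/se_i^2; the pooled estimate is the weighted mean and
    its standard error sqrt(1 / sum(w)).
    """
    if not estimates:
        raise EmptyInputError("inverse_variance_meta requires >= 1 estimate")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise InvalidParameterError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(math.sqrt(1.0 / np.sum(w)))
    return beta_meta, se_meta


def cochran_q(
    estimates: Sequence[tuple[float, float]], beta_meta: float
) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q = sum w_i (b_i - beta_meta)^2, df = k - 1."""
    if len(estimates) < 2:
        raise InsufficientCohortsError(
            "heterogeneity requires >= 2 estimates (Q undefined at df = 0)"
        )
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - beta_meta) ** 2))
    df = len(estimates) - 1
    het_p = float(stats.chi2.sf(q, df))
    return q, df, het_p


def joint_2df_meta(
    stats_or_pairs: Sequence,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Multivariate inverse-variance combination of (betaG, betaGL) vectors.

    Accepts CohortGliStat records or (beta_vec, cov_matrix) pairs. Per-cohort
    precision matrices are summed; the pooled vector is
    cov_meta @ sum(C_i^-1 b_i) with cov_meta the inverse precision sum. The
    Wald statistic b' cov_meta^-1 b is chi-square on 2 df under the joint null.
    """
    if not stats_or_pairs:
        raise EmptyInputError("joint_2df_meta requires >= 1 cohort")
    precision = np.zeros((2, 2))
    score = np.zeros(2)
    for item in stats_or_pairs:
        if isinstance(item, CohortGliStat):
            b = np.array([item.beta_G, item.beta_GL])
            cov = item.cov_matrix
        else:
            b, cov = item
            b = np.asarray(b, dtype=float)
            cov = np.asarray(cov, dtype=float)
        try:
            prec_i = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise SingularPrecisionError(
                "singular per-cohort covariance of (betaG, betaGL)"
            ) from exc
        precision += prec_i
        score += prec_i @ b
    try:
        cov_meta = np.linalg.inv(precision)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - needs adversarial input
        raise SingularPrecisionError("singular pooled precision matrix") from exc
    beta_meta = cov_meta @ score
    chi2 = float(beta_meta @ precision @ beta_meta)
    p_joint = float(stats.chi2.sf(chi2, 2))
    return beta_meta, cov_meta, chi2, p_joint


def _p_two_sided(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _combine(
    cohort_stats: Sequence[CohortGliStat],
    ancestry_group: str,
    het_stats: Sequence[CohortGliStat] | None = None,
) -> MetaGliRecord:
    """Pool one group of cohort records into a meta record.

    ``het_stats`` lets TRANS records measure heterogeneity across the original
    cohorts rather than the ancestry-level estimates.
    """
    first = cohort_stats[0]
    gl = [(s.beta_GL, s.se_GL) for s in cohort_stats]
    g = [(s.beta_G, s.se_G) for s in cohort_stats]
    beta_gl, se_gl = inverse_variance_meta(gl)
    beta_g, se_g = inverse_variance_meta(g)
    _, cov_meta, chi2, p_joint = joint_2df_meta(cohort_stats)

    het_src = het_stats if het_stats is not None else cohort_stats
    if len(het_src) >= 2:
        het_beta, _ = inverse_variance_meta([(s.beta_GL, s.se_GL) for s in het_src])
        q, df, het_p = cochran_q([(s.beta_GL, s.se_GL) for s in het_src], het_beta)
    else:
        q, df, het_p = float("nan"), 0, float("nan")

    n_total = int(sum(s.n for s in het_src))
    pooled_eaf = float(
        sum(s.eaf * s.n for s in het_src) / max(1, n_total)
    )
    return MetaGliRecord(
        variant_id=first.variant_id,
        chrom=first.chrom,
        pos=first.pos,
        effect_allele=first.effect_allele,
        other_allele=first.other_allele,
        pooled_eaf=pooled_eaf,
        n_total=n_total,
        k_cohorts=len(het_src),
        beta_GL_meta=beta_gl,
        se_GL_meta=se_gl,
        p_int=_p_two_sided(beta_gl, se_gl),
        beta_G_meta=beta_g,
        se_G_meta=se_g,
        cov_G_GL_meta=float(cov_meta[0, 1]),
        chi2_joint=chi2,
        p_joint=p_joint,
        het_Q=q,
        het_df=df,
        het_p=het_p,
        ancestry_group=ancestry_group,
        trait=first.trait,
        exposure=first.exposure,
    )


def _ancestry_record_as_stat(rec: MetaGliRecord) -> CohortGliStat:
    """View an ancestry-level meta record as a pseudo-cohort for stage two."""
    return CohortGliStat(
        variant_id=rec.variant_id,
        chrom=rec.chrom,
        pos=rec.pos,
        effect_allele=rec.effect_allele,
        other_allele=rec.other_allele,
        eaf=rec.pooled_eaf,
        n=rec.n_total,
        beta_G=rec.beta_G_meta,
        se_G=rec.se_G_meta,
        beta_GL=rec.beta_GL_meta,
        se_GL=rec.se_GL_meta,
        cov_G_GL=rec.cov_G_GL_meta,
        ancestry=rec.ancestry_group,
        trait=rec.trait,
        exposure=rec.exposure,
        cohort_id=f"meta:{rec.ancestry_group}",
    )


def meta_analyze(cohort_stats: Iterable[CohortGliStat]) -> list[MetaGliRecord]:
    """Two-stage meta-analysis: within-ancestry, then trans-ancestry.

    Records are grouped by (variant, trait, exposure); each ancestry present
    yields one record, and groups spanning >= 1 ancestry also yield a TRANS
    record combining the ancestry-level estimates. Heterogeneity for the
    TRANS record is computed across all contributing cohorts.
    """
    groups: dict[tuple, list[CohortGliStat]] = {}
    for s in cohort_stats:
        groups.setdefault((s.variant_id, s.trait, s.exposure), []).append(s)

    out: list[MetaGliRecord] = []
    for key in sorted(groups):
        members = groups[key]
        by_anc: dict[str, list[CohortGliStat]] = {}
        for s in members:
            by_anc.setdefault(s.ancestry, []).append(s)
        anc_records = [
            _combine(by_anc[a], ancestry_group=a) for a in sorted(by_anc)
        ]
        out.extend(anc_records)
        pseudo = [_ancestry_record_as_stat(r) for r in anc_records]
        out.append(_combine(pseudo, ancestry_group="TRANS", het_stats=members))
    return out


def qc_filter(
    records: Sequence[MetaGliRecord],
    maf_min: float = 0.01,
    het_alpha: float = 1e-6,
) -> tuple[list[MetaGliRecord], pd.DataFrame]:
    """Apply the MAF and heterogeneity exclusions (strict inequalities).

    Returns the retained records and an exclusion log with one row per
    dropped record (reason 'low MAF' or 'heterogeneity'). Records with
    undefined heterogeneity (single cohort) skip the heterogeneity filter.
    """
    kept: list[MetaGliRecord] = []
    log_rows: list[dict] = []
    for rec in records:
        if rec.pooled_maf < maf_min:
            log_rows.append(
                {
                    "variant_id": rec.variant_id,
                    "ancestry_group": rec.ancestry_group,
                    "trait": rec.trait,
                    "exposure": rec.exposure,
                    "reason": "low MAF",
                    "value": rec.pooled_maf,
                }
            )
        elif not math.isnan(rec.het_p) and rec.het_p < het_alpha:
            log_rows.append(
                {
                    "variant_id": rec.variant_id,
                    "ancestry_group": rec.ancestry_group,
                    "trait": rec.trait,
                    "exposure": rec.exposure,
                    "reason": "heterogeneity",
                    "value": rec.het_p,
                }
            )
        else:
            kept.append(rec)
    log = pd.DataFrame(
        log_rows,
        columns=["variant_id", "ancestry_group", "trait", "exposure", "reason", "value"],
    )
    return kept, log


# ---------------------------------------------------------------------------
# Frame / TSV conversion


def records_to_frame(records: Sequence[MetaGliRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {name: getattr(r, name) for name in MetaGliRecord.__dataclass_fields__}
        d["pooled_maf"] = r.pooled_maf
        rows.append(d)
    cols = list(MetaGliRecord.__dataclass_fields__) + ["pooled_maf"]
    return pd.DataFrame(rows, columns=cols)


def stats_to_frame(stats_list: Sequence[CohortGliStat]) -> pd.DataFrame:
    cols = [c for c in CohortGliStat.__dataclass_fields__ if c != "strand_ambiguous"]
    return pd.DataFrame(
        [{c: getattr(s, c) for c in cols} for s in stats_list], columns=cols
    )


def frame_to_stats(df: pd.DataFrame) -> list[CohortGliStat]:
    cols = [c for c in CohortGliStat.__dataclass_fields__ if c != "strand_ambiguous"]
    return [
        CohortGliStat(**{c: row[c] for c in cols})
        for row in df.to_dict(orient="records")
    ]


def write_cohort_tsv(stats_list: Sequence[CohortGliStat], path: str | Path) -> None:
    df = stats_to_frame(stats_list)
    df["p_int"] = [
        _p_two_sided(s.beta_GL, s.se_GL) for s in stats_list
    ]
    inv = {v: k for k, v in COHORT_TSV_COLUMNS.items()}
    df.rename(columns=inv)[list(COHORT_TSV_COLUMNS)].to_csv(
        path, sep="\t", index=False
    )


def read_cohort_tsv(path: str | Path) -> list[CohortGliStat]:
    df = pd.read_csv(path, sep="\t").rename(columns=COHORT_TSV_COLUMNS)
    return frame_to_stats(df.drop(columns=["p_int"], errors="ignore"))


def write_meta_tsv(records: Sequence[MetaGliRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    inv = {v: k for k, v in META_TSV_COLUMNS.items()}
    df.rename(columns=inv)[list(META_TSV_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_meta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").rename(columns=META_TSV_COLUMNS)
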