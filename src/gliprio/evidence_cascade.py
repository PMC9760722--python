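"""Multi-omics prioritization cascade for gene-by-lifestyle interaction loci.

Starting from screened GLI variants, the cascade accumulates evidence in
tiers:

1. **pairing** — significantly differentially methylated CpG sites within
   500 kb of a screened variant, for the variant's trait or exposure of
   interest;
2. **candidate** — genes whose flanked exon-span window contains a screened
   variant and a qualifying CpG (the gene-window intersection stage);
3. **prioritized** — candidate contexts where the variant is a significant
   eQTL for the gene in at least one tissue AND the CpG is a significant
   eQTM for the same gene;
4. **further_prioritized** — prioritized loci whose gene is additionally
   differentially expressed for the locus's exposure class.

A "locus" is keyed by (gene, ancestry group, trait, exposure); one gene may
appear in several contexts. All joins trust each evidence table's own
significance flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from gliprio import vocab
from gliprio.errors import VocabularyError
from gliprio.locus_builder import (
    DEFAULT_FLANK,
    GeneLocus,
    LocusIndex,
    gene_windows_from_annotation,
)

TIERS = ("candidate", "prioritized", "further_prioritized")

LOCI_COLUMNS = [
    "ancestry_group",
    "trait",
    "exposure",
    "gene_id",
    "tier",
    "n_variants",
    "variant_ids",
    "cpg_ids",
    "eqtl_tissues",
    "dexpr_flag",
    "joint2df_flag",
]

PAIR_COLUMNS = [
    "variant_id",
    "chrom",
    "variant_pos",
    "cpg_id",
    "cpg_pos",
    "context",
    "distance",
    "ancestry_group",
    "trait",
    "exposure",
]

_LOCUS_KEY = ["gene_id", "ancestry_group", "trait", "exposure"]


@dataclass
class EvidenceTables:
    """The four evidence streams consumed by the cascade.

    dme:   cpg_id, chrom, pos, context (a trait or exposure label), significant
    eqtm:  cpg_id, gene_id, significant
    eqtl:  variant_id, gene_id, tissue, significant
    dexpr: gene_id, exposure (class label: smoking/alcohol), significant
    """

    dme: pd.DataFrame
    eqtm: pd.DataFrame
    eqtl: pd.DataFrame
    dexpr: pd.DataFrame

    def validate(self) -> None:
        for name, df, required in (
            ("dme", self.dme, {"cpg_id", "chrom", "pos", "context", "significant"}),
            ("eqtm", self.eqtm, {"cpg_id", "gene_id", "significant"}),
            ("eqtl", self.eqtl, {"variant_id", "gene_id", "tissue", "significant"}),
            ("dexpr", self.dexpr, {"gene_id", "exposure", "significant"}),
        ):
            missing = required - set(df.columns)
            if missing:
                raise VocabularyError(f"{name} table missing columns: {sorted(missing)}")
        known_contexts = set(vocab.TRAITS) | set(vocab.EXPOSURES)
        bad = set(self.dme["context"]) - known_contexts
        if bad:
            raise VocabularyError(f"dme contexts outside vocabulary: {sorted(bad)}")


def find_dnam_near_variants(
    selected: pd.DataFrame,
    dme: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    context_mode: str = "or",
) -> pd.DataFrame:
    """Pair screened variants with nearby significant DNAm sites.

    A CpG qualifies for a variant when it is significant, lies on the same
    chromosome within ``flank`` bp (inclusive boundary), and its context
    matches the variant's trait or exposure. ``context_mode='and'`` demands
    the CpG be significant for both the trait and the exposure (matched as
    two rows of the DMe table for the same probe).
    """
    if context_mode not in ("or", "and"):
        raise VocabularyError(f"context_mode must be 'or' or 'and': {context_mode!r}")
    if selected.empty or dme.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    sig = dme.loc[dme["significant"].astype(bool)]
    merged = selected.merge(
        sig.rename(columns={"pos": "cpg_pos"}), on="chrom", suffixes=("", "_dme")
    )
    merged["distance"] = (merged["pos"] - merged["cpg_pos"]).abs()
    merged = merged.loc[merged["distance"] <= flank]
    hit_trait = merged["context"] == merged["trait"]
    hit_expo = merged["context"] == merged["exposure"]
    merged = merged.loc[hit_trait | hit_expo]
    if context_mode == "and":
        # keep only probes qualifying under both contexts for this variant
        key = ["variant_id", "cpg_id", "trait", "exposure", "ancestry_group"]
        both = (
            merged.assign(
                _t=(merged["context"] == merged["trait"]),
                _e=(merged["context"] == merged["exposure"]),
            )
            .groupby(key)[["_t", "_e"]]
            .any()
        )
        ok = both.index[both["_t"] & both["_e"]]
        merged = merged.set_index(key).loc[ok].reset_index()
    merged = merged.rename(columns={"pos": "variant_pos"})
    extra = [c for c in ("p_joint",) if c in merged.columns]
    out = merged[PAIR_COLUMNS + extra].drop_duplicates(
        subset=["variant_id", "cpg_id", "context", "trait", "exposure", "ancestry_group"]
    )
    return out.sort_values(PAIR_COLUMNS[:6]).reset_index(drop=True)


def _aggregate_loci(qualifying: pd.DataFrame, tier: str) -> pd.DataFrame:
    """Collapse qualifying (variant, cpg, gene, tissue) rows into locus rows."""
    if qualifying.empty:
        return pd.DataFrame(columns=LOCI_COLUMNS)

    def _agg(grp: pd.DataFrame) -> pd.Series:
        variants = sorted(set(grp["variant_id"]))
        cpgs = sorted(set(grp["cpg_id"]))
        tissues = sorted(set(grp["tissue"])) if "tissue" in grp else []
        tissues = [t for t in tissues if t]
        joint = bool(grp["joint_sig"].any()) if "joint_sig" in grp else False
        return pd.Series(
            {
                "tier": tier,
                "n_variants": len(variants),
                "variant_ids": variants,
                "cpg_ids": cpgs,
                "eqtl_tissues": tissues,
                "dexpr_flag": False,
                "joint2df_flag": joint,
            }
        )

    out = (
        qualifying.groupby(_LOCUS_KEY, sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out[LOCI_COLUMNS]


def prioritize(
    pairs: pd.DataFrame, eqtl: pd.DataFrame, eqtm: pd.DataFrame
) -> pd.DataFrame:
    """Tier 'prioritized': gene with a significant eQTL from the variant AND
    a significant eQTM from the paired CpG.

    Loci are aggregated per (gene, ancestry group, trait, exposure) with the
    supporting variant list, CpG list and union of qualifying eQTL tissues.
    """
    if pairs.empty or eqtl.empty or eqtm.empty:
        return pd.DataFrame(columns=LOCI_COLUMNS)
    eqtl_sig = eqtl.loc[eqtl["significant"].astype(bool), ["variant_id", "gene_id", "tissue"]]
    eqtm_sig = eqtm.loc[eqtm["significant"].astype(bool), ["cpg_id", "gene_id"]]
    joined = pairs.merge(eqtl_sig, on="variant_id").merge(
        eqtm_sig, on=["cpg_id", "gene_id"]
    )
    if "p_joint" in joined.columns:
        joined["joint_sig"] = joined["p_joint"] < 5e-8
    return _aggregate_loci(joined, "prioritized")


def further_prioritize(prioritized: pd.DataFrame, dexpr: pd.DataFrame) -> pd.DataFrame:
    """Tier 'further_prioritized': the gene is differentially expressed for
    the locus's exposure class.

    Exposure matching is class-level: current/ever smoking map to smoking
    DExpr evidence, the drinking exposures to alcohol DExpr evidence. With no
    DExpr table rows for a class (e.g. no alcohol expression study), loci of
    that class can never reach this tier.
    """
    if prioritized.empty:
        return prioritized.iloc[0:0].copy()

    def _to_class(label: str) -> str:
        # DExpr sources are exposure-class studies; accept either a class
        # label directly or a specific exposure mapped to its class
        return label if label in vocab.EXPOSURE_CLASSES else vocab.exposure_class(label)

    sig_classes = (
        {
            (r.gene_id, _to_class(str(r.exposure)))
            for r in dexpr.loc[dexpr["significant"].astype(bool)].itertuples()
        }
        if not dexpr.empty
        else set()
    )
    keep = prioritized.apply(
        lambda r: (r["gene_id"], vocab.exposure_class(r["exposure"])) in sig_classes,
        axis=1,
    )
    out = prioritized.loc[keep].copy()
    out["tier"] = "further_prioritized"
    out["dexpr_flag"] = True
    return out.reset_index(drop=True)


def candidate_loci(
    selected: pd.DataFrame,
    dme: pd.DataFrame,
    gene_windows: Mapping[str, GeneLocus],
    flank: int = DEFAULT_FLANK,
    context_mode: str = "or",
) -> pd.DataFrame:
    """Tier 'candidate': gene windows containing a screened variant plus an
    in-window qualifying DMe site (the gene-window intersection stage)."""
    if selected.empty or not gene_windows:
        return pd.DataFrame(columns=LOCI_COLUMNS)
    index = LocusIndex(gene_windows.values())
    sig_dme = dme.loc[dme["significant"].astype(bool)] if not dme.empty else dme
    rows = []
    for var in selected.itertuples():
        for locus in index.query(var.chrom, int(var.pos)):
            w = locus.window
            in_win = sig_dme.loc[
                (sig_dme["chrom"] == w.chrom)
                & (sig_dme["pos"] >= w.start)
                & (sig_dme["pos"] <= w.end)
            ]
            ctx_ok = (in_win["context"] == var.trait) | (
                in_win["context"] == var.exposure
            )
            if context_mode == "and":
                probes = in_win.loc[ctx_ok]
                by_probe = probes.groupby("cpg_id")["context"].agg(set)
                qualifying = by_probe.index[
                    by_probe.apply(lambda s: var.trait in s and var.exposure in s)
                ]
                in_win = probes.loc[probes["cpg_id"].isin(qualifying)]
            else:
                in_win = in_win.loc[ctx_ok]
            if in_win.empty:
                continue
            for cpg in in_win.itertuples():
                rows.append(
                    {
                        "gene_id": locus.gene_id,
                        "ancestry_group": var.ancestry_group,
                        "trait": var.trait,
                        "exposure": var.exposure,
                        "variant_id": var.variant_id,
                        "cpg_id": cpg.cpg_id,
                        "joint_sig": getattr(var, "p_joint", float("nan")) < 5e-8,
                    }
                )
    return _aggregate_loci(pd.DataFrame(rows), "candidate")


def sort_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Deterministic report order: ancestry, trait, exposure, descending
    variant count, gene id."""
    if loci.empty:
        return loci.reset_index(drop=True)
    df = loci.copy()
    df["_anc"] = df["ancestry_group"].map(
        {a: i for i, a in enumerate(vocab.ANCESTRY_GROUPS)}
    )
    df["_trait"] = df["trait"].map({t: i for i, t in enumerate(vocab.TRAITS)})
    df["_expo"] = df["exposure"].map({e: i for i, e in enumerate(vocab.EXPOSURES)})
    df = df.sort_values(
        ["_anc", "_trait", "_expo", "n_variants", "gene_id"],
        ascending=[True, True, True, False, True],
    )
    return df.drop(columns=["_anc", "_trait", "_expo"]).reset_index(drop=True)


def run_cascade(
    selected: pd.DataFrame,
    evidence: EvidenceTables,
    annotation: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    context_mode: str = "or",
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full cascade; returns the tiered locus table and step counts.

    Each locus row carries the highest tier it reached. The counts report
    both candidate-gene conventions: variant-in-gene-window (reported) and
    variant-near-CpG (genes whose window holds a variant with a qualifying
    paired CpG anywhere within the flank).
    """
    evidence.validate()
    windows = gene_windows_from_annotation(
        annotation, flank=flank, chrom_lengths=chrom_lengths
    )
    pairs = find_dnam_near_variants(
        selected, evidence.dme, flank=flank, context_mode=context_mode
    )
    cand = candidate_loci(
        selected, evidence.dme, windows, flank=flank, context_mode=context_mode
    )
    prio = prioritize(pairs, evidence.eqtl, evidence.eqtm)
    further = further_prioritize(prio, evidence.dexpr)

    # variant-near-CpG convention for the candidate-gene count
    paired_variants = set(pairs["variant_id"]) if not pairs.empty else set()
    index = LocusIndex(windows.values())
    cpg_conv_genes: set[str] = set()
    for var in selected.itertuples():
        if var.variant_id in paired_variants:
            for locus in index.query(var.chrom, int(var.pos)):
                cpg_conv_genes.add(locus.gene_id)

    tiers = pd.concat([cand, prio, further], ignore_index=True)
    if not tiers.empty:
        rank = {t: i for i, t in enumerate(TIERS)}
        tiers["_rank"] = tiers["tier"].map(rank)
        best = (
            tiers.sort_values("_rank", ascending=False)
            .drop_duplicates(subset=_LOCUS_KEY, keep="first")
            .drop(columns="_rank")
        )
    else:
        best = tiers
    loci = sort_loci(best)

    counts = {
        "n_selected_variants": int(selected["variant_id"].nunique())
        if not selected.empty
        else 0,
        "n_variant_cpg_pairs": int(len(pairs)),
        "candidate_genes_gene_window": int(cand["gene_id"].nunique())
        if not cand.empty
        else 0,
        "candidate_genes_cpg_window": len(cpg_conv_genes),
        "candidate_loci": int(len(cand)),
        "prioritized_loci": int(len(prio)),
        "further_prioritized_loci": int(len(further)),
        "prioritized_genes": int(prio["gene_id"].nunique()) if not prio.empty else 0,
        "further_prioritized_genes": int(further["gene_id"].nunique())
        if not further.empty
        else 0,
    }
    return loci, counts


def loci_to_tsv(loci: pd.DataFrame, path) -> None:
    """Write a locus table with list columns flattened to comma-joins."""
    df = loci.copy()
    for col in ("variant_ids", "cpg_ids", "eqtl_tissues"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: ",".join(v) if isinstance(v, list) else v)
    df.to_csv(path, sep="\t", index=False)


def loci_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_ids", "cpg_ids", "eqtl_tissues"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: [] if pd.isna(v) or v == "" else str(v).split(",")
            )
    return df
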