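"""Count surfaces and formatted reports over tiered locus tables.

``summarize_loci`` reduces a prioritized-locus table to the counts a study
write-up quotes: totals, partitions by ancestry group, exposure class and
trait class, ancestry shares, and the number of distinct differentially
expressed genes. ``emit_table2`` renders the table in the field's familiar
layout — rows grouped under ancestry-by-trait headings with exposure
abbreviations and footnote flags — and ``parse_table2`` reads that text back
for round-trip checks.

The packaged fixture ``table2_loci.tsv`` transcribes a published 48-row
prioritized-locus table and serves as a regression surface for the counting
logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from gliprio import vocab
from gliprio.errors import VocabularyError
from gliprio.variant_selection import SelectionTally

_ABBREV_TO_EXPOSURE = {v: k for k, v in vocab.EXPOSURE_ABBREV.items()}
_LABEL_TO_ANCESTRY = {v: k for k, v in vocab.ANCESTRY_LABELS.items()}

#: Tiers that count as "prioritized" for summary purposes.
_REPORT_TIERS = ("prioritized", "further_prioritized")


@dataclass
class LocusSummary:
    """Count surfaces over a prioritized-locus table."""

    total_loci: int = 0
    by_ancestry_group: dict[str, int] = field(default_factory=dict)
    by_exposure_class: dict[str, int] = field(default_factory=dict)
    by_trait_class: dict[str, int] = field(default_factory=dict)
    fraction_by_ancestry: dict[str, float] = field(default_factory=dict)
    n_distinct_dexpr_genes: int = 0
    cross_tab: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "total_loci": self.total_loci,
            "by_ancestry_group": self.by_ancestry_group,
            "by_exposure_class": self.by_exposure_class,
            "by_trait_class": self.by_trait_class,
            "fraction_by_ancestry": self.fraction_by_ancestry,
            "n_distinct_dexpr_genes": self.n_distinct_dexpr_genes,
            "cross_tab": {f"{a}|{e}": v for (a, e), v in self.cross_tab.items()},
        }
        return d


def _report_rows(loci: pd.DataFrame) -> pd.DataFrame:
    if "tier" in loci.columns:
        return loci.loc[loci["tier"].isin(_REPORT_TIERS)]
    return loci


def summarize_loci(loci: pd.DataFrame) -> LocusSummary:
    """Summarize a locus table (rows at tier prioritized or above)."""
    df = _report_rows(loci)
    summary = LocusSummary()
    if df.empty:
        return summary
    unknown_traits = set(df["trait"]) - set(vocab.TRAITS)
    unknown_expos = set(df["exposure"]) - set(vocab.EXPOSURES)
    if unknown_traits or unknown_expos:
        raise VocabularyError(
            f"labels outside vocabulary: {sorted(unknown_traits | unknown_expos)}"
        )
    df = df.assign(
        exposure_class=df["exposure"].map(vocab.exposure_class),
        trait_class=df["trait"].map(vocab.trait_class),
    )
    summary.total_loci = len(df)
    summary.by_ancestry_group = (
        df.groupby("ancestry_group").size().astype(int).to_dict()
    )
    summary.by_exposure_class = (
        df.groupby("exposure_class").size().astype(int).to_dict()
    )
    summary.by_trait_class = df.groupby("trait_class").size().astype(int).to_dict()
    summary.fraction_by_ancestry = {
        k: round(100.0 * v / summary.total_loci, 1)
        for k, v in summary.by_ancestry_group.items()
    }
    flagged = df.loc[df["dexpr_flag"].astype(bool), "gene_id"]
    summary.n_distinct_dexpr_genes = int(flagged.nunique())
    summary.cross_tab = {
        (str(a), str(e)): int(v)
        for (a, e), v in df.groupby(["ancestry_group", "exposure_class"])
        .size()
        .items()
    }
    return summary


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged 48-row prioritized-locus transcription."""
    with resources.files("gliprio.data").joinpath("table2_loci.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["dexpr_flag"] = df["dexpr_flag"].astype(bool)
    df["joint2df_flag"] = df["joint2df_flag"].astype(bool)
    df["eqtl_tissues"] = df["eqtl_tissues"].map(lambda s: [t.strip() for t in s.split(",")])
    return df


def emit_table2(loci: pd.DataFrame) -> str:
    """Render prioritized loci grouped under ancestry-by-trait headings.

    Footnote markers: ``*`` = differential expression by the exposure class,
    ``+`` = 2df joint association at the locus.
    """
    df = _report_rows(loci)
    lines = ["Exposure\tGene target\teQTL Tissue(s)\tNumber of GLI variants"]
    if df.empty:
        return "\n".join(lines) + "\n"
    df = df.copy()
    df["_anc"] = df["ancestry_group"].map(
        {a: i for i, a in enumerate(vocab.ANCESTRY_GROUPS)}
    )
    df["_trait"] = df["trait"].map({t: i for i, t in enumerate(vocab.TRAITS)})
    df["_expo"] = df["exposure"].map({e: i for i, e in enumerate(vocab.EXPOSURES)})
    df = df.sort_values(
        ["_anc", "_trait", "_expo", "n_variants", "gene_id"],
        ascending=[True, True, True, False, True],
    )
    for (anc, trait), grp in df.groupby(["ancestry_group", "trait"], sort=False):
        lines.append(f"[{vocab.ANCESTRY_LABELS[anc]} {trait}]")
        for row in grp.itertuples():
            tissues = row.eqtl_tissues
            if isinstance(tissues, list):
                tissues = ", ".join(tissues)
            flags = ""
            if bool(row.dexpr_flag):
                flags += "*"
            if bool(row.joint2df_flag):
                flags += "+"
            lines.append(
                f"{vocab.EXPOSURE_ABBREV[row.exposure]}\t{row.gene_id}{flags}\t"
                f"{tissues}\t{row.n_variants}"
            )
    lines.append("")
    lines.append("* differential expression by exposure; + 2df joint association")
    return "\n".join(lines) + "\n"


def parse_table2(text: str) -> pd.DataFrame:
    """Parse ``emit_table2`` output back into a locus frame (round trip)."""
    rows = []
    anc = trait = None
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("Exposure\t") or line.startswith("* "):
            continue
        if line.startswith("[") and line.endswith("]"):
            heading = line[1:-1]
            label, trait = heading.rsplit(" ", 1)
            anc = _LABEL_TO_ANCESTRY[label]
            continue
        abbrev, gene, tissues, n_var = line.split("\t")
        gene_id = gene.rstrip("*+")
        suffix = gene[len(gene_id):]
        dexpr = "*" in suffix
        joint = "+" in suffix
        rows.append(
            {
                "ancestry_group": anc,
                "trait": trait,
                "exposure": _ABBREV_TO_EXPOSURE[abbrev],
                "gene_id": gene_id,
                "eqtl_tissues": [t.strip() for t in tissues.split(",") if t.strip()],
                "n_variants": int(n_var),
                "dexpr_flag": dexpr,
                "joint2df_flag": joint,
                "tier": "further_prioritized" if dexpr else "prioritized",
            }
        )
    return pd.DataFrame(rows)


def selection_report(tally: SelectionTally) -> pd.DataFrame:
    """Tabulate selection tallies: one row per class and per analysis cell."""
    rows = [
        {"level": "total", "key": "unique variants", "count": tally.total_unique},
        {"level": "total", "key": "per-model rows", "count": tally.total_per_model},
    ]
    for name, mapping in (
        ("exposure_class", tally.by_exposure_class),
        ("trait_class", tally.by_trait_class),
        ("ancestry_group", tally.by_ancestry_group),
    ):
        for key in sorted(mapping):
            rows.append({"level": name, "key": key, "count": int(mapping[key])})
    for (trait, exposure, anc) in sorted(tally.per_cell):
        rows.append(
            {
                "level": "cell",
                "key": f"{trait}|{exposure}|{anc}",
                "count": int(tally.per_cell[(trait, exposure, anc)]),
            }
        )
    return pd.DataFrame(rows, columns=["level", "key", "count"])


def write_summary_json(summary: LocusSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_json_dict(), indent=2) + "\n")
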