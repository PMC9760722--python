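"""Interaction-significance screen and selection tallies.

Variants are screened per analysis set — one (trait, exposure, ancestry
group) context — keeping records whose 1df interaction p-value is strictly
below the threshold (5e-5 by default). A variant passing in several contexts
is retained once per context; tallies over exposure class, trait class and
ancestry group deduplicate by variant id within each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from gliprio import vocab
from gliprio.errors import InvalidParameterError

DEFAULT_ALPHA = 5e-5

SELECTED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "trait",
    "exposure",
    "ancestry_group",
    "beta_GL_meta",
    "se_GL_meta",
    "p_int",
    "p_joint",
]


def select_gli_variants(meta: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Keep meta records with p_int < alpha (strict), per analysis context.

    Input is a meta-analysis frame (QC-passing records) carrying trait,
    exposure and ancestry_group columns; output keeps one row per retained
    (variant, context) with the selection columns.
    """
    # alpha = 1 is the degenerate screen that keeps every record (p-values
    # never reach 1 exactly in continuous tests)
    if not 0.0 < alpha <= 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1], got {alpha}")
    kept = meta.loc[meta["p_int"] < alpha]
    cols = [c for c in SELECTED_COLUMNS if c in kept.columns]
    out = kept[cols].copy()
    return out.sort_values(
        ["ancestry_group", "trait", "exposure", "p_int", "variant_id"]
    ).reset_index(drop=True)


@dataclass
class SelectionTally:
    """Unique-variant counts by class and per analysis-set cell.

    ``by_*`` counts deduplicate variant ids within each class;
    ``total_unique`` deduplicates across everything;
    ``total_per_model`` counts (variant, context) rows without dedup, the
    alternative convention for share-of-total statements.
    """

    total_unique: int = 0
    total_per_model: int = 0
    by_exposure_class: dict[str, int] = field(default_factory=dict)
    by_trait_class: dict[str, int] = field(default_factory=dict)
    by_ancestry_group: dict[str, int] = field(default_factory=dict)
    per_cell: dict[tuple[str, str, str], int] = field(default_factory=dict)


def tally_selection(selected: pd.DataFrame) -> SelectionTally:
    """Tally a selected-variants frame into class-level unique counts."""
    tally = SelectionTally()
    if selected.empty:
        return tally
    df = selected.copy()
    df["exposure_class"] = df["exposure"].map(vocab.exposure_class)
    df["trait_class"] = df["trait"].map(vocab.trait_class)
    tally.total_unique = df["variant_id"].nunique()
    tally.total_per_model = len(df)
    tally.by_exposure_class = (
        df.groupby("exposure_class")["variant_id"].nunique().to_dict()
    )
    tally.by_trait_class = df.groupby("trait_class")["variant_id"].nunique().to_dict()
    tally.by_ancestry_group = (
        df.groupby("ancestry_group")["variant_id"].nunique().to_dict()
    )
    tally.per_cell = {
        key: int(v)
        for key, v in df.groupby(["trait", "exposure", "ancestry_group"])["variant_id"]
        .nunique()
        .items()
    }
    return tally
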