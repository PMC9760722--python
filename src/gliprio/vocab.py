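"""Closed vocabularies for traits, exposures and ancestry groups.

The analysis operates over seven quantitative cardiometabolic traits (three
serum lipids, four blood-pressure measures), five binary lifestyle exposures
(two smoking, three alcohol), and four self-identified ancestry groups plus
the trans-ancestry meta-analysis. All labels outside these vocabularies are
rejected with :class:`~gliprio.errors.VocabularyError`.
"""

from __future__ import annotations

from gliprio.errors import VocabularyError

ANCESTRIES: tuple[str, ...] = ("EA", "AA", "HA", "ASA")
#: Display / sort order used in reports (African, Asian, European, Hispanic, Trans).
ANCESTRY_GROUPS: tuple[str, ...] = ("AA", "ASA", "EA", "HA", "TRANS")

LIPID_TRAITS: tuple[str, ...] = ("HDL", "LDL", "TG")
BP_TRAITS: tuple[str, ...] = ("SBP", "DBP", "MAP", "PP")
TRAITS: tuple[str, ...] = LIPID_TRAITS + BP_TRAITS

SMOKING_EXPOSURES: tuple[str, ...] = ("current smoking", "ever smoking")
ALCOHOL_EXPOSURES: tuple[str, ...] = (
    "current drinking",
    "regular drinking",
    "drinking habits",
)
EXPOSURES: tuple[str, ...] = SMOKING_EXPOSURES + ALCOHOL_EXPOSURES

EXPOSURE_CLASSES: tuple[str, ...] = ("smoking", "alcohol")
TRAIT_CLASSES: tuple[str, ...] = ("lipids", "blood pressure")

EXPOSURE_ABBREV: dict[str, str] = {
    "current smoking": "Curr Smk",
    "ever smoking": "Ev Smk",
    "current drinking": "Curr Drnk",
    "regular drinking": "Reg Drnk",
    "drinking habits": "Drnk habits",
}

ANCESTRY_LABELS: dict[str, str] = {
    "AA": "African Ancestry",
    "ASA": "Asian Ancestry",
    "EA": "European Ancestry",
    "HA": "Hispanic Ancestry",
    "TRANS": "Trans Ancestry",
}


def trait_class(trait: str) -> str:
    """Map a trait label to its class ('lipids' or 'blood pressure')."""
    if trait in LIPID_TRAITS:
        return "lipids"
    if trait in BP_TRAITS:
        return "blood pressure"
    raise VocabularyError(f"unknown trait label: {trait!r}")


def exposure_class(exposure: str) -> str:
    """Map an exposure label to its class ('smoking' or 'alcohol')."""
    if exposure in SMOKING_EXPOSURES:
        return "smoking"
    if exposure in ALCOHOL_EXPOSURES:
        return "alcohol"
    raise VocabularyError(f"unknown exposure label: {exposure!r}")


def check_trait(trait: str) -> str:
    if trait not in TRAITS:
        raise VocabularyError(f"unknown trait label: {trait!r}")
    return trait


def check_exposure(exposure: str) -> str:
    if exposure not in EXPOSURES:
        raise VocabularyError(f"unknown exposure label: {exposure!r}")
    return exposure


def check_ancestry(ancestry: str, *, allow_trans: bool = False) -> str:
    allowed = ANCESTRY_GROUPS if allow_trans else ANCESTRIES
    if ancestry not in allowed:
        raise VocabularyError(f"unknown ancestry label: {ancestry!r}")
    return ancestry
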