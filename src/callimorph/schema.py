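"""Canonical trait keys, units, and taxon codes shared across the package."""

from __future__ import annotations

#: Traits measured once per animal (key -> unit).
UNILATERAL_TRAITS: dict[str, str] = {
    "WEIGHT": "g",
    "BODY": "cm",
    "TAIL": "cm",
    "IC": "mm",
    "FO": "mm",
    "ZYG": "mm",
    "JAW": "mm",
}

#: Traits measured on left and right sides and averaged per animal.
BILATERAL_TRAITS: dict[str, str] = {
    "HUMERUS": "cm",
    "FOREARM": "cm",
    "FEMUR": "cm",
    "TIBIA": "cm",
    "HAND": "mm",
    "FOOT": "mm",
}

#: The 13 canonical trait keys, in rendering order.
TRAIT_NAMES: tuple[str, ...] = (
    "WEIGHT",
    "BODY",
    "TAIL",
    "HUMERUS",
    "FOREARM",
    "FEMUR",
    "TIBIA",
    "IC",
    "FO",
    "ZYG",
    "JAW",
    "HAND",
    "FOOT",
)

TRAIT_UNITS: dict[str, str] = {**UNILATERAL_TRAITS, **BILATERAL_TRAITS}

#: Declared taxon codes: four species and four hybrid classes.
TAXON_CODES: tuple[str, ...] = ("A", "G", "J", "P", "AH", "PJ", "PG", "CC")

SPECIES_CODES: tuple[str, ...] = ("A", "G", "J", "P")

SEX_CODES: tuple[str, ...] = ("M", "F", "unknown")

AGE_CLASSES: tuple[str, ...] = ("adult", "juvenile", "unknown")

#: Metadata columns of the normalized flat trait matrix.
META_COLUMNS: tuple[str, ...] = ("individual_id", "taxon", "sex", "age_class", "site")


def significance_code(p: float) -> str:
    """Star code used in rendered tables: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
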