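"""Published per-taxon summary statistics for the four Callithrix species
and their hybrid groups.

These printed (n, mean, SD) values are the inputs for summary-mode
classification when the individual-level data is not at hand, and seed the
default synthetic scenario. Units: WEIGHT g; BODY/TAIL/HUMERUS/FOREARM/
FEMUR/TIBIA cm; IC/FO/ZYG/JAW/HAND/FOOT mm.
"""

from __future__ import annotations

from .stats_core import GroupSummary

# taxon -> trait -> (n, mean, sd)
PARENT_SUMMARIES: dict[str, dict[str, tuple[int, float, float]]] = {
    "A": {
        "BODY": (27, 21.9, 1.4),
        "FEMUR": (27, 6.5, 0.6),
        "FO": (27, 42.6, 2.9),
        "FOOT": (24, 61.1, 5.6),
        "FOREARM": (27, 5.2, 0.4),
        "HAND": (21, 30.5, 15.1),
        "HUMERUS": (26, 5.4, 0.8),
        "IC": (27, 33.1, 1.3),
        "JAW": (23, 23.7, 3.9),
        "TAIL": (26, 32.3, 1.7),
        "TIBIA": (27, 7.2, 0.5),
        "WEIGHT": (25, 440.6, 66.8),
        "ZYG": (23, 31.4, 2.6),
    },
    "G": {
        "BODY": (14, 22.2, 1.9),
        "FEMUR": (14, 6.3, 0.5),
        "FO": (14, 40.2, 2.6),
        "FOOT": (14, 55.4, 3.2),
        "FOREARM": (14, 4.8, 0.3),
        "HAND": (13, 36.3, 2.7),
        "HUMERUS": (14, 5.3, 0.3),
        "IC": (14, 30.2, 1.9),
        "JAW": (14, 25.7, 3.1),
        "TAIL": (13, 30.7, 3.2),
        "TIBIA": (14, 7.1, 0.3),
        "WEIGHT": (14, 386.2, 63.0),
        "ZYG": (14, 30.1, 3.3),
    },
    "J": {
        "BODY": (29, 19.9, 1.6),
        "FEMUR": (29, 5.5, 0.7),
        "FO": (24, 39.7, 2.2),
        "FOOT": (27, 54.7, 4.6),
        "FOREARM": (29, 4.5, 0.4),
        "HAND": (28, 35.4, 3.3),
        "HUMERUS": (29, 4.7, 0.5),
        "IC": (29, 27.4, 2.2),
        "JAW": (29, 22.2, 2.9),
        "TAIL": (24, 27.4, 2.9),
        "TIBIA": (29, 6.6, 0.6),
        "WEIGHT": (30, 322.6, 65.2),
        "ZYG": (29, 28.7, 1.5),
    },
    "P": {
        "BODY": (52, 20.9, 2.7),
        "FEMUR": (54, 5.8, 0.6),
        "FO": (50, 39.8, 2.1),
        "FOOT": (54, 54.2, 3.7),
        "FOREARM": (54, 4.6, 0.5),
        "HAND": (48, 35.2, 4.0),
        "HUMERUS": (54, 4.6, 0.7),
        "IC": (54, 28.4, 1.6),
        "JAW": (52, 22.9, 2.3),
        "TAIL": (51, 27.7, 3.2),
        "TIBIA": (54, 6.5, 0.6),
        "WEIGHT": (54, 308.4, 68.1),
        "ZYG": (51, 28.6, 2.1),
    },
}

# hybrid taxon -> trait -> (n, mean, sd)
HYBRID_SUMMARIES: dict[str, dict[str, tuple[int, float, float]]] = {
    "AH": {
        "BODY": (9, 21.4, 1.9),
        "FEMUR": (9, 6.4, 0.6),
        "FO": (9, 38.8, 3.6),
        "FOOT": (9, 57.9, 4.5),
        "FOREARM": (9, 5.2, 0.5),
        "HAND": (9, 39.0, 3.7),
        "HUMERUS": (9, 5.2, 0.8),
        "IC": (9, 32.6, 4.8),
        "JAW": (9, 26.3, 12.4),
        "TAIL": (9, 29.7, 3.6),
        "TIBIA": (9, 7.2, 0.7),
        "WEIGHT": (9, 408.1, 39.6),
        "ZYG": (9, 30.3, 3.0),
    },
    "PJ": {
        "BODY": (54, 21.3, 2.7),
        "FEMUR": (54, 5.8, 0.6),
        "FO": (49, 39.2, 3.1),
        "FOOT": (54, 54.4, 5.1),
        "FOREARM": (54, 4.6, 0.5),
        "HAND": (50, 34.4, 3.6),
        "HUMERUS": (54, 4.7, 0.7),
        "IC": (54, 28.9, 2.2),
        "JAW": (53, 23.7, 4.2),
        "TAIL": (52, 28.7, 2.4),
        "TIBIA": (54, 6.7, 0.6),
        "WEIGHT": (53, 317.9, 73.2),
        "ZYG": (53, 29.1, 2.4),
    },
    "PG": {
        "BODY": (18, 21.4, 0.9),
        "FEMUR": (18, 6.6, 0.6),
        "FO": (18, 37.7, 3.7),
        "FOOT": (16, 53.3, 3.2),
        "FOREARM": (18, 4.8, 0.4),
        "HAND": (9, 36.8, 3.2),
        "HUMERUS": (18, 5.1, 0.4),
        "IC": (18, 29.8, 2.2),
        "JAW": (18, 22.7, 2.9),
        "TAIL": (18, 30.7, 1.6),
        "TIBIA": (18, 7.1, 0.4),
        "WEIGHT": (18, 355.8, 27.8),
        "ZYG": (18, 30.3, 1.2),
    },
}

#: Study-scale sample sizes by taxon (total 209 adults across 8 taxa).
GROUP_SIZES: dict[str, int] = {
    "A": 27,
    "AH": 9,
    "CC": 2,
    "G": 14,
    "J": 30,
    "P": 55,
    "PG": 18,
    "PJ": 54,
}

#: Hybrid group -> putative parental pairs evaluated for it.
DEFAULT_PLAN: dict[str, list[tuple[str, str]]] = {
    "PJ": [("J", "P")],
    "PG": [("G", "P")],
    "AH": [("A", "J"), ("A", "P"), ("A", "G")],
}

#: Published between-species mean mitogenomic distances (substitutions/site).
REFERENCE_DISTANCES: dict[tuple[str, str], float] = {
    ("A", "G"): 0.059,
    ("A", "J"): 0.060,
    ("A", "P"): 0.059,
    ("G", "J"): 0.018,
    ("G", "P"): 0.018,
    ("J", "P"): 0.014,
}


def reference_group_summaries(include_hybrids: bool = True) -> list[GroupSummary]:
    """The printed summaries as :class:`GroupSummary` objects."""
    tables = dict(PARENT_SUMMARIES)
    if include_hybrids:
        tables.update(HYBRID_SUMMARIES)
    out = []
    for taxon, traits in tables.items():
        for trait, (n, mean, sd) in traits.items():
            out.append(GroupSummary(group=taxon, trait=trait, n=n, mean=mean, sd=sd))
    return out
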