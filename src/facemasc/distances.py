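"""Registry of the 26 Farkas inter-landmark facial distances.

Each distance is measured in two forms — Euclidean (straight line through
space) and geodesic (shortest path over the face surface) — giving the 52
candidate features of the gender model.  Feature-table columns are named
``e_<name>`` / ``g_<name>`` with spaces replaced by underscores.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DistanceDefinition:
    index: int              # 1-26
    name: str               # standard anthropometric label
    endpoints: tuple[str, str]
    side: str               # left | right | midline | bilateral-span


DISTANCE_DEFINITIONS: tuple[DistanceDefinition, ...] = (
    DistanceDefinition(1, "forehead width", ("Ft_l", "Ft_r"), "bilateral-span"),
    DistanceDefinition(2, "outer canthal width", ("Ex_l", "Ex_r"), "bilateral-span"),
    DistanceDefinition(3, "eye fissure length (left)", ("Ex_l", "En_l"), "left"),
    DistanceDefinition(4, "eye fissure length (right)", ("Ex_r", "En_r"), "right"),
    DistanceDefinition(5, "inter canthal width", ("En_l", "En_r"), "bilateral-span"),
    DistanceDefinition(6, "mid face width (left)", ("Ex_l", "N"), "left"),
    DistanceDefinition(7, "mid face width (right)", ("Ex_r", "N"), "right"),
    DistanceDefinition(8, "nasal root height (left)", ("En_l", "N"), "left"),
    DistanceDefinition(9, "nasal root height (right)", ("En_r", "N"), "right"),
    DistanceDefinition(10, "nose width", ("Al_l", "Al_r"), "bilateral-span"),
    DistanceDefinition(11, "alar-base width", ("Sbal_l", "Sbal_r"), "bilateral-span"),
    DistanceDefinition(12, "mouth width", ("Ch_l", "Ch_r"), "bilateral-span"),
    DistanceDefinition(13, "mandible height (left)", ("Ch_l", "Pg"), "left"),
    DistanceDefinition(14, "mandible height (right)", ("Ch_r", "Pg"), "right"),
    DistanceDefinition(15, "upper cheek height (left)", ("Ex_l", "Ch_l"), "left"),
    DistanceDefinition(16, "upper cheek height (right)", ("Ex_r", "Ch_r"), "right"),
    DistanceDefinition(17, "forehead height", ("Tr", "G"), "midline"),
    DistanceDefinition(18, "nasal bridge length", ("N", "Prn"), "midline"),
    DistanceDefinition(19, "nose height", ("N", "Sn"), "midline"),
    DistanceDefinition(20, "upper facial height", ("N", "Sto"), "midline"),
    DistanceDefinition(21, "nasal tip protrusion", ("Sn", "Prn"), "midline"),
    DistanceDefinition(22, "upper lip height", ("Sn", "Sto"), "midline"),
    DistanceDefinition(23, "philtrum length", ("Sn", "Ls"), "midline"),
    DistanceDefinition(24, "upper vermillion height", ("Ls", "Sto"), "midline"),
    DistanceDefinition(25, "lower vermillion height", ("Sto", "Li"), "midline"),
    DistanceDefinition(26, "mandible height", ("Sto", "Pg"), "midline"),
)


def _slug(name: str) -> str:
    return (
        name.replace(" (", "_").replace(")", "").replace("-", "_")
        .replace(" ", "_")
    )


def feature_name(defn: DistanceDefinition, form: str) -> str:
    """Column name for one distance in one form ('euclidean'/'geodesic')."""
    prefix = {"euclidean": "e", "geodesic": "g"}[form]
    return f"{prefix}_{_slug(defn.name)}"


#: All 52 distance feature column names (26 Euclidean then 26 geodesic).
EUCLIDEAN_FEATURES: tuple[str, ...] = tuple(
    feature_name(d, "euclidean") for d in DISTANCE_DEFINITIONS
)
GEODESIC_FEATURES: tuple[str, ...] = tuple(
    feature_name(d, "geodesic") for d in DISTANCE_DEFINITIONS
)
ALL_FEATURES: tuple[str, ...] = EUCLIDEAN_FEATURES + GEODESIC_FEATURES

#: Geodesic variables that are positively skewed in this kind of cohort and
#: are natural-log transformed before group statistics.
LOG_TRANSFORM_FEATURES: tuple[str, ...] = (
    "g_forehead_width",      # geodesic forehead width
    "g_mandible_height",     # geodesic mandible height (Sto-Pg)
)

#: The 10 features the gender-selection stage settles on for adult cohorts:
#: 4 Euclidean and 6 geodesic distances.
REPORTED_SELECTED_FEATURES: tuple[str, ...] = (
    "e_nose_width",
    "e_nasal_tip_protrusion",
    "e_nasal_bridge_length",
    "e_upper_lip_height",
    "g_upper_facial_height",
    "g_outer_canthal_width",
    "g_forehead_width",
    "g_mandible_height",
    "g_upper_cheek_height_left",
    "g_upper_cheek_height_right",
)


def definitions_table() -> str:
    """Render the distance registry as a plain-text table (one row per
    definition: index, landmark pair, distance name)."""
    lines = []
    for d in DISTANCE_DEFINITIONS:
        a, b = d.endpoints
        pair = f"{a.split('_')[0]}-{b.split('_')[0]}"
        side = ""
        if d.side in ("left", "right"):
            side = f" ({d.side})"
        lines.append(f"{d.index}\t{pair}{side}\t{d.name}")
    return "\n".join(lines)


BY_NAME: dict[str, DistanceDefinition] = {d.name: d for d in DISTANCE_DEFINITIONS}
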