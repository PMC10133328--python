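"""Study fixture: the 31 valli da pesca of the Venice lagoon and their
management groups, plus the registries of ecosystem services and landscape
indicators used throughout the assessment.

The valli da pesca are diked, privately managed sub-basins at the edge of
the Venice lagoon, historically devoted to extensive capture-based
aquaculture and waterfowl hunting.  Each unit is run under one of five
management strategies, defined by the ecosystem services (ESs) its manager
maximizes:

* ``F`` — fish production (extensive aquaculture prioritized)
* ``M`` — multiple ESs (aquaculture and hunting, sometimes tourism)
* ``H`` — hunting activity
* ``R`` — recreational / cultural activities
* ``N`` — not managed (abandoned)

Real per-unit surface areas are not part of the public record for these
private estates; the fixture ships configurable placeholder areas with a
plausible group-conditioned magnitude (hundreds to ~1700 ha).
"""

from __future__ import annotations

from dataclasses import dataclass

GROUPS = ("F", "M", "H", "R", "N")

GROUP_LABELS = {
    "F": "fish production",
    "M": "multiple ecosystem services",
    "H": "hunting activity",
    "R": "recreational activities",
    "N": "not managed",
}


@dataclass(frozen=True)
class ValleUnit:
    """One management unit (valle da pesca)."""

    legend_id: int
    name: str
    group: str
    total_area: float  # m^2

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; must be one of {GROUPS}")
        if not 1 <= self.legend_id <= 31:
            raise ValueError(f"legend_id must be in 1..31, got {self.legend_id}")
        if self.total_area <= 0:
            raise ValueError("total_area must be > 0")

    @property
    def hectares(self) -> float:
        return self.total_area / 10_000.0


# legend id -> (name, group, placeholder area in ha)
_FIXTURE: dict[int, tuple[str, str, float]] = {
    1: ("Valle Dogà", "F", 1700),
    2: ("Valle Grassabò", "F", 1100),
    3: ("Lago Vallesina di Grassabò", "H", 220),
    4: ("Valle Fosse", "H", 260),
    5: ("Valle Lio Maggiore", "M", 420),
    6: ("Valle Bianca", "H", 180),
    7: ("Valle Dragojesolo", "M", 480),
    8: ("Valle Cavallino", "M", 540),
    9: ("Valle Falconera", "R", 160),
    10: ("Valle Liona", "H", 340),
    11: ("Valle Olivara", "H", 300),
    12: ("Valli Saline-Manciane-Sparasera", "R", 380),
    13: ("Valle Paleazza", "F", 650),
    14: ("Valle Sacchettina", "R", 120),
    15: ("Valle Sacchetta", "R", 170),
    16: ("Valle Ca' Zane", "H", 240),
    17: ("Santa Cristina", "R", 140),
    18: ("Valle Perini", "M", 360),
    19: ("Valle Miana-Serraglia", "H", 520),
    20: ("Valle Averto", "R", 200),
    21: ("Valle A.M.A.", "F", 780),
    22: ("Valle Contarina-Tezze", "M", 390),
    23: ("Valle Cornio", "M", 310),
    24: ("Valle Zappa", "H", 430),
    25: ("Valle Figheri", "M", 560),
    26: ("Valle Pierimpiè", "M", 620),
    27: ("Valle Morosina", "H", 580),
    28: ("Valle Baseggia", "N", 280),
    29: ("Mesole", "N", 210),
    30: ("La Cura", "N", 190),
    31: ("Valle Millecampi", "N", 480),
}


def build_study_fixture(areas_ha: dict[int, float] | None = None) -> list[ValleUnit]:
    """Build the fixed 31-unit study fixture.

    Parameters
    ----------
    areas_ha
        Optional per-unit total areas in hectares overriding the
        placeholder values (real areas are not public).

    Returns
    -------
    list of :class:`ValleUnit`, sorted by legend id, covering all five
    management groups with cardinalities |F|=4, |M|=8, |H|=9, |R|=6, |N|=4.
    """
    areas_ha = areas_ha or {}
    units = []
    for legend_id in sorted(_FIXTURE):
        name, group, default_ha = _FIXTURE[legend_id]
        ha = areas_ha.get(legend_id, default_ha)
        units.append(ValleUnit(legend_id, name, group, total_area=ha * 10_000.0))
    return units


# --- ecosystem service registry -------------------------------------------

#: name -> (CICES category, capacity unit, flow unit)
ES_REGISTRY: dict[str, tuple[str, str, str]] = {
    "climate_regulation": ("regulating", "gC m-2 y-1", "gC m-2 y-1"),
    "water_purification": ("regulating", "% N load removed", "% N load removed"),
    "lifecycle_support": ("regulating", "attractiveness [0-1]", "normalized sum [0-2]"),
    "aquaculture": ("provisioning", "kg ha-1 y-1", "kg ha-1 y-1"),
    "hunting": ("provisioning", "n ha-1 y-1", "n ha-1 y-1"),
    "wild_food": ("provisioning", "kg ha-1 y-1", "kg ha-1 y-1"),
    "tourism": ("cultural", "attractiveness [0-1]", "n y-1"),
    "cognitive_development": ("cultural", "attractiveness [0-1]", "n y-1"),
    "birdwatching": ("cultural", "attractiveness [0-1]", "n y-1"),
}

ES_CATEGORIES = ("regulating", "provisioning", "cultural")

PROVISIONING_ES = ("aquaculture", "hunting", "wild_food")
CULTURAL_ES = ("tourism", "cognitive_development", "birdwatching")
REGULATING_ES = ("climate_regulation", "water_purification", "lifecycle_support")

#: the eight landscape indicators, in canonical column order
LANDSCAPE_INDICATORS = (
    "water_total",
    "land_total",
    "saltmarsh_total",
    "freshwater_brackish",
    "land_saltmarsh",
    "saltmarsh_perimeter_area",
    "shannon_diversity",
    "shannon_evenness",
)


def classify_management_group(maximized_es_set: set[str]) -> str:
    """Classify a unit's management group from the set of ESs it maximizes.

    The rule mirrors how managers' declared priorities map onto strategies:
    aquaculture only -> F; hunting only -> H; cultural services only -> R;
    nothing maximized -> N; any mix of two or more services that includes a
    provisioning activity (aquaculture or hunting) -> M.
    """
    unknown = set(maximized_es_set) - set(ES_REGISTRY)
    if unknown:
        raise ValueError(f"unknown ES name(s): {sorted(unknown)}")
    s = set(maximized_es_set)
    if not s:
        return "N"
    if s == {"aquaculture"}:
        return "F"
    if s == {"hunting"}:
        return "H"
    if s <= set(CULTURAL_ES):
        return "R"
    if len(s) >= 2 and (s & {"aquaculture", "hunting"}):
        return "M"
    # remaining single-service or non-extractive sets: closest strategy is
    # recreational when only cultural/regulating aims remain, else multiple
    return "M" if s & {"aquaculture", "hunting"} else "R"
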