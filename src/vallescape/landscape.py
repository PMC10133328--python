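"""Landscape-pattern indicators computed per management unit.

Eight indicators describe each unit's land-cover arrangement: five area
ratios, the saltmarsh perimeter-to-area ratio (km km^-2), and Shannon's
landscape diversity and evenness.  Water area is brackish + freshwater.

Zero-denominator ratios (e.g. freshwater/brackish in a unit with no
brackish water) are returned as NaN — an explicitly flagged undefined
value, excluded pairwise by the downstream statistics — never as 0.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .fixture import LANDSCAPE_INDICATORS
from .raster import (
    BRACKISH,
    FRESHWATER,
    LAND,
    SALTMARSH,
    LandCoverRaster,
    class_area,
    class_perimeter,
    label_patches,
)


def shannon_diversity(class_proportions, base: str = "e") -> float:
    """Shannon landscape diversity H = -sum p_i log p_i over classes present.

    Proportions must be non-negative and sum to 1 (within 1e-8); zero
    proportions are ignored.  ``base`` is ``"e"`` (nats, default) or ``"2"``.
    """
    p = np.asarray(class_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be >= 0")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= math.log(2)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return h


def shannon_evenness(class_proportions, base: str = "e") -> float:
    """Shannon evenness E = H / log S, S = number of classes present.

    A one-class landscape has no between-class contrast; its evenness is
    defined as 0 here (convention: richness S counts classes actually
    present, not the legend size).
    """
    p = np.asarray(class_proportions, dtype=float)
    s = int(np.count_nonzero(p > 0))
    if s <= 1:
        # validate even in the degenerate branch
        shannon_diversity(class_proportions, base=base)
        return 0.0
    hmax = math.log(s) if base == "e" else math.log2(s)
    return shannon_diversity(class_proportions, base=base) / hmax


def compute_landscape_indicators(raster: LandCoverRaster, base: str = "e") -> dict[str, float]:
    """Compute the eight landscape indicators for one unit's raster.

    Returns a dict keyed by :data:`~vallescape.fixture.LANDSCAPE_INDICATORS`.
    Ratios are unitless except ``saltmarsh_perimeter_area`` (km km^-2).
    """
    areas = {c: class_area(raster, c) for c in (LAND, SALTMARSH, BRACKISH, FRESHWATER)}
    total = sum(areas.values())
    if total == 0:
        raise ValueError("all-nodata raster: no landscape to describe")
    water = areas[BRACKISH] + areas[FRESHWATER]

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    sm_patches = label_patches(raster, SALTMARSH)
    sm_perim_m = class_perimeter(sm_patches)
    # km / km^2 == (m/1e3) / (m^2/1e6) == 1e3 * m / m^2
    pa = 1e3 * sm_perim_m / areas[SALTMARSH] if areas[SALTMARSH] > 0 else float("nan")

    props = np.array([areas[c] / total for c in (LAND, SALTMARSH, BRACKISH, FRESHWATER)])
    props = props[props > 0]
    return {
        "water_total": water / total,
        "land_total": areas[LAND] / total,
        "saltmarsh_total": areas[SALTMARSH] / total,
        "freshwater_brackish": ratio(areas[FRESHWATER], areas[BRACKISH]),
        "land_saltmarsh": ratio(areas[LAND], areas[SALTMARSH]),
        "saltmarsh_perimeter_area": pa,
        "shannon_diversity": shannon_diversity(props, base=base),
        "shannon_evenness": shannon_evenness(props, base=base),
    }


def landscape_table(rasters: dict[int, LandCoverRaster], base: str = "e") -> pd.DataFrame:
    """Landscape indicator table: one row per unit, Table-ordered columns."""
    rows = {uid: compute_landscape_indicators(r, base=base) for uid, r in rasters.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(LANDSCAPE_INDICATORS))
    df.index.name = "legend_id"
    return df.sort_index()
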