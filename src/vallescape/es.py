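"""Capacity and flow indicators for the nine ecosystem services.

Three CICES categories, three services each:

* regulating & maintenance — climate regulation (carbon sequestration by
  reed stands, vegetated saltmarshes and seagrass meadows), water
  purification (% of nitrogen load removed by denitrification in brackish
  basins), lifecycle support for fish and migratory waterbirds;
* provisioning — aquaculture production, waterfowl hunting, wild food
  (Salicornia + sea-lavender honey);
* cultural — tourism, information for cognitive development, birdwatching.

Capacity is the ecosystem's potential to deliver the service; flow is the
amount actually reaching society.  For climate regulation and water
purification, capacity and flow are equivalent (they occur at the same
place and time); attractiveness-based capacities live on a 0-1 scale;
record-based flows are yearly means over the study window.  Missing values
are NaN throughout and are excluded pairwise downstream, never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixture import ES_REGISTRY
from .rates import RateTable

#: habitat layers that carry a carbon sequestration rate
CARBON_HABITATS = ("reed_stand", "vegetated_saltmarsh", "seagrass_meadow")


@dataclass
class HabitatLayerSet:
    """Binary habitat masks congruent with one unit's land-cover raster."""

    masks: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"habitat masks not congruent: shapes {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def area(self, habitat: str) -> float:
        """Habitat area in m^2 (0 for an absent layer)."""
        mask = self.masks.get(habitat)
        if mask is None:
            return 0.0
        return float(np.count_nonzero(mask)) * self.pixel_size**2


def climate_regulation(
    habitats: HabitatLayerSet, rates: RateTable, unit_area_m2: float
) -> tuple[float, float]:
    """Mean annual carbon sequestration over the unit, gC m^-2 y^-1.

    Total carbon is the sum over vegetated habitats of area x rate, with
    the seagrass rate incremented by the deposition from micro-calcareous
    epiphytic seaweeds.  Capacity and flow are equivalent for this service;
    both are returned (identical).
    """
    total_gC = 0.0
    for habitat in habitats.masks:
        if habitat not in CARBON_HABITATS:
            continue
        area = habitats.area(habitat)
        if area == 0:
            continue
        if habitat not in rates.carbon_rates_gC_m2_y:
            raise KeyError(f"no carbon rate configured for present habitat {habitat!r}")
        rate = rates.carbon_rates_gC_m2_y[habitat]
        if habitat == "seagrass_meadow":
            rate += rates.seagrass_epiphyte_increment_gC_m2_y
        total_gC += area * rate
    mean = total_gC / unit_area_m2
    return mean, mean


@dataclass(frozen=True)
class PurificationResult:
    capacity_pct: float
    flow_pct: float
    removed_gN_y: float


def water_purification(
    brackish_area_m2: float, n_load_gN_m2_y: float, removal_fraction: float
) -> PurificationResult:
    """Percent of the nitrogen load removed by denitrification.

    Capacity and flow are equivalent.  The removed mass (fraction x areal
    load x brackish area) is reported alongside the percentage.
    """
    if not 0.0 <= removal_fraction <= 1.0:
        raise ValueError(f"removal_fraction must be in [0, 1], got {removal_fraction}")
    if n_load_gN_m2_y < 0:
        raise ValueError("nitrogen load must be >= 0")
    pct = removal_fraction * 100.0
    removed = removal_fraction * n_load_gN_m2_y * brackish_area_m2
    return PurificationResult(pct, pct, removed)


def attractiveness_index(
    factor_layers, weights, *, rescale_bounds: tuple[float, float] | None = None
) -> tuple[np.ndarray, float]:
    """Weighted map-algebra attractiveness index on a 0-1 scale.

    The per-pixel weighted sum of the factor layers is min-max rescaled so
    the maximum maps to 1 and the minimum to 0.  When an index is computed
    for several units jointly, pass the (min, max) of the weighted sum over
    the whole unit set as ``rescale_bounds`` so the scale is shared.

    Returns the index raster and its mean over the unit.
    """
    layers = [np.asarray(l, dtype=float) for l in factor_layers]
    if not layers:
        raise ValueError("need at least one factor layer")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(layers),):
        raise ValueError(f"{len(layers)} layers but {w.size} weights")
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    shapes = {l.shape for l in layers}
    if len(shapes) > 1:
        raise ValueError(f"factor layers not congruent: shapes {shapes}")
    raw = sum(wi * li for wi, li in zip(w, layers))
    lo, hi = rescale_bounds if rescale_bounds is not None else (raw.min(), raw.max())
    if hi > lo:
        index = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    else:
        index = np.zeros_like(raw)
    return index, float(index.mean())


def weighted_sum_bounds(layers_by_unit: dict, weights) -> tuple[float, float]:
    """(min, max) of the weighted factor sum across a whole unit set."""
    w = np.asarray(weights, dtype=float)
    lo, hi = np.inf, -np.inf
    for layers in layers_by_unit.values():
        raw = sum(wi * np.asarray(li, dtype=float) for wi, li in zip(w, layers))
        lo = min(lo, float(raw.min()))
        hi = max(hi, float(raw.max()))
    return lo, hi


def minmax_series(values: pd.Series) -> pd.Series:
    """Min-max normalize a cross-unit series to [0, 1]; NaN stays NaN.

    A constant vector maps to all zeros (no between-unit contrast carries
    no signal) with a warning.
    """
    v = values.astype(float)
    lo, hi = v.min(), v.max()
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("need at least one finite value to normalize")
    if hi == lo:
        warnings.warn("constant vector normalized to all zeros", stacklevel=2)
        return v * 0.0
    return (v - lo) / (hi - lo)


def lifecycle_flow(records: pd.DataFrame) -> pd.Series:
    """Combined lifecycle-support flow per unit on a 0-2 scale.

    The mean sown-fry biomass and the mean censused-waterbird density are
    each min-max normalized across units, then summed: a unit maximal in
    both components scores 2, one minimal in both scores 0.
    """
    fry = record_mean_flow(records, "fry_sown")
    birds = record_mean_flow(records, "waterbirds_censused")
    if len(fry) < 2:
        raise ValueError("lifecycle flow normalization needs >= 2 units")
    return minmax_series(fry) + minmax_series(birds)


def record_mean_flow(
    records: pd.DataFrame, field_name: str, years_window: tuple[int, int] | None = None
) -> pd.Series:
    """Per-unit mean yearly value of one management-record field.

    Years with missing values are excluded from the mean (never treated as
    zero); a unit with no usable records in the window gets NaN.
    """
    if field_name not in records.columns:
        raise KeyError(f"unknown record field {field_name!r}")
    df = records
    if years_window is not None:
        lo, hi = years_window
        if lo > hi:
            raise ValueError(f"empty years window ({lo}, {hi})")
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if df.empty:
        raise ValueError("no records in the requested years window")
    return df.groupby("legend_id")[field_name].mean()


def huntable_density_surface(
    census_points, template_shape: tuple[int, int], pixel_size: float, power: float = 2.0
) -> np.ndarray:
    """Inverse-distance-weighted density surface from waterbird census points.

    ``census_points`` is a sequence of ``(x, y, value)`` with x, y in metres
    from the grid's upper-left corner (x along columns, y along rows).  The
    surface reproduces point values exactly at point pixels; coincident
    points with conflicting values are averaged with a warning.  Unit
    capacity is the surface mean over the unit.
    """
    pts = list(census_points)
    if not pts:
        raise ValueError("need at least one census point")
    by_pixel: dict[tuple[int, int], list[float]] = {}
    for x, y, v in pts:
        key = (int(round(y / pixel_size)), int(round(x / pixel_size)))
        by_pixel.setdefault(key, []).append(float(v))
    for key, vals in by_pixel.items():
        if len(vals) > 1 and len(set(vals)) > 1:
            warnings.warn(f"coincident census points at pixel {key}; values averaged", stacklevel=2)
    rows = np.array([k[0] for k in by_pixel])
    cols = np.array([k[1] for k in by_pixel])
    vals = np.array([float(np.mean(v)) for v in by_pixel.values()])
    nr, nc = template_shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    # distances from every pixel centre to every census pixel, in metres
    d = np.hypot(rr[..., None] - rows, cc[..., None] - cols) * pixel_size
    at_point = d == 0
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[at_point] = 0.0
    surface = (w * vals).sum(axis=-1) / np.where(w.sum(axis=-1) == 0, 1.0, w.sum(axis=-1))
    exact = at_point.any(axis=-1)
    surface[exact] = vals[at_point.argmax(axis=-1)[exact]]
    if len(vals) == 1:
        surface[:] = vals[0]
    return surface


@dataclass(frozen=True)
class WildFoodCapacity:
    total_kg_ha_y: float
    salicornia_kg_ha_y: float
    honey_kg_ha_y: float


def wildfood_capacity(
    salicornia_mask: np.ndarray,
    limonium_area_m2: float,
    rates: RateTable,
    unit_area_m2: float,
    pixel_size: float,
) -> WildFoodCapacity:
    """Harvestable Salicornia biomass plus sea-lavender honey, kg ha^-1 y^-1.

    Honey yield is configured in g m^-2 y^-1 and converted to kg; the two
    components are combined by mass and also reported separately.
    """
    sal_area = float(np.count_nonzero(salicornia_mask)) * pixel_size**2
    hectares = unit_area_m2 / 10_000.0
    sal = sal_area * rates.salicornia_biomass_kg_m2_y / hectares
    honey = limonium_area_m2 * rates.honey_yield_g_m2_y / 1000.0 / hectares
    return WildFoodCapacity(sal + honey, sal, honey)


def aquaculture_capacity(potential_density_surface: np.ndarray, brackish_mask: np.ndarray) -> float:
    """Mean potential fish biomass density (kg ha^-1 y^-1) over brackish water.

    The potential-density surface is an input (produced by a spatialized
    food-web model in real applications, or by the synthetic generator
    here).  An empty brackish mask yields NaN (flagged missing).
    """
    surface = np.asarray(potential_density_surface, dtype=float)
    mask = np.asarray(brackish_mask, dtype=bool)
    if surface.shape != mask.shape:
        raise ValueError(f"surface shape {surface.shape} != mask shape {mask.shape}")
    if not mask.any():
        return float("nan")
    return float(surface[mask].mean())


def assemble_indicator_table(capacity: pd.DataFrame, flow: pd.DataFrame) -> pd.DataFrame:
    """Assemble the long-format unit x ES indicator table.

    ``capacity`` and ``flow`` are wide per-unit frames whose columns are ES
    names from the registry.  Units of measure and CICES categories are
    attached from the registry; unknown columns are rejected.
    """
    for df in (capacity, flow):
        unknown = set(df.columns) - set(ES_REGISTRY)
        if unknown:
            raise KeyError(f"unknown ES column(s): {sorted(unknown)}")
    rows = []
    for es, (category, cap_unit, flow_unit) in ES_REGISTRY.items():
        for uid in capacity.index:
            cap = capacity.at[uid, es] if es in capacity.columns else np.nan
            flo = flow.at[uid, es] if es in flow.columns else np.nan
            if category == "cultural" or es == "lifecycle_support":
                # attractiveness-based capacities are bounded by construction
                if np.isfinite(cap) and not (0.0 <= cap <= 1.0 + 1e-9):
                    raise ValueError(f"{es} capacity for unit {uid} outside [0, 1]: {cap}")
            if np.isfinite(flo) and flo < 0:
                raise ValueError(f"{es} flow for unit {uid} negative: {flo}")
            rows.append(
                {
                    "legend_id": uid,
                    "es": es,
                    "category": category,
                    "capacity": cap,
                    "flow": flo,
                    "capacity_unit": cap_unit,
                    "flow_unit": flow_unit,
                }
            )
    return pd.DataFrame(rows)
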