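"""Group-conditioned synthetic scenario generator.

The real dataset behind the assessment — classified very-high-resolution
imagery, managers' production records, hunting registers, visitor counts —
is private.  This module generates a synthetic stand-in with the
statistical structure the analysis assumes, conditioned on the management
group of each unit:

* **Landscapes.**  Per-unit land-cover rasters are synthesized by
  quantile-thresholding smoothed Gaussian random fields: a base field
  splits water from non-water at the unit's sampled water proportion, a
  second field splits freshwater from brackish within water, and a third
  field — whose smoothing length is the *edge-roughness* control — carves
  saltmarsh out of the non-water area.  Target class proportions are drawn
  from a Dirichlet distribution around group means, so realized
  compositions vary between units of a group while holding the group
  signal: fish-production units (F) are dominated by water, recreational
  units (R) by terrestrial land, abandoned units (N) have no freshwater
  pools, and the mixed/hunting groups (M, H) get rough-edged saltmarsh.

* **Records.**  Yearly management records are truncated-normal around
  group means with a per-unit level factor.  Zeros the study reports as
  structurally absent are enforced, not sampled: abandoned units (N) have
  no seeding, catch, or hunting records; closed-access units (F, H) have
  zero cultural flows (no tourists, excursionists, or birdwatchers).  A
  configurable flag raises the fish-catch mean of designated
  multiple-use (M) units above their potential-biomass capacity, emulating
  units whose provisioning flow exceeds capacity.

* **Surfaces and habitats.**  Fish-suitability and potential-biomass
  surfaces (inputs the real study took from a spatialized food-web model),
  attractiveness factor surfaces, habitat masks nested in their land-cover
  classes, toy red/NIR reflectance stacks whose mean NDVI places
  Salicornia pixels inside the configured detection range, and waterbird
  census points for the hunting-capacity interpolation.

Everything is a pure function of ``(unit, config, seed)``: per-unit,
per-stage random generators are spawned from the master seed via
``numpy``'s ``SeedSequence`` so regenerating any piece in isolation gives
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .es import HabitatLayerSet
from .fixture import GROUPS, ValleUnit, build_study_fixture
from .raster import BRACKISH, FRESHWATER, LAND, SALTMARSH, LandCoverRaster

RECORD_FIELDS = (
    "fry_sown",
    "fish_catch",
    "waterbirds_censused",
    "waterfowl_catch",
    "salicornia_harvest",
    "honey_harvest",
    "tourists",
    "excursionists",
    "birdwatchers",
)

#: record fields forced to zero per group (structural absences, not sampled)
STRUCTURAL_ZEROS = {
    "N": ("fry_sown", "fish_catch", "waterfowl_catch", "honey_harvest", "salicornia_harvest"),
    "F": ("tourists", "excursionists", "birdwatchers"),
    "H": ("tourists", "excursionists", "birdwatchers"),
}

_STAGES = {
    "landscape": 1,
    "habitats": 2,
    "surfaces": 3,
    "ndvi": 4,
    "census": 5,
    "records": 6,
    "purification": 7,
    "levels": 8,
}


@dataclass
class GroupParams:
    """Generator parameters for one management group."""

    #: mean class proportions (land, saltmarsh, brackish, freshwater); sum <= 1
    class_proportions: tuple[float, float, float, float]
    #: smoothing length (pixels) of the saltmarsh field; smaller = rougher edges
    saltmarsh_smoothness: float
    #: habitat areas as fractions of their parent class
    habitat_fractions: dict[str, float]
    #: amplitude of the [0, 1] attractiveness factor surfaces
    surface_scales: dict[str, float]
    potential_biomass_kg_ha_y: float
    huntable_density_n_ha_y: float
    n_removal_fraction_mean: float
    #: yearly record means (units per field, see the record schema)
    record_means: dict[str, float]


def _default_group_params() -> dict[str, GroupParams]:
    return {
        "F": GroupParams(
            class_proportions=(0.07, 0.08, 0.75, 0.10),
            saltmarsh_smoothness=3.0,
            habitat_fractions={
                "vegetated_saltmarsh": 0.70,
                "seagrass_meadow": 0.30,
                "reed_stand": 0.30,
                "shrub": 0.15,
                "herbaceous": 0.25,
                "pedestrian_path": 0.02,
                "nesting_area": 0.20,
                "salicornia": 0.12,
                "limonium": 0.10,
            },
            surface_scales={
                "fish_suitability": 0.90,
                "fauna_occurrence": 0.70,
                "water_quality": 0.80,
                "natural_terrestrial_proximity": 0.50,
                "inclusivity": 0.10,
                "bird_probability": 0.60,
            },
            potential_biomass_kg_ha_y=200.0,
            huntable_density_n_ha_y=8.0,
            n_removal_fraction_mean=0.45,
            record_means={
                "fry_sown": 60.0,
                "fish_catch": 140.0,
                "waterbirds_censused": 10.0,
                "waterfowl_catch": 0.5,
                "salicornia_harvest": 0.35,
                "honey_harvest": 0.02,
                "tourists": 0.0,
                "excursionists": 0.0,
                "birdwatchers": 0.0,
            },
        ),
        "M": GroupParams(
            class_proportions=(0.17, 0.18, 0.55, 0.10),
            saltmarsh_smoothness=1.0,
            habitat_fractions={
                "vegetated_saltmarsh": 0.80,
                "seagrass_meadow": 0.25,
                "reed_stand": 0.30,
                "shrub": 0.15,
                "herbaceous": 0.25,
                "pedestrian_path": 0.05,
                "nesting_area": 0.25,
                "salicornia": 0.15,
                "limonium": 0.10,
            },
            surface_scales={
                "fish_suitability": 0.70,
                "fauna_occurrence": 0.80,
                "water_quality": 0.70,
                "natural_terrestrial_proximity": 0.70,
                "inclusivity": 0.50,
                "bird_probability": 0.70,
            },
            potential_biomass_kg_ha_y=120.0,
            huntable_density_n_ha_y=15.0,
            n_removal_fraction_mean=0.42,
            record_means={
                "fry_sown": 35.0,
                "fish_catch": 60.0,
                "waterbirds_censused": 20.0,
                "waterfowl_catch": 5.0,
                "salicornia_harvest": 1.5,
                "honey_harvest": 0.05,
                "tourists": 300.0,
                "excursionists": 150.0,
                "birdwatchers": 60.0,
            },
        ),
        "H": GroupParams(
            class_proportions=(0.16, 0.19, 0.50, 0.15),
            saltmarsh_smoothness=1.0,
            habitat_fractions={
                "vegetated_saltmarsh": 0.80,
                "seagrass_meadow": 0.25,
                "reed_stand": 0.30,
                "shrub": 0.15,
                "herbaceous": 0.25,
                "pedestrian_path": 0.02,
                "nesting_area": 0.30,
                "salicornia": 0.12,
                "limonium": 0.10,
            },
            surface_scales={
                "fish_suitability": 0.50,
                "fauna_occurrence": 0.80,
                "water_quality": 0.70,
                "natural_terrestrial_proximity": 0.70,
                "inclusivity": 0.10,
                "bird_probability": 0.80,
            },
            potential_biomass_kg_ha_y=60.0,
            huntable_density_n_ha_y=20.0,
            n_removal_fraction_mean=0.40,
            record_means={
                "fry_sown": 8.0,
                "fish_catch": 10.0,
                "waterbirds_censused": 25.0,
                "waterfowl_catch": 8.0,
                "salicornia_harvest": 0.45,
                "honey_harvest": 0.02,
                "tourists": 0.0,
                "excursionists": 0.0,
                "birdwatchers": 0.0,
            },
        ),
        "R": GroupParams(
            class_proportions=(0.55, 0.10, 0.30, 0.05),
            saltmarsh_smoothness=3.0,
            habitat_fractions={
                "vegetated_saltmarsh": 0.60,
                "seagrass_meadow": 0.05,
                "reed_stand": 0.30,
                "shrub": 0.15,
                "herbaceous": 0.25,
                "pedestrian_path": 0.10,
                "nesting_area": 0.15,
                "salicornia": 0.10,
                "limonium": 0.05,
            },
            surface_scales={
                "fish_suitability": 0.30,
                "fauna_occurrence": 0.85,
                "water_quality": 0.75,
                "natural_terrestrial_proximity": 0.80,
                "inclusivity": 0.80,
                "bird_probability": 0.70,
            },
            potential_biomass_kg_ha_y=30.0,
            huntable_density_n_ha_y=6.0,
            n_removal_fraction_mean=0.28,
            record_means={
                "fry_sown": 0.0,
                "fish_catch": 0.0,
                "waterbirds_censused": 8.0,
                "waterfowl_catch": 0.0,
                "salicornia_harvest": 0.15,
                "honey_harvest": 0.01,
                "tourists": 3000.0,
                "excursionists": 1500.0,
                "birdwatchers": 200.0,
            },
        ),
        "N": GroupParams(
            class_proportions=(0.20, 0.10, 0.70, 0.0),
            saltmarsh_smoothness=3.0,
            habitat_fractions={
                "vegetated_saltmarsh": 0.30,
                "seagrass_meadow": 0.05,
                "reed_stand": 0.10,
                "shrub": 0.15,
                "herbaceous": 0.25,
                "pedestrian_path": 0.0,
                "nesting_area": 0.10,
                "salicornia": 0.05,
                "limonium": 0.05,
            },
            surface_scales={
                "fish_suitability": 0.35,
                "fauna_occurrence": 0.55,
                "water_quality": 0.55,
                "natural_terrestrial_proximity": 0.45,
                "inclusivity": 0.15,
                "bird_probability": 0.50,
            },
            potential_biomass_kg_ha_y=25.0,
            huntable_density_n_ha_y=10.0,
            n_removal_fraction_mean=0.22,
            record_means={
                "fry_sown": 0.0,
                "fish_catch": 0.0,
                "waterbirds_censused": 12.0,
                "waterfowl_catch": 0.0,
                "salicornia_harvest": 0.0,
                "honey_harvest": 0.0,
                "tourists": 400.0,
                "excursionists": 250.0,
                "birdwatchers": 80.0,
            },
        ),
    }


@dataclass
class ScenarioConfig:
    """All tunables of a synthetic scenario; a pure function of this + seed."""

    group_params: dict[str, GroupParams] = field(default_factory=_default_group_params)
    pixel_size: float = 25.0
    base_smoothness: float = 4.0
    proportion_concentration: float = 300.0
    years: tuple[int, int] = (2010, 2020)
    record_year_cv: float = 0.10
    unit_level_sd: float = 0.05
    #: legend ids of M units whose fish-catch mean is set above capacity
    flow_exceeds_capacity_units: tuple[int, ...] = (22, 26)
    flow_exceeds_factor: float = 2.0
    salicornia_ndvi_range: tuple[float, float] = (0.20, 0.45)
    n_load_gN_m2_y: float = 15.0
    n_removal_sd: float = 0.03
    census_points_range: tuple[int, int] = (4, 8)
    seed: int = 0

    def validate(self) -> list[str]:
        """Return diagnostics; empty list iff the config is runnable."""
        issues = []
        for g in GROUPS:
            if g not in self.group_params:
                issues.append(f"group_params missing group {g!r}")
                continue
            gp = self.group_params[g]
            props = np.asarray(gp.class_proportions, dtype=float)
            if (props < 0).any() or (props > 1).any():
                issues.append(f"group {g}: class proportions must be in [0, 1]")
            if props.sum() > 1.0 + 1e-9:
                issues.append(f"group {g}: class proportions sum to {props.sum():.3f} > 1")
            if not 0.0 <= gp.n_removal_fraction_mean <= 1.0:
                issues.append(f"group {g}: n_removal_fraction_mean outside [0, 1]")
            for name, frac in gp.habitat_fractions.items():
                if not 0.0 <= frac <= 1.0:
                    issues.append(f"group {g}: habitat fraction {name} outside [0, 1]")
            for name, mean in gp.record_means.items():
                if mean < 0:
                    issues.append(f"group {g}: record mean {name} negative")
        if self.pixel_size <= 0:
            issues.append("pixel_size must be > 0")
        if self.years[0] > self.years[1]:
            issues.append(f"empty years window {self.years}")
        if self.flow_exceeds_factor < 0:
            issues.append("flow_exceeds_factor must be >= 0")
        lo, hi = self.salicornia_ndvi_range
        if lo > hi:
            issues.append("salicornia_ndvi_range lower bound exceeds upper bound")
        return issues

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "group_params" in data:
            data["group_params"] = {
                g: GroupParams(
                    **{
                        **gp,
                        "class_proportions": tuple(gp["class_proportions"]),
                    }
                )
                for g, gp in data["group_params"].items()
            }
        for key in ("years", "flow_exceeds_capacity_units", "salicornia_ndvi_range",
                    "census_points_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _rng(seed: int, legend_id: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(legend_id, _STAGES[stage])))


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smoothed standard-normal field rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _select_lowest(field_vals: np.ndarray, mask: np.ndarray, count: int) -> np.ndarray:
    """Boolean mask of the ``count`` lowest-field pixels within ``mask``."""
    out = np.zeros(mask.shape, dtype=bool)
    if count <= 0:
        return out
    idx = np.flatnonzero(mask)
    order = np.argsort(field_vals.ravel()[idx], kind="stable")
    out.ravel()[idx[order[:count]]] = True
    return out


def unit_level_factors(unit: ValleUnit, config: ScenarioConfig, seed: int | None = None) -> dict[str, float]:
    """Per-unit multiplicative level factors shared by capacity and flow.

    A unit that can grow more fish is also fished harder; a unit richer in
    waterfowl sees more hunting.  Capacity surfaces and the matching record
    means therefore share one level factor per service family (``fish``,
    ``hunt``) so that between-unit level variation does not decouple flow
    from capacity.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, unit.legend_id, "levels")
    return {
        "fish": max(0.1, 1.0 + rng.normal(0.0, config.unit_level_sd)),
        "hunt": max(0.1, 1.0 + rng.normal(0.0, config.unit_level_sd)),
        "cultural": max(0.1, 1.0 + rng.normal(0.0, config.unit_level_sd)),
    }


def _sample_props(rng: np.random.Generator, gp: GroupParams, config: ScenarioConfig) -> np.ndarray:
    """Dirichlet draw of (land, saltmarsh, brackish, freshwater) proportions."""
    props = np.asarray(gp.class_proportions, dtype=float)
    if props.sum() > 1.0 + 1e-9:
        raise ValueError(f"class proportion targets sum to {props.sum():.3f} > 1")
    present = props > 0
    alpha = props[present] * config.proportion_concentration
    sampled = np.zeros(4)
    sampled[present] = rng.dirichlet(alpha)
    return sampled


def sample_class_proportions(
    unit: ValleUnit, config: ScenarioConfig, seed: int | None = None
) -> np.ndarray:
    """The unit's realized class proportions, identical to the ones used by
    :func:`generate_landscape` (same stream, same first draw)."""
    seed = config.seed if seed is None else seed
    return _sample_props(_rng(seed, unit.legend_id, "landscape"), config.group_params[unit.group], config)


def grid_shape(unit: ValleUnit, config: ScenarioConfig) -> tuple[int, int]:
    """Square grid side covering the unit's nominal area at the pixel size."""
    n = int(round(np.sqrt(unit.total_area) / config.pixel_size))
    if n < 8:
        raise ValueError(
            f"unit {unit.legend_id} area {unit.total_area} m^2 too small for "
            f"pixel size {config.pixel_size} m"
        )
    return (n, n)


def generate_landscape(unit: ValleUnit, config: ScenarioConfig, seed: int | None = None) -> LandCoverRaster:
    """Synthesize the unit's land-cover raster (deterministic in the seed)."""
    seed = config.seed if seed is None else seed
    gp = config.group_params[unit.group]
    shape = grid_shape(unit, config)
    n_pixels = shape[0] * shape[1]
    rng = _rng(seed, unit.legend_id, "landscape")

    # Dirichlet draw around the group's target composition (absent classes stay absent)
    try:
        sampled = _sample_props(rng, gp, config)
    except ValueError as exc:
        raise ValueError(f"group {unit.group}: {exc}") from exc
    p_land, p_salt, p_brack, p_fresh = sampled

    base = gaussian_filter(rng.standard_normal(shape), sigma=config.base_smoothness, mode="reflect")
    water_count = int(round((p_brack + p_fresh) * n_pixels))
    water = _select_lowest(base, np.ones(shape, dtype=bool), water_count)

    fresh_field = gaussian_filter(rng.standard_normal(shape), sigma=config.base_smoothness, mode="reflect")
    fresh_count = int(round(p_fresh * n_pixels))
    fresh = _select_lowest(fresh_field, water, fresh_count)

    salt_field = gaussian_filter(rng.standard_normal(shape), sigma=gp.saltmarsh_smoothness, mode="reflect")
    salt_count = int(round(p_salt * n_pixels))
    salt = _select_lowest(salt_field, ~water, salt_count)

    grid = np.full(shape, LAND, dtype=np.int16)
    grid[water] = BRACKISH
    grid[fresh] = FRESHWATER
    grid[salt] = SALTMARSH
    return LandCoverRaster(grid, pixel_size=config.pixel_size)


def generate_habitats(
    unit: ValleUnit, raster: LandCoverRaster, config: ScenarioConfig, seed: int | None = None
) -> tuple[HabitatLayerSet, float]:
    """Habitat masks nested in their land-cover classes, plus Limonium area (m^2).

    Salicornia patches are a subset of vegetated saltmarsh; seagrass lies in
    brackish water; reed stands in freshwater; shrub, herbaceous vegetation
    and pedestrian paths on terrestrial land; nesting areas on saltmarsh.
    """
    seed = config.seed if seed is None else seed
    gp = config.group_params[unit.group]
    fr = gp.habitat_fractions
    rng = _rng(seed, unit.legend_id, "habitats")
    shape = raster.shape

    def subset(parent: np.ndarray, fraction: float, sigma: float = 2.0) -> np.ndarray:
        count = int(round(fraction * np.count_nonzero(parent)))
        f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
        return _select_lowest(f, parent, count)

    salt = raster.mask(SALTMARSH)
    land = raster.mask(LAND)
    veg_salt = subset(salt, fr["vegetated_saltmarsh"])
    masks = {
        "vegetated_saltmarsh": veg_salt,
        "seagrass_meadow": subset(raster.mask(BRACKISH), fr["seagrass_meadow"]),
        "reed_stand": subset(raster.mask(FRESHWATER), fr["reed_stand"]),
        "shrub": subset(land, fr["shrub"]),
        "herbaceous": subset(land, fr["herbaceous"]),
        "freshwater_pool": raster.mask(FRESHWATER),
        "pedestrian_path": subset(land, fr["pedestrian_path"], sigma=1.0),
        "nesting_area": subset(salt, fr["nesting_area"]),
        "salicornia": subset(veg_salt, min(1.0, fr["salicornia"] / max(fr["vegetated_saltmarsh"], 1e-9))),
        "saltmarsh": salt,
        "freshwater": raster.mask(FRESHWATER),
    }
    limonium_area = fr["limonium"] * np.count_nonzero(salt) * raster.pixel_area
    return HabitatLayerSet(masks, pixel_size=raster.pixel_size), float(limonium_area)


SURFACE_NAMES = (
    "fish_suitability",
    "fauna_occurrence",
    "water_quality",
    "natural_terrestrial_proximity",
    "inclusivity",
    "bird_probability",
)


def generate_surfaces(
    unit: ValleUnit, raster: LandCoverRaster, config: ScenarioConfig, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Smooth random attractiveness-factor and potential-biomass surfaces."""
    seed = config.seed if seed is None else seed
    gp = config.group_params[unit.group]
    rng = _rng(seed, unit.legend_id, "surfaces")
    shape = raster.shape
    out: dict[str, np.ndarray] = {}
    for name in SURFACE_NAMES:
        scale = gp.surface_scales[name]
        f = _smooth_unit_field(rng, shape, sigma=3.0)
        out[name] = scale * (0.5 + 0.5 * f)
    level = unit_level_factors(unit, config, seed)["fish"]
    f = _smooth_unit_field(rng, shape, sigma=3.0)
    out["potential_biomass"] = gp.potential_biomass_kg_ha_y * level * (0.9 + 0.2 * f)
    return out


def generate_ndvi_stack(
    unit: ValleUnit,
    raster: LandCoverRaster,
    habitats: HabitatLayerSet,
    config: ScenarioConfig,
    seed: int | None = None,
    n_years: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Toy red/NIR reflectance stacks (n_years, rows, cols).

    Pixel-level target NDVI: Salicornia patches sit at the centre of the
    configured detection range; other vegetation is greener (above the
    range), water is negative, bare land near zero — so mean-NDVI range
    filtering recovers exactly the Salicornia patches.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, unit.legend_id, "ndvi")
    lo, hi = config.salicornia_ndvi_range
    centre = 0.5 * (lo + hi)
    shape = raster.shape
    target = np.full(shape, 0.05)
    vegetated = (
        habitats.masks["vegetated_saltmarsh"]
        | habitats.masks["shrub"]
        | habitats.masks["herbaceous"]
        | habitats.masks["reed_stand"]
    )
    target[vegetated] = min(hi + 0.25, 0.9)
    target[(raster.grid == BRACKISH) | (raster.grid == FRESHWATER)] = -0.3
    target[habitats.masks["salicornia"]] = centre
    jitter_sd = min(0.02, 0.2 * (hi - lo))
    red = np.empty((n_years, *shape))
    nir = np.empty((n_years, *shape))
    for y in range(n_years):
        t = np.clip(target + rng.normal(0.0, jitter_sd, shape), -0.95, 0.95)
        red[y] = 0.2
        nir[y] = 0.2 * (1 + t) / (1 - t)
    return red, nir


def generate_census_points(
    unit: ValleUnit, raster: LandCoverRaster, config: ScenarioConfig, seed: int | None = None
) -> list[tuple[float, float, float]]:
    """Waterbird census points ``(x, y, n ha^-1 y^-1)`` within the unit."""
    seed = config.seed if seed is None else seed
    gp = config.group_params[unit.group]
    rng = _rng(seed, unit.legend_id, "census")
    lo, hi = config.census_points_range
    k = int(rng.integers(lo, hi + 1))
    nr, nc = raster.shape
    level = unit_level_factors(unit, config, seed)["hunt"]
    mean = gp.huntable_density_n_ha_y * level
    pts = []
    for _ in range(k):
        r = rng.integers(0, nr)
        c = rng.integers(0, nc)
        v = max(0.0, rng.normal(mean, 0.10 * mean))
        pts.append((float(c * raster.pixel_size), float(r * raster.pixel_size), v))
    return pts


def generate_purification_params(
    unit: ValleUnit, config: ScenarioConfig, seed: int | None = None
) -> tuple[float, float]:
    """Per-unit (nitrogen load gN m^-2 y^-1, removal fraction)."""
    seed = config.seed if seed is None else seed
    gp = config.group_params[unit.group]
    rng = _rng(seed, unit.legend_id, "purification")
    load = max(0.0, rng.normal(config.n_load_gN_m2_y, 0.05 * config.n_load_gN_m2_y))
    frac = float(np.clip(rng.normal(gp.n_removal_fraction_mean, config.n_removal_sd), 0.0, 1.0))
    return load, frac


def generate_records(
    unit: ValleUnit, config: ScenarioConfig, seed: int | None = None
) -> pd.DataFrame:
    """Yearly management records for one unit (one row per year).

    Truncated-normal draws around the group means, scaled by the per-unit
    level factor of the matching service family (see
    :func:`unit_level_factors`) — wild-food harvests scale with the unit's
    realized saltmarsh share instead, since the harvest tracks how much
    halophyte habitat the unit actually has.  Structural zeros are enforced
    per :data:`STRUCTURAL_ZEROS`; the fish-catch mean of designated M units
    is raised above their potential-biomass capacity when the
    flow-exceeds-capacity flag applies.
    """
    seed = config.seed if seed is None else seed
    gp = config.group_params[unit.group]
    rng = _rng(seed, unit.legend_id, "records")
    y0, y1 = config.years
    if y0 > y1:
        raise ValueError(f"empty years window {config.years}")
    years = np.arange(y0, y1 + 1)
    zeros = STRUCTURAL_ZEROS.get(unit.group, ())
    levels = unit_level_factors(unit, config, seed)
    salt_mean = gp.class_proportions[1]
    salt_realized = sample_class_proportions(unit, config, seed)[1]
    salt_ratio = salt_realized / salt_mean if salt_mean > 0 else 1.0
    family_level = {
        "fry_sown": levels["fish"],
        "fish_catch": levels["fish"],
        "waterbirds_censused": levels["hunt"],
        "waterfowl_catch": levels["hunt"],
        "salicornia_harvest": salt_ratio,
        "honey_harvest": salt_ratio,
        "tourists": levels["cultural"],
        "excursionists": levels["cultural"],
        "birdwatchers": levels["cultural"],
    }
    rows = []
    for year in years:
        row = {"legend_id": unit.legend_id, "group": unit.group, "year": int(year)}
        for fname in RECORD_FIELDS:
            mean = gp.record_means[fname]
            if (
                fname == "fish_catch"
                and unit.group == "M"
                and unit.legend_id in config.flow_exceeds_capacity_units
            ):
                mean = config.flow_exceeds_factor * gp.potential_biomass_kg_ha_y
            if fname in zeros or mean == 0.0:
                row[fname] = 0.0
                continue
            mean = mean * family_level[fname]
            v = max(0.0, rng.normal(mean, config.record_year_cv * mean))
            if unit.group == "R" and fname == "tourists":
                v = max(v, 1.0)  # recreational units always host some visitors
            row[fname] = v
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class Scenario:
    """A fully generated synthetic study: all inputs the assessment needs."""

    config: ScenarioConfig
    seed: int
    units: list[ValleUnit]
    rasters: dict[int, LandCoverRaster]
    habitats: dict[int, HabitatLayerSet]
    limonium_areas: dict[int, float]
    surfaces: dict[int, dict[str, np.ndarray]]
    ndvi_stacks: dict[int, tuple[np.ndarray, np.ndarray]]
    census_points: dict[int, list[tuple[float, float, float]]]
    purification: dict[int, tuple[float, float]]
    records: pd.DataFrame


def generate_scenario(
    config: ScenarioConfig | None = None,
    seed: int | None = None,
    units: list[ValleUnit] | None = None,
) -> Scenario:
    """Generate the full 31-unit synthetic study (pure in config + seed)."""
    config = config or ScenarioConfig()
    seed = config.seed if seed is None else seed
    issues = config.validate()
    if issues:
        raise ValueError("invalid scenario config: " + "; ".join(issues))
    units = units if units is not None else build_study_fixture()
    rasters, habitats, limonium, surfaces, ndvi_stacks, census, purif = (
        {}, {}, {}, {}, {}, {}, {},
    )
    all_records = []
    for unit in units:
        uid = unit.legend_id
        rasters[uid] = generate_landscape(unit, config, seed)
        habitats[uid], limonium[uid] = generate_habitats(unit, rasters[uid], config, seed)
        surfaces[uid] = generate_surfaces(unit, rasters[uid], config, seed)
        ndvi_stacks[uid] = generate_ndvi_stack(unit, rasters[uid], habitats[uid], config, seed)
        census[uid] = generate_census_points(unit, rasters[uid], config, seed)
        purif[uid] = generate_purification_params(unit, config, seed)
        all_records.append(generate_records(unit, config, seed))
    return Scenario(
        config=config,
        seed=seed,
        units=list(units),
        rasters=rasters,
        habitats=habitats,
        limonium_areas=limonium,
        surfaces=surfaces,
        ndvi_stacks=ndvi_stacks,
        census_points=census,
        purification=purif,
        records=pd.concat(all_records, ignore_index=True),
    )
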