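"""End-to-end assessment pipeline.

Composes the stages — synthetic scenario generation, landscape metrics, ES
capacity/flow indicators, normalization + aggregation, and group
statistics — into one seed-deterministic run.  Stages are plain functions
over in-memory tables, so any stage can be recomputed (e.g. statistics at
a different alpha) without regenerating upstream inputs.

Every output table carries a metadata comment header (seed, config hash,
software version); outputs contain no timestamps, so two runs with the
same config and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import aggregated_table, radar_chart_data
from .es import (
    aquaculture_capacity,
    assemble_indicator_table,
    attractiveness_index,
    climate_regulation,
    huntable_density_surface,
    lifecycle_flow,
    record_mean_flow,
    water_purification,
    weighted_sum_bounds,
    wildfood_capacity,
)
from .fixture import LANDSCAPE_INDICATORS
from .landscape import landscape_table
from .raster import BRACKISH, detect_vegetation_patches, ndvi, write_raster
from .rates import DEFAULT_WEIGHTS, RateTable
from .stats import compare_groups, spearman_correlogram
from .synthetic import Scenario, ScenarioConfig, generate_scenario

log = logging.getLogger("vallescape")

AGGREGATE_COLUMNS = (
    "regulating_capacity",
    "regulating_flow",
    "provisioning_capacity",
    "provisioning_flow",
    "cultural_capacity",
    "cultural_flow",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (and unit if known)."""

    def __init__(self, stage: str, unit_id: int | None, cause: Exception):
        where = f"stage {stage!r}" + (f", unit {unit_id}" if unit_id is not None else "")
        super().__init__(f"{where}: {cause}")
        self.stage = stage
        self.unit_id = unit_id


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    rates: RateTable = field(default_factory=RateTable)
    weights: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_WEIGHTS.items()})
    alpha: float = 0.05
    adjustment: str = "none"
    seed: int = 0
    out_dir: str = "vallescape_run"
    write_rasters: bool = True


def validate_config(config: RunConfig) -> list[str]:
    """Diagnostics for a run config; empty list iff runnable."""
    issues = list(config.scenario.validate())
    if not 0.0 < config.alpha < 1.0:
        issues.append(f"alpha must be in (0, 1), got {config.alpha}")
    if config.adjustment not in ("none", "holm", "bonferroni", "bh"):
        issues.append(f"unknown adjustment {config.adjustment!r}")
    expected_lengths = {k: len(v) for k, v in DEFAULT_WEIGHTS.items()}
    for index_name, wset in config.weights.items():
        if index_name not in expected_lengths:
            issues.append(f"unknown attractiveness index {index_name!r}")
            continue
        if len(wset) != expected_lengths[index_name]:
            issues.append(
                f"attractiveness index {index_name!r}: {len(wset)} weights, "
                f"expected {expected_lengths[index_name]}"
            )
        for fct, w in wset.items():
            if w < 0:
                issues.append(f"attractiveness index {index_name!r}: weight {fct} negative")
    try:
        RateTable(**{k: getattr(config.rates, k) for k in vars(config.rates)})
    except ValueError as exc:
        issues.append(str(exc))
    return issues


def compute_es_indicators(
    scenario: Scenario, rates: RateTable | None = None, weights: dict | None = None
) -> pd.DataFrame:
    """Compute the long-format unit x ES capacity/flow table for a scenario."""
    rates = rates or RateTable()
    weights = weights or DEFAULT_WEIGHTS
    uids = [u.legend_id for u in scenario.units]
    capacity = pd.DataFrame(index=pd.Index(uids, name="legend_id"), dtype=float)
    flow = pd.DataFrame(index=capacity.index, dtype=float)

    # attractiveness indices share one min-max scale across the unit set
    def attractiveness_means(index_name: str, layer_builder) -> pd.Series:
        w = list(weights[index_name].values())
        layers_by_unit = {uid: layer_builder(uid) for uid in uids}
        bounds = weighted_sum_bounds(layers_by_unit, w)
        means = {}
        for uid, layers in layers_by_unit.items():
            _, means[uid] = attractiveness_index(layers, w, rescale_bounds=bounds)
        return pd.Series(means)

    def masks(uid):
        return scenario.habitats[uid].masks

    def surf(uid):
        return scenario.surfaces[uid]

    for uid in uids:
        unit_area = scenario.rasters[uid].grid.size * scenario.rasters[uid].pixel_area
        try:
            cap, flo = climate_regulation(scenario.habitats[uid], rates, unit_area)
            capacity.at[uid, "climate_regulation"] = cap
            flow.at[uid, "climate_regulation"] = flo

            brackish_area = float(
                np.count_nonzero(scenario.rasters[uid].grid == BRACKISH)
            ) * scenario.rasters[uid].pixel_area
            load, frac = scenario.purification[uid]
            pur = water_purification(brackish_area, load, frac)
            capacity.at[uid, "water_purification"] = pur.capacity_pct
            flow.at[uid, "water_purification"] = pur.flow_pct

            surface = huntable_density_surface(
                scenario.census_points[uid],
                scenario.rasters[uid].shape,
                scenario.rasters[uid].pixel_size,
            )
            capacity.at[uid, "hunting"] = float(surface.mean())

            capacity.at[uid, "aquaculture"] = aquaculture_capacity(
                surf(uid)["potential_biomass"], scenario.rasters[uid].grid == BRACKISH
            )

            red, nir = scenario.ndvi_stacks[uid]
            annual = np.stack([ndvi(red[y], nir[y]) for y in range(red.shape[0])])
            salicornia = detect_vegetation_patches(annual, scenario.config.salicornia_ndvi_range)
            wf = wildfood_capacity(
                salicornia,
                scenario.limonium_areas[uid],
                rates,
                unit_area,
                scenario.rasters[uid].pixel_size,
            )
            capacity.at[uid, "wild_food"] = wf.total_kg_ha_y
        except Exception as exc:  # pragma: no cover - converted for diagnostics
            raise StageError("es_indicators", uid, exc) from exc

    capacity["lifecycle_support"] = attractiveness_means(
        "lifecycle_support",
        lambda uid: [
            masks(uid)["saltmarsh"],
            masks(uid)["freshwater"],
            masks(uid)["shrub"],
            masks(uid)["herbaceous"],
            surf(uid)["fish_suitability"],
        ],
    )
    capacity["tourism"] = attractiveness_means(
        "tourism",
        lambda uid: [
            masks(uid)["saltmarsh"],
            surf(uid)["fauna_occurrence"],
            surf(uid)["water_quality"],
            surf(uid)["natural_terrestrial_proximity"],
        ],
    )
    capacity["cognitive_development"] = attractiveness_means(
        "cognitive_development",
        lambda uid: [
            masks(uid)["saltmarsh"],
            surf(uid)["fauna_occurrence"],
            surf(uid)["water_quality"],
            surf(uid)["natural_terrestrial_proximity"],
            surf(uid)["inclusivity"],
        ],
    )
    capacity["birdwatching"] = attractiveness_means(
        "birdwatching",
        lambda uid: [
            masks(uid)["pedestrian_path"],
            masks(uid)["saltmarsh"],
            masks(uid)["nesting_area"],
            surf(uid)["bird_probability"],
        ],
    )

    records = scenario.records
    years = scenario.config.years
    flow["lifecycle_support"] = lifecycle_flow(records)
    flow["aquaculture"] = record_mean_flow(records, "fish_catch", years)
    flow["hunting"] = record_mean_flow(records, "waterfowl_catch", years)
    flow["wild_food"] = record_mean_flow(records, "salicornia_harvest", years) + record_mean_flow(
        records, "honey_harvest", years
    )
    flow["tourism"] = record_mean_flow(records, "tourists", years)
    flow["cognitive_development"] = record_mean_flow(records, "excursionists", years)
    flow["birdwatching"] = record_mean_flow(records, "birdwatchers", years)
    return assemble_indicator_table(capacity, flow)


def run_statistics(
    aggregated: pd.DataFrame,
    landscape: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    adjustment: str = "none",
):
    """Routed group comparisons for every aggregate and landscape indicator,
    plus the Spearman correlogram of the six ES aggregates.

    ``groups`` maps legend id -> management group.  Returns
    ``(comparisons, rho, p)``.
    """
    comparisons = {}
    for name in list(AGGREGATE_COLUMNS) + [f"{c}_difference" for c in
                                           ("regulating", "provisioning", "cultural")]:
        values = {
            g: aggregated.loc[groups[groups == g].index, name].dropna().to_numpy()
            for g in sorted(groups.unique())
        }
        comparisons[name] = compare_groups(name, values, alpha=alpha, adjustment=adjustment)
    for name in LANDSCAPE_INDICATORS:
        values = {
            g: landscape.loc[groups[groups == g].index, name].dropna().to_numpy()
            for g in sorted(groups.unique())
        }
        try:
            comparisons[name] = compare_groups(name, values, alpha=alpha, adjustment=adjustment)
        except ValueError as exc:
            log.warning("indicator %s not comparable across groups: %s", name, exc)
    rho, p = spearman_correlogram(aggregated, columns=list(AGGREGATE_COLUMNS))
    return comparisons, rho, p


def _config_hash(config: RunConfig) -> str:
    payload = yaml.safe_dump(
        {
            "scenario": yaml.safe_load(yaml.safe_dump(_asdict_safe(config.scenario))),
            "rates": _asdict_safe(config.rates),
            "weights": config.weights,
            "alpha": config.alpha,
            "adjustment": config.adjustment,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _asdict_safe(obj):
    from dataclasses import asdict, is_dataclass

    if is_dataclass(obj):
        return json.loads(json.dumps(asdict(obj), default=str))
    return obj


def _write_table(df: pd.DataFrame, path: Path, meta: dict, index: bool = True) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write all outputs under ``config.out_dir``.

    Returns the machine-readable run summary (also written as JSON).
    Aborts with :class:`StageError` naming the failing stage and unit.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid run config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": _config_hash(config), "version": __version__}
    timing: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)

            def __exit__(self, exc_type, exc, tb):
                timing[name] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s finished in %.2fs", name, timing[name])
                return False

        return _Timer()

    with stage("generate"):
        try:
            scenario = generate_scenario(config.scenario, seed=config.seed)
        except Exception as exc:
            raise StageError("generate", None, exc) from exc
        groups = pd.Series(
            {u.legend_id: u.group for u in scenario.units}, name="group"
        ).rename_axis("legend_id")
        _write_table(scenario.records, out / "records.csv", meta, index=False)
        units_df = pd.DataFrame(
            [
                {"legend_id": u.legend_id, "name": u.name, "group": u.group,
                 "total_area_m2": u.total_area}
                for u in scenario.units
            ]
        )
        _write_table(units_df, out / "units.csv", meta, index=False)
        if config.write_rasters:
            rdir = out / "rasters"
            rdir.mkdir(exist_ok=True)
            for uid, raster in scenario.rasters.items():
                write_raster(raster, rdir / f"unit_{uid:02d}.asc")

    with stage("metrics"):
        try:
            landscape = landscape_table(scenario.rasters)
        except Exception as exc:
            raise StageError("metrics", None, exc) from exc
        _write_table(landscape, out / "landscape_indicators.csv", meta)

    with stage("assess"):
        es_table = compute_es_indicators(scenario, config.rates, config.weights)
        _write_table(es_table, out / "es_indicators.csv", meta, index=False)

    with stage("aggregate"):
        try:
            aggregated = aggregated_table(es_table)
            radar = radar_chart_data(es_table)
        except Exception as exc:
            raise StageError("aggregate", None, exc) from exc
        _write_table(aggregated, out / "aggregated_indicators.csv", meta)
        _write_table(radar, out / "radar_data.csv", meta, index=False)

    with stage("stats"):
        try:
            comparisons, rho, pmat = run_statistics(
                aggregated, landscape, groups, alpha=config.alpha, adjustment=config.adjustment
            )
        except Exception as exc:
            raise StageError("stats", None, exc) from exc
        omnibus = pd.DataFrame(
            [
                {
                    "indicator": r.indicator,
                    "routing": r.routing,
                    "statistic": r.omnibus_statistic,
                    "p": r.omnibus_p,
                }
                for r in comparisons.values()
            ]
        )
        pairwise = pd.concat(
            [r.pairwise.assign(indicator=r.indicator) for r in comparisons.values()],
            ignore_index=True,
        )
        _write_table(omnibus, out / "stats_omnibus.csv", meta, index=False)
        _write_table(pairwise, out / "stats_pairwise.csv", meta, index=False)
        _write_table(rho, out / "correlogram_rho.csv", meta)
        _write_table(pmat, out / "correlogram_p.csv", meta)

    summary = {
        **meta,
        "alpha": config.alpha,
        "adjustment": config.adjustment,
        "n_units": len(scenario.units),
        "timing_s": timing,
        "annotations": {
            name: {g: sorted(s) for g, s in r.annotations.items()}
            for name, r in comparisons.items()
        },
        "correlogram_rho": {
            f"{a}|{b}": round(float(rho.at[a, b]), 4)
            for i, a in enumerate(AGGREGATE_COLUMNS)
            for b in AGGREGATE_COLUMNS[i + 1 :]
        },
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
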