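"""Min-max normalization and per-category aggregation of ES indicators.

Raw indicators live in incommensurable units, so before summation each one
is min-max normalized to [0, 1] across the 31-unit comparison set.  The
aggregated capacity of a category is the plain sum of its three normalized
capacity indicators (range [0, 3]); likewise for flow.  Capacity and flow
are normalized independently, each by its own min/max — which is what
allows a unit's normalized flow to exceed its normalized capacity.

The capacity-flow difference (capacity minus flow per category) may
therefore be negative: a negative value flags exploitation exceeding the
unit's normalized potential.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .fixture import ES_CATEGORIES, ES_REGISTRY


def minmax_normalize(values) -> pd.Series:
    """Min-max normalize a cross-unit vector to [0, 1].

    ``(x - min) / (max - min)``; the minimum maps to 0, the maximum to 1,
    missing values stay missing.  A constant vector is mapped to all zeros
    with a warning: absence of between-unit contrast carries no signal.
    """
    v = pd.Series(values).astype(float)
    if v.notna().sum() < 2:
        raise ValueError("min-max normalization needs >= 2 non-missing values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant vector: normalized to all zeros", stacklevel=2)
        return v * 0.0
    return (v - lo) / (hi - lo)


def _category_components(category: str) -> list[str]:
    if category not in ES_CATEGORIES:
        raise KeyError(f"unknown category {category!r}; must be one of {ES_CATEGORIES}")
    return [es for es, (cat, _, _) in ES_REGISTRY.items() if cat == category]


def aggregate_category(es_table: pd.DataFrame, category: str) -> pd.DataFrame:
    """Aggregated capacity and flow for one CICES category.

    ``es_table`` is the long-format unit x ES table.  Each component
    indicator is min-max normalized across units, then summed within the
    category.  A unit missing any component gets NaN (flagged, excluded
    pairwise downstream).

    Returns a frame indexed by unit with columns ``capacity`` and ``flow``.
    """
    components = _category_components(category)
    sub = es_table[es_table["es"].isin(components)]
    if set(sub["es"]) != set(components):
        missing = set(components) - set(sub["es"])
        raise KeyError(f"table missing component ES(s) {sorted(missing)} of {category!r}")
    out = {}
    for kind in ("capacity", "flow"):
        wide = sub.pivot(index="legend_id", columns="es", values=kind)[components]
        normalized = wide.apply(minmax_normalize, axis=0)
        out[kind] = normalized.sum(axis=1, skipna=False)
    return pd.DataFrame(out)


def capacity_flow_difference(aggregates: pd.DataFrame) -> pd.Series:
    """Per-unit capacity minus flow for one category's aggregates.

    Sign is preserved: negative values (flow exceeding normalized capacity)
    are meaningful and kept.
    """
    return aggregates["capacity"] - aggregates["flow"]


def aggregated_table(es_table: pd.DataFrame) -> pd.DataFrame:
    """Full per-unit aggregated indicator table.

    Columns: ``<category>_capacity``, ``<category>_flow`` and
    ``<category>_difference`` for the three CICES categories; each aggregate
    lies in [0, 3] (sum of three normalized components).
    """
    frames = {}
    for category in ES_CATEGORIES:
        agg = aggregate_category(es_table, category)
        frames[f"{category}_capacity"] = agg["capacity"]
        frames[f"{category}_flow"] = agg["flow"]
        frames[f"{category}_difference"] = capacity_flow_difference(agg)
    df = pd.DataFrame(frames)
    df.index.name = "legend_id"
    return df.sort_index()


def radar_chart_data(es_table: pd.DataFrame) -> pd.DataFrame:
    """Long-format normalized per-ES capacity/flow values for radar charts."""
    rows = []
    for category in ES_CATEGORIES:
        components = _category_components(category)
        sub = es_table[es_table["es"].isin(components)]
        for kind in ("capacity", "flow"):
            wide = sub.pivot(index="legend_id", columns="es", values=kind)[components]
            normalized = wide.apply(minmax_normalize, axis=0)
            for es in components:
                for uid, val in normalized[es].items():
                    rows.append(
                        {"legend_id": uid, "es": es, "kind": kind, "normalized_value": val}
                    )
    return pd.DataFrame(rows)
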