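"""Food-item aggregation and intake standardization.

Food-frequency-questionnaire data arrive as grams/day per food item. For
network analysis, items are collapsed into a fixed registry of food groups
(35 groups by default) and each group column is z-scored so that every food
enters the Gaussian graphical model on the same scale.

Tables are pandas DataFrames indexed by ``subject_id``; columns are food
items or food groups and values are intakes in g/d (raw) or z-scores
(standardized).
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_food_group_registry",
    "load_food_group_map",
    "validate_intake_table",
    "aggregate_to_groups",
    "standardize",
]


def load_food_group_registry() -> list[str]:
    """Return the packaged food-group registry in its canonical order.

    The default registry holds the 35 food groups used for dietary-network
    analysis (meats, dairy, fruit and vegetable subgroups, grains, legumes,
    snacks, fats and oils, beverages). Whole grains are deliberately absent:
    they are not a meaningful category in the source population's diet.
    """
    ref = importlib.resources.files("dietnet.data").joinpath("food_groups.csv")
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path)
    return table.sort_values("index")["group"].tolist()


def load_food_group_map(path) -> dict[str, str]:
    """Read a two-column (item, group) CSV into an item -> group mapping."""
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError("food-group map needs two columns: item, group")
    items = table.iloc[:, 0].astype(str)
    groups = table.iloc[:, 1].astype(str)
    dup = items[items.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate items in food-group map: {dup}")
    return dict(zip(items, groups))


def validate_intake_table(
    intakes: pd.DataFrame, *, allow_missing: bool = False, allow_negative: bool = False
) -> pd.DataFrame:
    """Check an intake table: unique subjects, >=2 rows, nonnegative g/d.

    ``allow_negative`` admits latent-scale (already-transformed) tables for
    which the g/d nonnegativity constraint does not apply.
    """
    if intakes.index.duplicated().any():
        dups = intakes.index[intakes.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject_id values: {dups}")
    if len(intakes) < 2:
        raise ValueError("intake table needs at least 2 subjects")
    if not allow_missing and intakes.isna().any().any():
        bad = intakes.columns[intakes.isna().any()].tolist()
        raise ValueError(f"missing intakes in columns: {bad}; use allow_missing or drop subjects")
    if not allow_negative and (intakes < 0).any().any():
        bad = intakes.columns[(intakes < 0).any()].tolist()
        raise ValueError(f"negative intakes in columns: {bad}")
    return intakes


def aggregate_to_groups(
    items: pd.DataFrame,
    food_group_map: dict[str, str],
    *,
    registry: list[str] | None = None,
) -> pd.DataFrame:
    """Sum item-level intakes (g/d) into food-group columns.

    Parameters
    ----------
    items
        Item-level intake table (subjects x items), indexed by subject_id.
    food_group_map
        item name -> group name. Every item column must be mapped.
    registry
        Ordered list of admissible group names. Defaults to the packaged
        35-group registry. Output columns follow registry order; groups
        with no mapped items are absent (logged).
    """
    validate_intake_table(items)
    if registry is None:
        registry = load_food_group_registry()

    unmapped = [c for c in items.columns if c not in food_group_map]
    if unmapped:
        raise ValueError(f"item columns missing from food-group map: {unmapped}")
    unknown = sorted({g for g in food_group_map.values() if g not in registry})
    if unknown:
        raise ValueError(f"map targets outside the group registry: {unknown}")

    grouped = items.T.groupby(items.columns.map(food_group_map)).sum().T
    present = [g for g in registry if g in grouped.columns]
    absent = [g for g in registry if g not in grouped.columns]
    if absent:
        logger.info("food groups with no mapped items: %s", absent)
    return grouped[present]


def standardize(grouped: pd.DataFrame, *, log_transform: bool = False) -> pd.DataFrame:
    """Z-score each food-group column: (x - mean) / SD with the n-1 SD.

    Every group then has mean 0 and standard deviation 1, which puts
    high-volume staples and condiments on a common footing before
    correlation-based modelling and network scoring.

    ``log_transform`` applies log(x + 1) first, pulling in the long right
    tail typical of intake data; off by default (and requires nonnegative
    intakes).
    """
    validate_intake_table(grouped, allow_negative=not log_transform)
    values = grouped.astype(float)
    if log_transform:
        values = np.log1p(values)
    sd = values.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ValueError(f"constant food-group columns cannot be standardized: {constant}")
    return (values - values.mean(axis=0)) / sd
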