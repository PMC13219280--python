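"""Trial-level scoring: questionnaire composites and the analysis-ready table.

Each trial carries six questionnaire items on a 0-6 scale; three items form
the Urge-to-Move composite and three the Pleasure composite, each the plain
arithmetic mean of its items.  The assembled trial table joins design keys,
composites and synchrony measures one-to-one and adds treatment-coded
syncopation dummies (Low as the reference category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL_KEYS = ("participant", "movement", "syncopation", "pattern")

#: Canonical syncopation level order (reference first).
LEVEL_ORDER = ("Low", "Middle", "High")

#: Default item-to-subscale map: items 1-3 -> urge, items 4-6 -> pleasure.
DEFAULT_ITEM_MAP: dict[str, tuple[str, str, str]] = {
    "urge": ("item1", "item2", "item3"),
    "pleasure": ("item4", "item5", "item6"),
}


class IncompleteItemsError(ValueError):
    """A trial is missing one or more item responses; it is flagged, not imputed."""


@dataclass(frozen=True)
class ItemResponses:
    """Six item scores (0-6) of one trial plus the item-to-subscale map."""

    items: dict[str, float]
    item_map: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_MAP)
    )

    def __post_init__(self) -> None:
        for subscale, names in self.item_map.items():
            if len(names) != 3:
                raise ValueError(f"subscale {subscale} must have exactly three items")
            for name in names:
                if name not in self.items or self.items[name] is None or (
                    isinstance(self.items[name], float) and np.isnan(self.items[name])
                ):
                    raise IncompleteItemsError(f"missing item {name}")
                v = self.items[name]
                if not 0 <= v <= 6:
                    raise ValueError(f"item {name}={v} outside [0, 6]")


def composite_scores(items: ItemResponses) -> tuple[float, float]:
    """(urge, pleasure) composites: arithmetic means of three items each."""
    urge = float(np.mean([items.items[k] for k in items.item_map["urge"]]))
    pleasure = float(np.mean([items.items[k] for k in items.item_map["pleasure"]]))
    return urge, pleasure


def composite_table(
    item_table: pd.DataFrame,
    item_map: dict[str, tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Vectorized composites for a table of item columns keyed by trial.

    Rows with any missing item are flagged in the returned ``incomplete``
    column (listwise exclusion is the caller's policy; nothing is imputed).
    """
    item_map = item_map or DEFAULT_ITEM_MAP
    out = item_table.copy()
    all_items = [c for cols in item_map.values() for c in cols]
    missing_cols = set(all_items) - set(out.columns)
    if missing_cols:
        raise IncompleteItemsError(f"missing item columns: {sorted(missing_cols)}")
    vals = out[all_items]
    if ((vals < 0) | (vals > 6)).any().any():
        bad = out.index[((vals < 0) | (vals > 6)).any(axis=1)].tolist()
        raise ValueError(f"item scores outside [0, 6] at rows {bad[:5]}")
    out["incomplete"] = vals.isna().any(axis=1)
    for subscale, cols in item_map.items():
        out[subscale] = out[list(cols)].mean(axis=1, skipna=False)
    return out


def add_syncopation_dummies(table: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded dummies with the Low level as reference.

    Non-canonical label sets are coded in first-appearance order, first level
    as reference.
    """
    out = table.copy()
    levels = list(pd.unique(out["syncopation"]))
    if set(levels) <= set(LEVEL_ORDER):
        order = [lv for lv in LEVEL_ORDER if lv in levels]
    else:
        order = levels
    if len(order) < 2:
        raise ValueError("need at least two syncopation levels for dummy coding")
    mid = order[1]
    out["sync_mid"] = (out["syncopation"] == mid).astype(int)
    if len(order) >= 3:
        out["sync_high"] = (out["syncopation"] == order[2]).astype(int)
    else:
        out["sync_high"] = 0
    return out


def assemble(
    design: pd.DataFrame,
    composites: pd.DataFrame,
    plv_results: pd.DataFrame,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Inner-join design, rating composites and PLV measures on the trial key.

    The join must be lossless and one-to-one; unmatched or duplicated keys
    raise with the offending trial key named.  Incomplete-rating trials are
    excluded listwise (with a report attached as ``DataFrame.attrs``).
    """
    keys = list(TRIAL_KEYS)
    for name, frame in (("design", design), ("composites", composites), ("plv", plv_results)):
        missing = set(keys) - set(frame.columns)
        if missing:
            raise KeyError(f"{name} table lacks key columns {sorted(missing)}")
        dup = frame.duplicated(subset=keys)
        if dup.any():
            first = frame.loc[dup, keys].iloc[0].to_dict()
            raise ValueError(f"duplicate trial key in {name} table: {first}")

    merged = design.merge(
        composites[keys + [c for c in ("urge", "pleasure", "incomplete") if c in composites]],
        on=keys,
        how="left",
        validate="one_to_one",
    ).merge(
        plv_results[keys + [c for c in ("plv1", "plv2") if c in plv_results]],
        on=keys,
        how="left",
        validate="one_to_one",
    )
    for col, source in (("urge", "composites"), ("plv1", "plv"), ("plv2", "plv")):
        if col in merged and merged[col].isna().any():
            key = merged.loc[merged[col].isna(), keys].iloc[0].to_dict()
            raise ValueError(f"no {source} row for trial {key}")

    excluded = 0
    if "incomplete" in merged:
        mask = merged.pop("incomplete").astype(bool)
        excluded = int(mask.sum())
        if drop_incomplete and excluded:
            merged = merged.loc[~mask].reset_index(drop=True)
    merged = add_syncopation_dummies(merged)
    merged.attrs["excluded_incomplete_trials"] = excluded
    return merged
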