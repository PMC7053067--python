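"""PDQ-39 scoring: item responses -> eight 0-100 subscale indices + summary index.

The PDQ-39 is the Parkinson's-disease-specific quality-of-life questionnaire:
39 items answered on a five-point frequency scale ("never" .. "always",
coded 0..4), grouped into eight subscales.  Each subscale is scored as

    index = 100 * (sum of answered item values) / (4 * number answered)

so 0 is the best and 100 the worst possible health-related quality of life.
The summary index (SI) is the arithmetic mean of the eight subscale indices.

A subscale is scorable when at least half of its items are answered (the
published scoring-manual convention); otherwise the subscale -- and hence the
summary index -- is missing for that questionnaire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical subscale names in instrument order, with item counts.
SUBSCALE_ITEMS: dict[str, int] = {
    "mobility": 10,
    "activities_of_daily_living": 6,
    "emotional_wellbeing": 6,
    "stigma": 4,
    "social_support": 3,
    "cognitions": 4,
    "communication": 3,
    "bodily_discomfort": 3,
}

SUBSCALE_NAMES: tuple[str, ...] = tuple(SUBSCALE_ITEMS)

#: Default item->subscale assignment using the published PDQ-39 ordering:
#: items 1-10 mobility, 11-16 ADL, 17-22 emotional well-being, 23-26 stigma,
#: 27-29 social support, 30-33 cognitions, 34-36 communication,
#: 37-39 bodily discomfort.  Keys are 1-based item numbers.
DEFAULT_ITEM_MAP: dict[int, str] = {}
_next = 1
for _name, _count in SUBSCALE_ITEMS.items():
    for _ in range(_count):
        DEFAULT_ITEM_MAP[_next] = _name
        _next += 1
del _name, _count, _next

assert len(DEFAULT_ITEM_MAP) == 39


class UnscorableSubscaleError(ValueError):
    """Fewer than half of a subscale's items were answered."""


@dataclass(frozen=True)
class SubscaleProfile:
    """Eight PDQ-39 subscale indices for one subject-visit.

    ``indices`` maps canonical subscale names to values in [0, 100];
    a subscale that could not be scored is absent.  The summary index is
    defined only when all eight subscales are present.
    """

    indices: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.indices.items():
            if name not in SUBSCALE_ITEMS:
                raise ValueError(f"unknown subscale {name!r}")
            if not (0.0 <= value <= 100.0):
                raise ValueError(f"subscale {name!r} index {value} outside [0, 100]")

    @property
    def complete(self) -> bool:
        return len(self.indices) == len(SUBSCALE_ITEMS)

    @property
    def summary_index(self) -> float | None:
        """Mean of the eight subscale indices; None if any is missing."""
        if not self.complete:
            return None
        return float(np.mean([self.indices[s] for s in SUBSCALE_NAMES]))

    def __getitem__(self, name: str) -> float:
        return self.indices[name]


def score_subscale(items) -> float:
    """Score one subscale from its item values.

    Parameters
    ----------
    items
        Sequence of item values for a single subscale; each entry is an
        integer 0..4 or missing (None / NaN).

    Returns
    -------
    float
        The 0-100 subscale index over the answered items.

    Raises
    ------
    UnscorableSubscaleError
        If fewer than half of the items are answered.
    ValueError
        If any answered value is not an integer in {0, 1, 2, 3, 4}.
    """
    values = np.asarray(items, dtype=float)
    present = ~np.isnan(values)
    answered = values[present]
    if np.any((answered < 0) | (answered > 4) | (answered != np.round(answered))):
        raise ValueError("item responses must be integers in 0..4")
    if answered.size * 2 < values.size:
        raise UnscorableSubscaleError(
            f"only {answered.size}/{values.size} items answered"
        )
    return float(100.0 * answered.sum() / (4.0 * answered.size))


def score_profile(responses, item_map: dict[int, str] | None = None) -> SubscaleProfile:
    """Score a full 39-item questionnaire into a :class:`SubscaleProfile`.

    Parameters
    ----------
    responses
        Mapping of 1-based item number -> value (0..4 or None/NaN), or a
        sequence of 39 values in item order.
    item_map
        Item -> subscale assignment; defaults to the published ordering.

    Unscorable subscales are omitted from the returned profile, which is
    then flagged incomplete (``profile.complete`` is False).
    """
    item_map = item_map or DEFAULT_ITEM_MAP
    if not isinstance(responses, dict):
        seq = list(responses)
        if len(seq) != 39:
            raise ValueError(f"expected 39 item values, got {len(seq)}")
        responses = {i + 1: v for i, v in enumerate(seq)}
    groups: dict[str, list] = {name: [] for name in SUBSCALE_ITEMS}
    for item, subscale in item_map.items():
        v = responses.get(item)
        groups[subscale].append(np.nan if v is None else v)
    for name, expected in SUBSCALE_ITEMS.items():
        if len(groups[name]) != expected:
            raise ValueError(
                f"item map assigns {len(groups[name])} items to {name!r}, "
                f"expected {expected}"
            )
    indices: dict[str, float] = {}
    for name, vals in groups.items():
        try:
            indices[name] = score_subscale(vals)
        except UnscorableSubscaleError:
            continue
    return SubscaleProfile(indices)


def score_items_table(
    items: pd.DataFrame, item_columns: dict[int, str] | None = None
) -> pd.DataFrame:
    """Score a table of item-level responses, one questionnaire per row.

    ``item_columns`` maps 1-based item numbers to column names; by default
    columns ``item_1`` .. ``item_39`` are expected.  Returns a DataFrame with
    the eight canonical subscale columns plus ``summary_index`` (NaN where a
    subscale was unscorable), indexed like the input.
    """
    if item_columns is None:
        item_columns = {i: f"item_{i}" for i in range(1, 40)}
    missing = [c for c in item_columns.values() if c not in items.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing}")
    out = pd.DataFrame(index=items.index, columns=list(SUBSCALE_NAMES), dtype=float)
    for subscale in SUBSCALE_NAMES:
        cols = [
            item_columns[i] for i, s in DEFAULT_ITEM_MAP.items() if s == subscale
        ]
        vals = items[cols].to_numpy(dtype=float)
        answered = ~np.isnan(vals)
        n_ans = answered.sum(axis=1)
        scorable = 2 * n_ans >= vals.shape[1]
        sums = np.nansum(vals, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = 100.0 * sums / (4.0 * n_ans)
        out[subscale] = np.where(scorable, idx, np.nan)
    out["summary_index"] = out[list(SUBSCALE_NAMES)].mean(axis=1, skipna=False)
    return out
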