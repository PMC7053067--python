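"""EQ-5D-3L value sets: convert a five-dimension state into a utility.

A value set (tariff) assigns each EQ-5D-3L state a societal preference
weight anchored at 1.0 (full health, state 11111) and 0.0 (death); states
worse than death take negative values.  The additive form used here follows
the standard time-trade-off tariff structure:

    u = 1.0
        - any_dysfunction   (once, if any dimension is above level 1)
        - sum of per-dimension decrements for levels 2/3
        - extreme           (once, if any dimension is at level 3)

Value sets without an any-dysfunction or extreme-level term simply set the
constant to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .mapping import EQ5D_DIMENSIONS


class ValueSetValidationError(ValueError):
    """Value-set file violates the schema or monotone-dominance structure."""


class InvalidStateError(ValueError):
    """An EQ-5D level outside {1, 2, 3}."""


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-3L tariff.

    ``decrements`` maps dimension name -> (level-2 decrement, level-3
    decrement); all decrements are >= 0 and the level-3 decrement is at
    least the level-2 decrement, so the tariff is monotone in each
    dimension (more severe never values higher).
    """

    country: str
    any_dysfunction: float
    decrements: dict[str, tuple[float, float]]
    extreme: float = 0.0
    full_health: float = 1.0

    def __post_init__(self) -> None:
        if self.full_health != 1.0:
            raise ValueSetValidationError("full-health constant must be 1.0")
        if set(self.decrements) != set(EQ5D_DIMENSIONS):
            raise ValueSetValidationError(
                f"decrements must cover exactly {list(EQ5D_DIMENSIONS)}"
            )
        if self.any_dysfunction < 0 or self.extreme < 0:
            raise ValueSetValidationError("constants must be >= 0")
        for dim, (d2, d3) in self.decrements.items():
            if d2 < 0 or d3 < 0:
                raise ValueSetValidationError(f"{dim}: negative decrement")
            if d3 < d2:
                raise ValueSetValidationError(
                    f"{dim}: level-3 decrement ({d3}) below level-2 ({d2})"
                )


def load_value_set(path: str | Path) -> ValueSet:
    """Load and validate a value-set file (YAML)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueSetValidationError(f"{path}: top level must be a mapping")
    try:
        dec_block = doc["decrements"]
        decs = {
            dim: (float(block["level2"]), float(block["level3"]))
            for dim, block in dec_block.items()
        }
        return ValueSet(
            country=str(doc["country"]),
            any_dysfunction=float(doc.get("any_dysfunction", 0.0)),
            decrements=decs,
            extreme=float(doc.get("extreme", 0.0)),
            full_health=float(doc.get("full_health", 1.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ValueSetValidationError(f"{path}: malformed value set ({exc})") from None


def utility(state, vs: ValueSet) -> float:
    """Utility of one EQ-5D-3L state (5-tuple of levels in {1,2,3})."""
    state = tuple(int(lv) for lv in state)
    if len(state) != 5 or any(lv not in (1, 2, 3) for lv in state):
        raise InvalidStateError(f"invalid EQ-5D-3L state {state}")
    u = vs.full_health
    if any(lv > 1 for lv in state):
        u -= vs.any_dysfunction
    for dim, lv in zip(EQ5D_DIMENSIONS, state):
        if lv > 1:
            u -= vs.decrements[dim][lv - 2]
    if any(lv == 3 for lv in state):
        u -= vs.extreme
    return u


def utilities_for_levels(levels: pd.DataFrame, vs: ValueSet) -> pd.Series:
    """Vectorized utilities from a table of ``level_<dim>`` columns.

    Rows with any NaN level yield NaN (unmapped records stay unmapped).
    """
    cols = [f"level_{d}" for d in EQ5D_DIMENSIONS]
    lv = levels[cols].to_numpy(dtype=float)
    u = pd.Series(vs.full_health, index=levels.index, dtype=float)
    any_dys = (lv > 1).any(axis=1)
    u -= vs.any_dysfunction * any_dys
    for j, dim in enumerate(EQ5D_DIMENSIONS):
        d2, d3 = vs.decrements[dim]
        u -= d2 * (lv[:, j] == 2) + d3 * (lv[:, j] == 3)
    u -= vs.extreme * (lv == 3).any(axis=1)
    u[pd.isna(lv).any(axis=1)] = float("nan")
    return u


def tabulate_all_states(vs: ValueSet) -> pd.DataFrame:
    """Exhaustive 243-row table of state -> utility, sorted canonically."""
    rows = []
    for state in itertools.product((1, 2, 3), repeat=5):
        rows.append(
            {"state": "".join(map(str, state)), "utility": utility(state, vs)}
            | dict(zip(EQ5D_DIMENSIONS, state))
        )
    return pd.DataFrame(rows)
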