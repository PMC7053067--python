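"""End-to-end orchestration: score -> map -> value -> analyse.

The pipeline consumes a tidy subject x visit table (item-level responses or
precomputed subscale indices), predicts EQ-5D-3L states under one or both
mapping families, converts states to utilities under one or more country
value sets, and runs the longitudinal trial analysis on each resulting
utility panel.  Every (family x value set) combination yields one utility
panel and one statistics bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import stats as tstats
from .mapping import EQ5D_DIMENSIONS, MappingModel, load_mapping_model, predict_table
from .scoring import SUBSCALE_NAMES, score_items_table
from .tariff import ValueSet, load_value_set, utilities_for_levels

log = logging.getLogger("pdqmap")

FAMILIES = ("ordinal", "multinomial")


class ConfigError(ValueError):
    """Run configuration is invalid."""


def _data_path(*parts: str) -> Path:
    return Path(resources.files("pdqmap").joinpath("data", *parts))


def demo_coefficients(family: str) -> MappingModel:
    """The packaged synthetic demonstration coefficient set for a family."""
    if family not in FAMILIES:
        raise ConfigError(f"unknown family {family!r}")
    return load_mapping_model(_data_path("coefficients", f"{family}_demo.yaml"))


def demo_value_set(which: str = "uk") -> ValueSet:
    """A packaged synthetic demonstration value set ('uk' or 'fr')."""
    return load_value_set(_data_path("valuesets", f"{which}_demo.yaml"))


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    data: str
    outdir: str = "pdqmap_out"
    granularity: str = "subscales"  # "items" | "subscales"
    family: str = "both"  # "ordinal" | "multinomial" | "both"
    coefficients: dict[str, str] = field(default_factory=dict)  # family -> path
    valuesets: list[str] = field(default_factory=list)
    column_map: dict[str, str] = field(default_factory=dict)
    family_alpha: float = 0.05
    welch: bool = False
    min_stratum_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.granularity not in ("items", "subscales"):
            raise ConfigError(f"granularity must be items|subscales")
        if self.family not in FAMILIES + ("both",):
            raise ConfigError(f"family must be ordinal|multinomial|both")
        if not 0 < self.family_alpha < 1:
            raise ConfigError("family_alpha must be in (0, 1)")

    @property
    def families(self) -> tuple[str, ...]:
        return FAMILIES if self.family == "both" else (self.family,)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def load_models(config: RunConfig) -> dict[str, MappingModel]:
    models = {}
    for fam in config.families:
        path = config.coefficients.get(fam)
        models[fam] = load_mapping_model(path) if path else demo_coefficients(fam)
    return models


def load_valuesets(config: RunConfig) -> list[ValueSet]:
    if config.valuesets:
        return [load_value_set(p) for p in config.valuesets]
    return [demo_value_set("uk")]


def prepare_dataset(config: RunConfig) -> pd.DataFrame:
    """Read the input table and reduce it to subscale granularity."""
    df = pd.read_csv(config.data, sep=None, engine="python")
    if config.column_map:
        df = df.rename(columns=config.column_map)
    required = ["subject_id", "arm", "visit_month"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"input data lacks required columns: {missing}")
    if config.granularity == "items":
        scored = score_items_table(df)
        df = pd.concat([df.drop(columns=list(SUBSCALE_NAMES), errors="ignore"),
                        scored], axis=1)
    else:
        missing = [s for s in SUBSCALE_NAMES if s not in df.columns]
        if missing:
            raise ConfigError(f"input data lacks subscale columns: {missing}")
    return df


def _encode_gender(df: pd.DataFrame, model: MappingModel) -> pd.DataFrame:
    if "gender" in df.columns and df["gender"].dtype == object:
        df = df.copy()
        df["gender"] = df["gender"].map(model.gender_coding)
    return df


def map_and_value(
    data: pd.DataFrame, model: MappingModel, vs: ValueSet
) -> pd.DataFrame:
    """Predict states for each record and attach the tariff utility."""
    if model.family == "multinomial":
        for col in ("age", "gender"):
            if col not in data.columns:
                raise ConfigError(
                    f"multinomial family requires a {col!r} column in the data"
                )
        data = _encode_gender(data, model)
    mapped = predict_table(model, data)
    mapped["utility"] = utilities_for_levels(mapped, vs)
    return mapped


def analyse_panel(
    panel: pd.DataFrame,
    family_alpha: float = 0.05,
    welch: bool = False,
    min_stratum_n: int = 10,
) -> dict[str, pd.DataFrame]:
    """Run the full statistics battery on one utility panel.

    ``panel`` needs subject_id, arm, visit_month, utility (plus hy_stage for
    the severity stratification).  Returns tidy tables: exclusions, within,
    between, anova, responsiveness, strata.
    """
    visits = sorted(panel["visit_month"].unique())
    n_tests = len(visits) - 1
    filtered, exclusions = tstats.complete_cases(panel, visits)
    changes = tstats.change_from_baseline(filtered)

    within_rows, between_rows = [], []
    for visit, dv in changes.groupby("visit_month"):
        for arm_label, g in dv.groupby("arm"):
            r = tstats.within_group_test(
                g["change"], visit=visit, family_alpha=family_alpha, n_tests=n_tests
            )
            within_rows.append({"arm": arm_label} | dataclasses.asdict(r))
        r = tstats.between_group_test(
            dv.loc[dv["arm"] == "A", "change"],
            dv.loc[dv["arm"] == "B", "change"],
            visit=visit,
            family_alpha=family_alpha,
            n_tests=n_tests,
            welch=welch,
        )
        between_rows.append(dataclasses.asdict(r))

    anova = tstats.repeated_measures_anova(filtered)
    resp = tstats.responsiveness_table(changes)
    if "hy_stage" in panel.columns:
        strata = tstats.strata_table(
            tstats.hy_strata(filtered, min_n=min_stratum_n)
        )
    else:
        strata = pd.DataFrame()
    return {
        "exclusions": exclusions,
        "within": pd.DataFrame(within_rows),
        "between": pd.DataFrame(between_rows),
        "anova": anova,
        "responsiveness": resp,
        "strata": strata,
    }


def run(config: RunConfig) -> dict[str, dict[str, pd.DataFrame]]:
    """Execute the full pipeline and write one artifact set per combination.

    Returns ``{"<family>_<country>": {table name: DataFrame}}`` and writes
    every table as tab-delimited text under ``config.outdir``, together with
    a machine-readable run summary.  All results are computed before
    anything is written, so a failing run emits no partial result tables.
    """
    data = prepare_dataset(config)
    models = load_models(config)
    valuesets = load_valuesets(config)

    results: dict[str, dict[str, pd.DataFrame]] = {}
    for fam, model in models.items():
        for vs in valuesets:
            key = f"{fam}_{vs.country}"
            log.info("mapping family=%s value_set=%s", fam, vs.country)
            mapped = map_and_value(data, model, vs)
            bundle = analyse_panel(
                mapped,
                family_alpha=config.family_alpha,
                welch=config.welch,
                min_stratum_n=config.min_stratum_n,
            )
            bundle["panel"] = mapped
            results[key] = bundle

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "families": list(models),
        "valuesets": [vs.country for vs in valuesets],
        "n_records": int(len(data)),
        "combinations": list(results),
    }
    for key, bundle in results.items():
        for name, table in bundle.items():
            table.to_csv(outdir / f"{key}_{name}.tsv", sep="\t", index=False)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("wrote %d artifact sets to %s", len(results), outdir)
    return results
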