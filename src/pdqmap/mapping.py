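"""Response mapping: predict EQ-5D-3L dimension levels from PDQ-39 subscales.

Two pre-estimated model families are supported, consumed as coefficient
files (the regressions are never re-fit here):

* **Ordinal (Cauchit link).**  Per dimension, cut-points ``alpha1 < alpha2``
  and a slope vector ``beta`` over a declared subset of the eight subscale
  indices.  With linear predictor eta = beta'X, the cumulative inverse-Cauchy
  link gives

      p1 = 0.5 - atan(-alpha1 + eta) / pi          ("no problems")
      c2 = 0.5 - atan(-alpha2 + eta) / pi
      p2 = c2 - p1                                  ("some problems")
      p3 = 1 - c2                                   ("extreme problems")

* **Multinomial logit.**  Per dimension, linear scores s1 = 0 (level 1 is
  the pivot outcome), s2 = beta2'x, s3 = beta3'x where x holds the eight
  subscale indices, age in years, a gender indicator and an intercept; the
  level probabilities are softmax(s1, s2, s3).

The predicted level is the one with the largest probability; exact ties
break toward the lower (less severe) level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scoring import SUBSCALE_NAMES, SubscaleProfile

#: Canonical EQ-5D-3L dimension order.
EQ5D_DIMENSIONS: tuple[str, ...] = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

LEVELS = (1, 2, 3)

#: Covariates a multinomial coefficient block may declare, in canonical order.
MULTINOMIAL_COVARIATES: tuple[str, ...] = SUBSCALE_NAMES + ("age", "gender")


class ModelValidationError(ValueError):
    """Coefficient file violates the model-family schema."""


class UnmappedRecordError(ValueError):
    """A record lacks a covariate the mapping model requires."""


@dataclass(frozen=True)
class OrdinalDimensionModel:
    dimension: str
    alpha1: float
    alpha2: float
    beta: dict[str, float]

    def __post_init__(self) -> None:
        if not self.alpha1 < self.alpha2:
            raise ModelValidationError(
                f"{self.dimension}: alpha1 ({self.alpha1}) must be < alpha2 "
                f"({self.alpha2})"
            )
        unknown = set(self.beta) - set(SUBSCALE_NAMES)
        if unknown:
            raise ModelValidationError(
                f"{self.dimension}: unknown subscales in beta: {sorted(unknown)}"
            )


@dataclass(frozen=True)
class MultinomialDimensionModel:
    """Coefficients for levels 2 and 3; level 1 is the pivot (all zero).

    Each level block maps covariate name -> coefficient and must contain an
    ``intercept`` entry; omitted covariates contribute zero.
    """

    dimension: str
    level2: dict[str, float]
    level3: dict[str, float]

    def __post_init__(self) -> None:
        for lvl, coefs in (("level2", self.level2), ("level3", self.level3)):
            if "intercept" not in coefs:
                raise ModelValidationError(
                    f"{self.dimension}/{lvl}: missing 'intercept'"
                )
            unknown = set(coefs) - set(MULTINOMIAL_COVARIATES) - {"intercept"}
            if unknown:
                raise ModelValidationError(
                    f"{self.dimension}/{lvl}: unknown covariates: {sorted(unknown)}"
                )


@dataclass(frozen=True)
class MappingModel:
    """A full five-dimension model of one family, as loaded from file."""

    family: str  # "ordinal" | "multinomial"
    dimensions: dict[str, OrdinalDimensionModel | MultinomialDimensionModel]
    gender_coding: dict[str, int] = field(
        default_factory=lambda: {"female": 1, "male": 0}
    )
    age_centering: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("ordinal", "multinomial"):
            raise ModelValidationError(f"unknown family {self.family!r}")
        missing = set(EQ5D_DIMENSIONS) - set(self.dimensions)
        if missing:
            raise ModelValidationError(f"missing dimension blocks: {sorted(missing)}")
        expected = (
            OrdinalDimensionModel if self.family == "ordinal"
            else MultinomialDimensionModel
        )
        for dim, model in self.dimensions.items():
            if not isinstance(model, expected):
                raise ModelValidationError(
                    f"{dim}: wrong model type for family {self.family!r}"
                )


def load_mapping_model(path: str | Path) -> MappingModel:
    """Load and schema-validate a coefficient file (YAML)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelValidationError(f"{path}: top level must be a mapping")
    try:
        family = doc["family"]
        dim_blocks = doc["dimensions"]
    except KeyError as exc:
        raise ModelValidationError(f"{path}: missing key {exc}") from None
    dims: dict[str, OrdinalDimensionModel | MultinomialDimensionModel] = {}
    for dim, block in dim_blocks.items():
        if dim not in EQ5D_DIMENSIONS:
            raise ModelValidationError(f"{path}: unknown dimension {dim!r}")
        if not isinstance(block, dict):
            raise ModelValidationError(f"{path}: dimension {dim!r} must be a mapping")
        try:
            if family == "ordinal":
                dims[dim] = OrdinalDimensionModel(
                    dimension=dim,
                    alpha1=float(block["alpha1"]),
                    alpha2=float(block["alpha2"]),
                    beta={k: float(v) for k, v in block.get("beta", {}).items()},
                )
            elif family == "multinomial":
                dims[dim] = MultinomialDimensionModel(
                    dimension=dim,
                    level2={k: float(v) for k, v in block["level2"].items()},
                    level3={k: float(v) for k, v in block["level3"].items()},
                )
            else:
                raise ModelValidationError(f"{path}: unknown family {family!r}")
        except KeyError as exc:
            raise ModelValidationError(
                f"{path}: dimension {dim!r} missing key {exc}"
            ) from None
    coding = doc.get("gender_coding", {"female": 1, "male": 0})
    if set(coding) != {"female", "male"} or set(coding.values()) != {0, 1}:
        raise ModelValidationError(
            f"{path}: gender_coding must assign 0 and 1 to 'female' and 'male'"
        )
    return MappingModel(
        family=family,
        dimensions=dims,
        gender_coding={k: int(v) for k, v in coding.items()},
        age_centering=float(doc.get("age_centering", 0.0)),
        label=str(doc.get("label", path.stem)),
    )


# ---------------------------------------------------------------------------
# probability computation


def ordinal_probs(model: OrdinalDimensionModel, profile: SubscaleProfile) -> np.ndarray:
    """Level probabilities (p1, p2, p3) under the cumulative Cauchit model."""
    try:
        eta = sum(b * profile[s] for s, b in model.beta.items())
    except KeyError as exc:
        raise UnmappedRecordError(
            f"{model.dimension}: profile lacks subscale {exc}"
        ) from None
    p1 = 0.5 - np.arctan(-model.alpha1 + eta) / np.pi
    c2 = 0.5 - np.arctan(-model.alpha2 + eta) / np.pi
    return np.array([p1, c2 - p1, 1.0 - c2])


def multinomial_probs(
    model: MultinomialDimensionModel,
    profile: SubscaleProfile,
    age: float,
    gender: int,
) -> np.ndarray:
    """Level probabilities via softmax over (0, beta2'x, beta3'x)."""
    if age is None or gender is None or (isinstance(age, float) and np.isnan(age)):
        raise UnmappedRecordError(f"{model.dimension}: age/gender required")

    def score(coefs: dict[str, float]) -> float:
        s = coefs["intercept"]
        for cov, b in coefs.items():
            if cov == "intercept":
                continue
            if cov == "age":
                s += b * age
            elif cov == "gender":
                s += b * gender
            else:
                try:
                    s += b * profile[cov]
                except KeyError:
                    raise UnmappedRecordError(
                        f"{model.dimension}: profile lacks subscale {cov!r}"
                    ) from None
        return s

    return _softmax3(0.0, score(model.level2), score(model.level3))


def _softmax3(s1, s2, s3) -> np.ndarray:
    s = np.array([s1, s2, s3], dtype=float)
    s -= s.max()  # overflow guard
    e = np.exp(s)
    return e / e.sum()


def assign_level(probs) -> int:
    """Maximum-probability level; exact ties go to the less severe level."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,):
        raise ValueError("expected a probability triple")
    return int(np.argmax(p)) + 1  # argmax returns the first (lowest) maximum


def predict_state(
    model: MappingModel,
    profile: SubscaleProfile,
    age: float | None = None,
    gender: int | None = None,
) -> tuple[tuple[int, ...], np.ndarray]:
    """Predict the five-dimension EQ-5D-3L state for one profile.

    Returns ``(state, probs)`` where ``state`` is the 5-tuple of assigned
    levels in canonical dimension order and ``probs`` the 5x3 probability
    table.  Any unmappable dimension fails the whole record.
    """
    probs = np.empty((5, 3))
    for i, dim in enumerate(EQ5D_DIMENSIONS):
        dm = model.dimensions[dim]
        if model.family == "ordinal":
            probs[i] = ordinal_probs(dm, profile)
        else:
            a = age if model.age_centering == 0.0 else age - model.age_centering
            probs[i] = multinomial_probs(dm, profile, a, gender)
    state = tuple(assign_level(probs[i]) for i in range(5))
    return state, probs


# ---------------------------------------------------------------------------
# vectorized table interface


def predict_table(model: MappingModel, data: pd.DataFrame) -> pd.DataFrame:
    """Predict states for every row of a subscale-level table.

    ``data`` must carry the eight canonical subscale columns (plus ``age``
    and ``gender`` — coded per the model's declaration — for the multinomial
    family).  Returns a copy of ``data`` with ``level_<dim>`` and
    ``p<k>_<dim>`` columns appended.  Rows with any required covariate
    missing get NaN levels (whole-record semantics: one missing dimension
    voids all five).
    """
    n = len(data)
    out = data.copy()
    levels = np.zeros((n, 5))
    probs = np.zeros((n, 5, 3))
    valid = np.ones(n, dtype=bool)

    sub = {}
    for s in SUBSCALE_NAMES:
        if s in data.columns:
            sub[s] = data[s].to_numpy(dtype=float)

    if model.family == "multinomial":
        for col in ("age", "gender"):
            if col not in data.columns:
                raise UnmappedRecordError(f"multinomial family requires {col!r} column")
        age = data["age"].to_numpy(dtype=float) - model.age_centering
        gender = data["gender"].to_numpy(dtype=float)
        valid &= ~(np.isnan(age) | np.isnan(gender))

    for i, dim in enumerate(EQ5D_DIMENSIONS):
        dm = model.dimensions[dim]
        if model.family == "ordinal":
            eta = np.zeros(n)
            for s, b in dm.beta.items():
                if s not in sub:
                    raise UnmappedRecordError(f"{dim}: missing subscale column {s!r}")
                eta = eta + b * sub[s]
            p1 = 0.5 - np.arctan(-dm.alpha1 + eta) / np.pi
            c2 = 0.5 - np.arctan(-dm.alpha2 + eta) / np.pi
            probs[:, i, 0] = p1
            probs[:, i, 1] = c2 - p1
            probs[:, i, 2] = 1.0 - c2
        else:
            scores = np.zeros((n, 3))
            for j, coefs in ((1, dm.level2), (2, dm.level3)):
                s = np.full(n, coefs["intercept"])
                for cov, b in coefs.items():
                    if cov == "intercept":
                        continue
                    if cov == "age":
                        s = s + b * age
                    elif cov == "gender":
                        s = s + b * gender
                    else:
                        if cov not in sub:
                            raise UnmappedRecordError(
                                f"{dim}: missing subscale column {cov!r}"
                            )
                        s = s + b * sub[cov]
                scores[:, j] = s
            scores -= scores.max(axis=1, keepdims=True)
            e = np.exp(scores)
            probs[:, i, :] = e / e.sum(axis=1, keepdims=True)
        valid &= ~np.isnan(probs[:, i, :]).any(axis=1)
        levels[:, i] = np.argmax(probs[:, i, :], axis=1) + 1

    for i, dim in enumerate(EQ5D_DIMENSIONS):
        out[f"level_{dim}"] = np.where(valid, levels[:, i], np.nan)
        for k in range(3):
            out[f"p{k + 1}_{dim}"] = np.where(valid, probs[:, i, k], np.nan)
    return out
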