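"""Synthetic two-arm longitudinal PDQ-39 trial data with known ground truth.

Emulates the structure of an early-Parkinson's randomized trial comparing
deep-brain stimulation plus medication (arm A) against best medical therapy
alone (arm B): ~125 subjects per arm, visits at baseline and 5/12/24
months, mean age 52, Hoehn & Yahr stage <= 2.5 at baseline, a between-arm
summary-index treatment effect of about 8 PDQ-39 points, and a few percent
of subjects with an incomplete visit schedule.

Generative model (per subject i in arm g, visit t):

    L_it = mu + b_i + effect_g(t) + e_it
    b_i  ~ N(0, rho * sd^2)          subject random intercept
    e_it ~ N(0, (1 - rho) * sd^2)    visit-level noise

where ``mu`` is the baseline summary-index mean, ``sd`` its SD and ``rho``
the within-subject correlation.  Arm A's latent index drops by the full
``arm_effect_si`` at every follow-up visit (lower PDQ-39 = better); arm B
is flat in expectation.  The eight observed subscales are the latent index
plus independent N(0, subscale_spread_sd) perturbations, clipped to
[0, 100].  Clipping is a (small, documented) bias source; designs whose
clipping would absorb more than half the intended effect are rejected.

Missingness is at the subject level: an ``incomplete`` subject has the
subscales of one randomly chosen follow-up visit withheld, matching
complete-case analysis semantics downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .mapping import EQ5D_DIMENSIONS, MappingModel, predict_table
from .scoring import SUBSCALE_NAMES

HY_STAGES = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)


class DesignError(ValueError):
    """Trial design is invalid or produces an unusable scenario."""


@dataclass(frozen=True)
class TrialDesign:
    """Parameters of the synthetic trial generator.

    Defaults describe the early-PD two-arm scenario above.  ``arm_effect_si``
    is the between-arm difference in summary-index change from baseline at
    the final visit, in PDQ-39 points, with positive values meaning arm A
    improves more (its index falls further).
    """

    n_arm_a: int = 124
    n_arm_b: int = 127
    visits: tuple[float, ...] = (0, 5, 12, 24)
    baseline_si_mean: float = 32.0
    baseline_si_sd: float = 12.0
    arm_effect_si: float = 8.0
    within_subject_corr: float = 0.7
    subscale_spread_sd: float = 10.0
    age_mean: float = 52.0
    age_sd: float = 6.0
    prop_female: float = 0.35
    hy_probs: dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 1.0: 0.10, 1.5: 0.15, 2.0: 0.50, 2.5: 0.25}
    )
    missing_case_rate: float = 9 / 251
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_arm_a < 0 or self.n_arm_b < 0 or self.n_arm_a + self.n_arm_b == 0:
            raise DesignError("need at least one subject across arms")
        if self.baseline_si_sd <= 0 or self.subscale_spread_sd <= 0 or self.age_sd <= 0:
            raise DesignError("all SDs must be > 0")
        if not 0 <= self.within_subject_corr < 1:
            raise DesignError("within_subject_corr must be in [0, 1)")
        for name in ("prop_female", "missing_case_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DesignError(f"{name} must be in [0, 1]")
        visits = tuple(self.visits)
        if len(visits) < 1 or visits[0] != 0:
            raise DesignError("first visit must be baseline (month 0)")
        if any(b <= a for a, b in zip(visits, visits[1:])):
            raise DesignError("visits must be strictly increasing")
        object.__setattr__(self, "visits", visits)
        unknown = set(self.hy_probs) - set(HY_STAGES)
        if unknown:
            raise DesignError(f"unknown H&Y stages: {sorted(unknown)}")
        if any(p < 0 for p in self.hy_probs.values()):
            raise DesignError("hy_probs must be non-negative")
        if abs(sum(self.hy_probs.values()) - 1.0) > 1e-9:
            raise DesignError("hy_probs must sum to 1")
        _check_truncation(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "visits" in doc:
            doc["visits"] = tuple(doc["visits"])
        if "hy_probs" in doc:
            doc["hy_probs"] = {float(k): float(v) for k, v in doc["hy_probs"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise DesignError(f"{path}: unknown design keys: {sorted(unknown)}")
        return cls(**doc)


def _clipped_mean(mu: float, sigma: float, lo: float = 0.0, hi: float = 100.0) -> float:
    """E[clip(X, lo, hi)] for X ~ N(mu, sigma); closed form."""
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    return (
        mu * (norm.cdf(b) - norm.cdf(a))
        + sigma * (norm.pdf(a) - norm.pdf(b))
        + lo * norm.cdf(a)
        + hi * norm.sf(b)
    )


def _check_truncation(design: TrialDesign) -> None:
    """Reject designs where [0,100] clipping eats > half the intended effect."""
    effect = design.arm_effect_si
    if effect == 0:
        return
    sigma = float(
        np.hypot(design.baseline_si_sd, design.subscale_spread_sd)
    )  # per-subscale SD around the arm mean
    mu = design.baseline_si_mean
    realized = _clipped_mean(mu, sigma) - _clipped_mean(mu - effect, sigma)
    if abs(realized) < abs(effect) / 2:
        raise DesignError(
            f"clipping to [0, 100] absorbs more than half the intended effect "
            f"(realized {realized:.2f} of {effect:.2f} points); move "
            f"baseline_si_mean away from the scale boundary"
        )


def generate_trial(design: TrialDesign) -> pd.DataFrame:
    """Generate one synthetic trial as a tidy subject x visit table.

    Columns: subject_id, arm, visit_month, age, gender, hy_stage, complete,
    and the eight canonical subscale columns (NaN on withheld visits of
    incomplete subjects).  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_arm_a + design.n_arm_b
    visits = np.asarray(design.visits, dtype=float)
    n_vis = len(visits)

    arm = np.array(["A"] * design.n_arm_a + ["B"] * design.n_arm_b)
    age = rng.normal(design.age_mean, design.age_sd, n)
    gender = np.where(rng.random(n) < design.prop_female, "female", "male")
    stages = np.array(sorted(design.hy_probs))
    hy = rng.choice(stages, size=n, p=[design.hy_probs[s] for s in stages])

    sd2 = design.baseline_si_sd**2
    sigma_b = np.sqrt(design.within_subject_corr * sd2)
    sigma_e = np.sqrt((1 - design.within_subject_corr) * sd2)
    intercept = design.baseline_si_mean + rng.normal(0.0, sigma_b, n)

    # full treatment effect at every follow-up visit; arm B flat in expectation
    effect = np.zeros((n, n_vis))
    effect[arm == "A", 1:] = -design.arm_effect_si
    latent = intercept[:, None] + effect + rng.normal(0.0, sigma_e, (n, n_vis))

    subscales = np.clip(
        latent[:, :, None]
        + rng.normal(0.0, design.subscale_spread_sd, (n, n_vis, len(SUBSCALE_NAMES))),
        0.0,
        100.0,
    )

    incomplete = rng.random(n) < design.missing_case_rate
    withheld_visit = np.full(n, -1)
    if n_vis > 1:
        withheld_visit[incomplete] = rng.integers(1, n_vis, incomplete.sum())

    rows = {
        "subject_id": np.repeat([f"S{i + 1:04d}" for i in range(n)], n_vis),
        "arm": np.repeat(arm, n_vis),
        "visit_month": np.tile(visits, n),
        "age": np.repeat(np.round(age, 1), n_vis),
        "gender": np.repeat(gender, n_vis),
        "hy_stage": np.repeat(hy, n_vis),
        "complete": np.repeat(~incomplete, n_vis),
    }
    df = pd.DataFrame(rows)
    sub = subscales.reshape(n * n_vis, len(SUBSCALE_NAMES))
    mask = np.zeros(n * n_vis, dtype=bool)
    for i in np.nonzero(incomplete)[0]:
        mask[i * n_vis + withheld_visit[i]] = True
    sub[mask] = np.nan
    for k, name in enumerate(SUBSCALE_NAMES):
        df[name] = sub[:, k]
    return df


def summary_index(df: pd.DataFrame) -> pd.Series:
    """PDQ-39 summary index per row: mean of the eight subscales (NaN-strict)."""
    return df[list(SUBSCALE_NAMES)].mean(axis=1, skipna=False)


def generate_true_states(
    records: pd.DataFrame, model: MappingModel, seed: int
) -> pd.DataFrame:
    """Draw a ground-truth EQ-5D-3L level per dimension for each record.

    Levels are sampled from the mapping model's predicted probabilities
    (not the argmax), giving a probabilistic truth against which the
    deterministic argmax predictor can be scored.  Adds ``true_<dim>``
    columns; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pred = predict_table(model, records)
    out = records.copy()
    u = rng.random((len(records), len(EQ5D_DIMENSIONS)))
    for i, dim in enumerate(EQ5D_DIMENSIONS):
        p = pred[[f"p1_{dim}", f"p2_{dim}", f"p3_{dim}"]].to_numpy(dtype=float)
        cum = np.cumsum(p, axis=1)
        lvl = 1 + (u[:, i : i + 1] > cum[:, :2]).sum(axis=1).astype(float)
        lvl[np.isnan(p).any(axis=1)] = np.nan
        out[f"true_{dim}"] = lvl
    return out


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write the subject-level table as tab-delimited text with a header."""
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a subject-level table, renaming columns via ``column_map``
    (file column -> canonical name) if given."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    return df
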