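"""Longitudinal two-arm trial statistics on mapped utilities.

Implements the analysis battery for a change-from-baseline trial readout:
complete-case filtering, within-group one-sample t-tests on change scores
(equivalent to a paired t of visit vs baseline), between-group two-sample
Student's t-tests (pooled variance by default, Welch on request),
two-way mixed repeated-measures ANOVA (between: arm, within: visit),
Bonferroni adjustment over the follow-up visits, responsiveness statistics
(effect size = mean change / SD of baselines; standardized response mean =
mean change / SD of changes), and Tukey boxplot summaries stratified by
Hoehn & Yahr stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Too few observations or zero variance where a test needs spread."""


def _is_zero_spread(x: np.ndarray) -> bool:
    """SD indistinguishable from zero at floating precision for this scale."""
    scale = max(1.0, float(np.abs(x).max(initial=0.0)))
    return float(np.std(x, ddof=1)) <= 1e-12 * scale


@dataclass(frozen=True)
class ComparisonResult:
    """One t-test: estimate, inference and multiplicity-adjusted quantities.

    ``estimate`` is the mean change (within-group) or the difference in mean
    change, arm A minus arm B (between-group), in utility units.  The
    confidence interval is at the Bonferroni-adjusted level
    1 - family_alpha / k.
    """

    visit: float
    estimate: float
    se: float
    t: float
    df: float
    p: float
    n: int
    adjusted_threshold: float
    adjusted_p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.adjusted_threshold


@dataclass(frozen=True)
class ResponsivenessResult:
    group: str
    visit: float
    n: int
    mean_change: float
    es: float | None  # undefined when baseline SD is zero
    srm: float | None  # undefined when change-score SD is zero


@dataclass(frozen=True)
class StrataSummary:
    """Tukey boxplot statistics for one H&Y stage."""

    stage: float
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()
    low_reliability: bool = False


# ---------------------------------------------------------------------------
# panel handling


def complete_cases(
    panel: pd.DataFrame,
    visits,
    value_col: str = "utility",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain subjects observed at every scheduled visit.

    A *case* is a subject: anyone missing ``value_col`` at any visit in
    ``visits`` (or missing the row entirely) is dropped at all visits.
    Returns the filtered panel and a per-arm exclusion report with counts
    and percentages (rounded to the nearest integer, as conventionally
    reported).
    """
    visits = list(visits)
    wide = panel.pivot_table(
        index="subject_id", columns="visit_month", values=value_col, dropna=False
    )
    for v in visits:
        if v not in wide.columns:
            wide[v] = np.nan
    ok = wide[visits].notna().all(axis=1)
    arms = panel.drop_duplicates("subject_id").set_index("subject_id")["arm"]
    rows = []
    for arm_label, arm_subjects in arms.groupby(arms):
        ids = arm_subjects.index
        n = len(ids)
        excluded = [s for s in ids if not ok.get(s, False)]
        rows.append(
            {
                "arm": arm_label,
                "n": n,
                "excluded": len(excluded),
                "retained": n - len(excluded),
                "percent_excluded": int(round(100.0 * len(excluded) / n)) if n else 0,
                "excluded_subjects": ",".join(map(str, excluded)),
            }
        )
    report = pd.DataFrame(rows)
    keep = set(ok.index[ok])
    filtered = panel[panel["subject_id"].isin(keep)].copy()
    if filtered.empty:
        raise DegenerateDataError("no complete cases remain after filtering")
    return filtered, report


def change_from_baseline(
    panel: pd.DataFrame, value_col: str = "utility"
) -> pd.DataFrame:
    """Per-subject change scores at each follow-up visit.

    change = value(visit) - value(baseline); positive change means
    improvement on the utility scale.  Expects complete cases.
    """
    wide = panel.pivot_table(
        index=["subject_id", "arm"], columns="visit_month", values=value_col
    )
    visits = sorted(wide.columns)
    baseline = visits[0]
    out = []
    for v in visits[1:]:
        chg = (wide[v] - wide[baseline]).reset_index()
        chg.columns = ["subject_id", "arm", "change"]
        chg["visit_month"] = v
        chg["baseline"] = wide[baseline].to_numpy()
        out.append(chg)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# t-tests


def bonferroni(p_values, family_alpha: float = 0.05, k: int | None = None):
    """Bonferroni correction: per-test threshold and adjusted p-values.

    ``k`` defaults to the number of p-values (the number of follow-up
    visits).  Returns ``(threshold, adjusted)`` with threshold =
    family_alpha / k and adjusted p = min(1, k * p).
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if k is None:
        k = p.size
    if k <= 0:
        raise ValueError("number of tests k must be >= 1")
    threshold = family_alpha / k
    adjusted = np.minimum(1.0, k * p)
    return threshold, adjusted


def _t_inference(
    estimate: float,
    se: float,
    df: float,
    visit: float,
    n: int,
    family_alpha: float,
    n_tests: int,
) -> ComparisonResult:
    threshold = family_alpha / n_tests
    if se == 0.0:
        # exact verdict for a degenerate (zero-variance) sample
        p = 1.0 if estimate == 0.0 else 0.0
        t = 0.0 if estimate == 0.0 else math.copysign(math.inf, estimate)
        return ComparisonResult(
            visit=visit, estimate=estimate, se=0.0, t=t, df=df, p=p, n=n,
            adjusted_threshold=threshold, adjusted_p=min(1.0, n_tests * p),
            ci_low=estimate, ci_high=estimate, degenerate=True,
        )
    t = estimate / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(1.0 - threshold / 2.0, df)
    return ComparisonResult(
        visit=visit, estimate=estimate, se=se, t=t, df=df, p=p, n=n,
        adjusted_threshold=threshold, adjusted_p=min(1.0, n_tests * p),
        ci_low=estimate - tcrit * se, ci_high=estimate + tcrit * se,
    )


def within_group_test(
    changes,
    visit: float = math.nan,
    family_alpha: float = 0.05,
    n_tests: int = 3,
) -> ComparisonResult:
    """One-sample two-tailed t-test of mean change against zero."""
    x = np.asarray(changes, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise DegenerateDataError(f"need >= 2 change scores, got {n}")
    mean = float(x.mean())
    sd = 0.0 if _is_zero_spread(x) else float(x.std(ddof=1))
    if sd == 0.0 and abs(mean) <= 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0))):
        mean = 0.0
    return _t_inference(mean, sd / math.sqrt(n), n - 1, visit, n, family_alpha, n_tests)


def between_group_test(
    changes_a,
    changes_b,
    visit: float = math.nan,
    family_alpha: float = 0.05,
    n_tests: int = 3,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sample two-tailed t-test on change scores; estimate = mean(A) - mean(B).

    Classical Student's pooled-variance form by default; ``welch=True``
    switches to the unequal-variance (Welch-Satterthwaite) form.
    """
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DegenerateDataError("both arms need >= 2 change scores")
    estimate = float(a.mean() - b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    if welch:
        se2 = va / na + vb / nb
        se = math.sqrt(se2)
        df = (
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            if se2 > 0
            else na + nb - 2
        )
    else:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    return _t_inference(estimate, se, df, visit, na + nb, family_alpha, n_tests)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def repeated_measures_anova(
    panel: pd.DataFrame, value_col: str = "utility"
) -> pd.DataFrame:
    """Two-way mixed ANOVA: between factor arm, within factor visit.

    Expects a complete-case panel (every subject at every visit).  Returns
    the ANOVA table with F, df and p for the arm main effect, the visit
    main effect and the arm x visit interaction; the Greenhouse-Geisser
    corrected p for within-subject terms is reported alongside but not
    substituted.
    """
    import pingouin as pg

    if panel["arm"].nunique() < 2:
        raise DegenerateDataError("mixed ANOVA needs both arms")
    if panel["visit_month"].nunique() < 2:
        raise DegenerateDataError("mixed ANOVA needs >= 2 visits")
    counts = panel.groupby("subject_id")["visit_month"].nunique()
    if counts.nunique() != 1:
        raise DegenerateDataError("unbalanced panel: run complete_cases first")
    table = pg.mixed_anova(
        data=panel,
        dv=value_col,
        within="visit_month",
        between="arm",
        subject="subject_id",
        correction=True,
    )
    return table.rename(columns={"Source": "effect", "p-unc": "p", "p_unc": "p"})


# ---------------------------------------------------------------------------
# responsiveness


def responsiveness(
    changes, baselines, group: str = "", visit: float = math.nan
) -> ResponsivenessResult:
    """Effect size and standardized response mean for one group x visit.

    ES = mean change / SD(baseline values); SRM = mean change / SD(change
    scores); both sample SDs (n-1).  A zero SD leaves the corresponding
    statistic undefined (None) rather than infinite.
    """
    chg = np.asarray(changes, dtype=float)
    base = np.asarray(baselines, dtype=float)
    chg, base = chg[~np.isnan(chg)], base[~np.isnan(base)]
    if chg.size < 2 or base.size < 2:
        raise DegenerateDataError("need >= 2 observations for responsiveness")
    mean_change = float(chg.mean())
    sd_base = 0.0 if _is_zero_spread(base) else float(base.std(ddof=1))
    sd_chg = 0.0 if _is_zero_spread(chg) else float(chg.std(ddof=1))
    return ResponsivenessResult(
        group=group,
        visit=visit,
        n=chg.size,
        mean_change=mean_change,
        es=mean_change / sd_base if sd_base > 0 else None,
        srm=mean_change / sd_chg if sd_chg > 0 else None,
    )


def responsiveness_table(
    changes: pd.DataFrame, family_label: str = ""
) -> pd.DataFrame:
    """ES/SRM per arm and combined, per follow-up visit, as a tidy table."""
    rows = []
    for visit, dv in changes.groupby("visit_month"):
        groups = {"A": dv[dv["arm"] == "A"], "B": dv[dv["arm"] == "B"], "combined": dv}
        for label, g in groups.items():
            if len(g) < 2:
                continue
            r = responsiveness(g["change"], g["baseline"], group=label, visit=visit)
            rows.append(
                {
                    "family": family_label,
                    "group": label,
                    "visit_month": visit,
                    "n": r.n,
                    "mean_change": r.mean_change,
                    "es": r.es,
                    "srm": r.srm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# H&Y stratification


def hy_strata(
    observations: pd.DataFrame,
    value_col: str = "utility",
    stage_col: str = "hy_stage",
    min_n: int = 10,
) -> list[StrataSummary]:
    """Tukey boxplot statistics per H&Y stage over subject-visit observations.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    observation within 1.5 * IQR of the nearer quartile; points beyond are
    listed as outliers.  Stages with fewer than ``min_n`` observations are
    flagged low-reliability; empty stages are omitted.
    """
    out: list[StrataSummary] = []
    data = observations[[stage_col, value_col]].dropna()
    for stage, grp in data.groupby(stage_col):
        v = np.sort(grp[value_col].to_numpy(dtype=float))
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        out.append(
            StrataSummary(
                stage=float(stage),
                n=v.size,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
                outliers=tuple(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
                low_reliability=v.size < min_n,
            )
        )
    out.sort(key=lambda s: s.stage)
    total = sum(s.n for s in out)
    assert total == len(data)
    return out


def strata_table(summaries: list[StrataSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hy_stage": s.stage,
                "n": s.n,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
                "n_outliers": len(s.outliers),
                "low_reliability": s.low_reliability,
            }
            for s in summaries
        ]
    )
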