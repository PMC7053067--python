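"""Response mapping: link-function arithmetic, argmax assignment, schema."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdqmap.mapping import (
    EQ5D_DIMENSIONS,
    MappingModel,
    ModelValidationError,
    MultinomialDimensionModel,
    OrdinalDimensionModel,
    UnmappedRecordError,
    assign_level,
    multinomial_probs,
    ordinal_probs,
    predict_state,
    predict_table,
)
from pdqmap.scoring import SUBSCALE_NAMES, SubscaleProfile


def flat_profile(value: float) -> SubscaleProfile:
    return SubscaleProfile({s: value for s in SUBSCALE_NAMES})


def make_ordinal(alpha1, alpha2, beta=None, dim="mobility"):
    return OrdinalDimensionModel(dim, alpha1, alpha2, beta or {})


def make_multinomial(l2, l3, dim="mobility"):
    return MultinomialDimensionModel(dim, l2, l3)


# ---------------------------------------------------------------------------
# ordinal (Cauchit) family


def test_ordinal_zero_predictor_is_half():
    p = ordinal_probs(make_ordinal(0.0, 1.0), flat_profile(0.0))
    assert p[0] == pytest.approx(0.5, abs=1e-15)


def test_ordinal_frozen_example():
    # alpha1=1, alpha2=2, eta=0:
    # p1 = 0.5 + atan(1)/pi = 0.75; c2 = 0.5 + atan(2)/pi
    p = ordinal_probs(make_ordinal(1.0, 2.0), flat_profile(0.0))
    c2 = 0.5 + np.arctan(2.0) / np.pi
    assert p[0] == pytest.approx(0.75, abs=1e-12)
    assert p[1] == pytest.approx(c2 - 0.75, abs=1e-12)
    assert p[2] == pytest.approx(1.0 - c2, abs=1e-12)
    assert p[1] == pytest.approx(0.102416, abs=1e-6)
    assert p[2] == pytest.approx(0.147584, abs=1e-6)


def test_ordinal_cutpoint_limits():
    # very negative alpha1 -> p1 ~ 0; very positive -> p1 ~ 1
    assert ordinal_probs(make_ordinal(-1e8, 1e9), flat_profile(0.0))[0] < 1e-7
    assert ordinal_probs(make_ordinal(1e8, 1e9), flat_profile(0.0))[0] > 1 - 1e-7


def test_ordinal_slope_shifts_severity():
    m = make_ordinal(1.0, 2.0, {"mobility": 0.05})
    p_mild = ordinal_probs(m, flat_profile(0.0))
    p_severe = ordinal_probs(m, flat_profile(100.0))
    assert p_severe[0] < p_mild[0]
    assert p_severe[2] > p_mild[2]


def test_ordinal_requires_declared_subscale():
    m = make_ordinal(1.0, 2.0, {"stigma": 0.1})
    with pytest.raises(UnmappedRecordError):
        ordinal_probs(m, SubscaleProfile({"mobility": 10.0}))


def test_ordinal_cutpoint_order_validated_at_load():
    with pytest.raises(ModelValidationError):
        make_ordinal(2.0, 1.0)


@settings(max_examples=300, deadline=None)
@given(
    st.floats(-5, 5),
    st.floats(0.01, 5),
    st.floats(0, 0.1),
    st.floats(0, 100),
)
def test_ordinal_normalization_and_range(alpha1, gap, beta, x):
    p = ordinal_probs(
        make_ordinal(alpha1, alpha1 + gap, {"mobility": beta}),
        SubscaleProfile({"mobility": x}),
    )
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(st.floats(0, 100), st.floats(0, 100))
def test_ordinal_stochastic_monotonicity(x_low, x_high):
    """With non-negative slopes, worse subscales never raise p1 or lower p3."""
    lo, hi = sorted((x_low, x_high))
    m = make_ordinal(1.0, 2.5, {"mobility": 0.03, "stigma": 0.01})
    p_lo = ordinal_probs(m, flat_profile(lo))
    p_hi = ordinal_probs(m, flat_profile(hi))
    assert p_hi[0] <= p_lo[0] + 1e-12
    assert p_hi[2] >= p_lo[2] - 1e-12


# ---------------------------------------------------------------------------
# multinomial family


def test_multinomial_all_zero_is_uniform():
    m = make_multinomial({"intercept": 0.0}, {"intercept": 0.0})
    p = multinomial_probs(m, flat_profile(50.0), age=52.0, gender=1)
    assert p == pytest.approx([1 / 3] * 3, abs=1e-15)


def test_multinomial_intercept_only_softmax():
    # s2 = ln 2, s3 = ln 3 -> (1/6, 2/6, 3/6)
    m = make_multinomial({"intercept": np.log(2)}, {"intercept": np.log(3)})
    p = multinomial_probs(m, flat_profile(0.0), age=0.0, gender=0)
    assert p == pytest.approx([1 / 6, 2 / 6, 3 / 6], abs=1e-12)


def test_multinomial_overflow_guard():
    m = make_multinomial({"intercept": -1000.0}, {"intercept": -1000.0})
    p = multinomial_probs(m, flat_profile(0.0), age=0.0, gender=0)
    assert p[0] == pytest.approx(1.0, abs=1e-15)
    m = make_multinomial({"intercept": 1000.0}, {"intercept": 900.0})
    p = multinomial_probs(m, flat_profile(0.0), age=0.0, gender=0)
    assert np.isfinite(p).all()
    assert p[1] == pytest.approx(1.0, abs=1e-15)


def test_multinomial_covariates_enter_scores():
    m = make_multinomial(
        {"intercept": 0.0, "age": 0.1, "gender": 1.0, "mobility": 0.01},
        {"intercept": 0.0},
    )
    p_male = multinomial_probs(m, flat_profile(0.0), age=50.0, gender=0)
    p_female = multinomial_probs(m, flat_profile(0.0), age=50.0, gender=1)
    assert p_female[1] > p_male[1]
    with pytest.raises(UnmappedRecordError):
        multinomial_probs(m, flat_profile(0.0), age=float("nan"), gender=0)


@settings(max_examples=300, deadline=None)
@given(
    st.floats(-30, 30),
    st.floats(-30, 30),
    st.floats(-0.1, 0.1),
    st.floats(0, 100),
    st.floats(20, 90),
)
def test_multinomial_normalization(b2, b3, slope, x, age):
    m = make_multinomial(
        {"intercept": b2, "mobility": slope, "age": 0.01},
        {"intercept": b3, "mobility": slope / 2},
    )
    p = multinomial_probs(m, flat_profile(x), age=age, gender=1)
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# level assignment


@pytest.mark.parametrize(
    "triple,expected",
    [
        ((0.2, 0.5, 0.3), 2),
        ((0.4, 0.4, 0.2), 1),  # tie -> less severe
        ((0.3, 0.3, 0.4), 3),
        ((1 / 3, 1 / 3, 1 / 3), 1),
        ((0.1, 0.45, 0.45), 2),
    ],
)
def test_assign_level_examples(triple, expected):
    assert assign_level(triple) == expected


def test_assign_level_matches_enumeration_oracle():
    """Argmax with low-level tie-break vs brute-force enumeration, 10k triples."""
    rng = np.random.default_rng(42)
    triples = rng.dirichlet((1.0, 1.0, 1.0), size=10_000)
    # engineered exact ties
    ties = np.array([[0.4, 0.4, 0.2], [0.2, 0.4, 0.4], [1 / 3, 1 / 3, 1 / 3]])
    for p in np.vstack([triples, ties]):
        best = max(p)
        oracle = min(lv for lv in (1, 2, 3) if p[lv - 1] == best)
        assert assign_level(p) == oracle


# ---------------------------------------------------------------------------
# full-state prediction


def _uniform_ordinal_model(alpha1=1.0, alpha2=2.0, beta=None):
    return MappingModel(
        family="ordinal",
        dimensions={
            d: OrdinalDimensionModel(d, alpha1, alpha2, dict(beta or {}))
            for d in EQ5D_DIMENSIONS
        },
    )


def test_predict_state_no_slope_gives_full_health():
    # p1 = 0.75 dominates in every dimension
    state, probs = predict_state(_uniform_ordinal_model(), flat_profile(50.0))
    assert state == (1, 1, 1, 1, 1)
    assert probs.shape == (5, 3)
    assert probs.sum(axis=1) == pytest.approx([1.0] * 5, abs=1e-12)


def test_predict_state_zero_multinomial_tie_breaks_low():
    m = MappingModel(
        family="multinomial",
        dimensions={
            d: MultinomialDimensionModel(d, {"intercept": 0.0}, {"intercept": 0.0})
            for d in EQ5D_DIMENSIONS
        },
    )
    state, _ = predict_state(m, flat_profile(50.0), age=52.0, gender=0)
    assert state == (1, 1, 1, 1, 1)


def test_predict_state_severe_limit():
    m = _uniform_ordinal_model(beta={"mobility": 10.0})
    state, _ = predict_state(m, flat_profile(100.0))
    assert state == (3, 3, 3, 3, 3)


def test_family_parity_on_identical_records(ordinal_model, multinomial_model):
    """Both engines consume the same table and emit the same schema."""
    rng = np.random.default_rng(5)
    df = pd.DataFrame({s: rng.uniform(0, 100, 40) for s in SUBSCALE_NAMES})
    df["age"] = rng.normal(52, 6, 40)
    df["gender"] = rng.integers(0, 2, 40)
    out_o = predict_table(ordinal_model, df)
    out_m = predict_table(multinomial_model, df)
    cols = {f"level_{d}" for d in EQ5D_DIMENSIONS}
    assert cols <= set(out_o.columns) and cols <= set(out_m.columns)
    for out in (out_o, out_m):
        for d in EQ5D_DIMENSIONS:
            lv = out[f"level_{d}"]
            assert lv.isin([1, 2, 3]).all()
            psum = out[[f"p1_{d}", f"p2_{d}", f"p3_{d}"]].sum(axis=1)
            assert np.allclose(psum, 1.0, atol=1e-12)


def test_predict_table_matches_scalar_path(ordinal_model, multinomial_model):
    rng = np.random.default_rng(9)
    df = pd.DataFrame({s: rng.uniform(0, 100, 25) for s in SUBSCALE_NAMES})
    df["age"] = rng.normal(52, 6, 25)
    df["gender"] = rng.integers(0, 2, 25)
    for model in (ordinal_model, multinomial_model):
        out = predict_table(model, df)
        for r in range(len(df)):
            profile = SubscaleProfile({s: df.loc[r, s] for s in SUBSCALE_NAMES})
            state, probs = predict_state(
                model, profile, age=df.loc[r, "age"], gender=df.loc[r, "gender"]
            )
            for i, d in enumerate(EQ5D_DIMENSIONS):
                assert out.loc[r, f"level_{d}"] == state[i]
                assert out.loc[r, f"p1_{d}"] == pytest.approx(probs[i, 0], abs=1e-12)


def test_predict_table_voids_whole_record_on_missing_covariate(multinomial_model):
    rng = np.random.default_rng(2)
    df = pd.DataFrame({s: rng.uniform(0, 100, 4) for s in SUBSCALE_NAMES})
    df["age"] = [50.0, np.nan, 60.0, 55.0]
    df["gender"] = [0, 1, 1, 0]
    out = predict_table(multinomial_model, df)
    assert out.loc[1, [f"level_{d}" for d in EQ5D_DIMENSIONS]].isna().all()
    assert out.loc[0, [f"level_{d}" for d in EQ5D_DIMENSIONS]].notna().all()


# ---------------------------------------------------------------------------
# schema validation


def test_mapping_model_requires_all_dimensions():
    with pytest.raises(ModelValidationError):
        MappingModel(
            family="ordinal",
            dimensions={"mobility": OrdinalDimensionModel("mobility", 0.0, 1.0, {})},
        )


def test_multinomial_block_requires_intercept():
    with pytest.raises(ModelValidationError):
        MultinomialDimensionModel("mobility", {"mobility": 0.1}, {"intercept": 0.0})


def test_unknown_covariate_rejected():
    with pytest.raises(ModelValidationError):
        MultinomialDimensionModel(
            "mobility", {"intercept": 0.0, "bmi": 0.1}, {"intercept": 0.0}
        )
    with pytest.raises(ModelValidationError):
        OrdinalDimensionModel("mobility", 0.0, 1.0, {"bmi": 0.1})


def test_load_demo_models(ordinal_model, multinomial_model):
    assert set(ordinal_model.dimensions) == set(EQ5D_DIMENSIONS)
    assert set(multinomial_model.dimensions) == set(EQ5D_DIMENSIONS)
    assert multinomial_model.gender_coding == {"female": 1, "male": 0}
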