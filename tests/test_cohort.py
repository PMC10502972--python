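"""Cohort simulation and longitudinal statistics."""

import logging

import numpy as np
import pandas as pd
import pytest

from choroidseg import (
    CohortSpec, adjusted_group_change, change_from_baseline,
    hierarchical_regression, pearson_r, percent_change, simulate_cohort,
)
from choroidseg.cohort import VISITS


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(seed=3))


# ---------------------------------------------------------------------- #
# simulation


def test_cohort_shape_and_schedule(cohort):
    assert set(cohort["visit"]) == set(VISITS)
    counts = cohort.groupby("subject")["visit"].nunique()
    assert (counts == len(VISITS)).all()  # visits unique per subject
    assert (cohort["sfcht"] > 0).all()
    six_monthly = cohort[cohort["visit"].isin(["1w", "1m", "3m"])]
    assert six_monthly["axial_length"].isna().all()
    assert cohort[cohort["visit"] == "12m"]["axial_length"].notna().all()
    assert len(cohort) == (78 + 80) * len(VISITS)


def test_cohort_deterministic():
    a = simulate_cohort(CohortSpec(seed=5))
    b = simulate_cohort(CohortSpec(seed=5))
    pd.testing.assert_frame_equal(a, b)


def test_zero_noise_reproduces_configured_group_means():
    spec = CohortSpec(n_dims=5, n_sv=5, visit_noise_sd=0.0,
                      subject_response_sd=0.0, seed=1)
    ch = change_from_baseline(simulate_cohort(spec))
    w1 = ch[(ch["visit"] == "1w") & (ch["group"] == "DIMS")]
    assert np.allclose(w1["d_sfcht"], 6.75)
    w1sv = ch[(ch["visit"] == "1w") & (ch["group"] == "SV")]
    assert np.allclose(w1sv["d_sfcht"], -3.17)


def test_sample_means_near_configured_baselines(cohort):
    base = cohort[cohort["visit"] == "baseline"]
    for group, mean, sd, n in (("DIMS", 280.95, 54.30, 78),
                               ("SV", 259.53, 49.36, 80)):
        got = base.loc[base["group"] == group, "sfcht"].mean()
        assert abs(got - mean) < 2 * sd / np.sqrt(n)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError, match="2 subjects"):
        CohortSpec(n_dims=1).validate()
    with pytest.raises(ValueError, match="non-negative"):
        CohortSpec(visit_noise_sd=-1).validate()


# ---------------------------------------------------------------------- #
# change from baseline


def test_change_from_baseline_arithmetic(cohort):
    ch = change_from_baseline(cohort)
    sub = cohort["subject"].iloc[0]
    base = cohort[(cohort["subject"] == sub)
                  & (cohort["visit"] == "baseline")]["sfcht"].iloc[0]
    v12 = cohort[(cohort["subject"] == sub)
                 & (cohort["visit"] == "12m")]["sfcht"].iloc[0]
    got = ch[(ch["subject"] == sub) & (ch["visit"] == "12m")]["d_sfcht"]
    assert got.iloc[0] == pytest.approx(v12 - base)


def test_change_from_baseline_simple_cases():
    df = pd.DataFrame({
        "subject": ["a", "a", "b", "b"],
        "group": ["DIMS"] * 4, "age": [10.0] * 4, "gender": ["M"] * 4,
        "visit": ["baseline", "1w", "baseline", "1w"],
        "sfcht": [280.0, 290.0, 250.0, 250.0],
        "axial_length": [np.nan] * 4, "ser": [np.nan] * 4,
    })
    ch = change_from_baseline(df)
    assert ch.loc[ch["subject"] == "a", "d_sfcht"].iloc[0] == 10.0
    assert ch.loc[ch["subject"] == "b", "d_sfcht"].iloc[0] == 0.0


def test_missing_baseline_subject_excluded(caplog):
    df = pd.DataFrame({
        "subject": ["a", "a", "b"],
        "group": ["DIMS"] * 3, "age": [10.0] * 3, "gender": ["F"] * 3,
        "visit": ["baseline", "1w", "1w"],
        "sfcht": [280.0, 290.0, 260.0],
        "axial_length": [np.nan] * 3, "ser": [np.nan] * 3,
    })
    with caplog.at_level(logging.WARNING, logger="choroidseg.cohort"):
        ch = change_from_baseline(df)
    assert set(ch["subject"]) == {"a"}
    assert any("without baseline" in r.message for r in caplog.records)


# ---------------------------------------------------------------------- #
# adjusted group change


def test_adjusted_equals_raw_when_baselines_identical():
    rng = np.random.default_rng(0)
    groups = np.array(["DIMS"] * 10 + ["SV"] * 10)
    changes = np.where(groups == "DIMS", 6.0, -3.0) + rng.normal(0, 1, 20)
    baselines = np.full(20, 270.0)
    out = adjusted_group_change(changes, baselines, groups)
    assert out["DIMS"]["adjusted_mean"] == pytest.approx(
        changes[groups == "DIMS"].mean())
    assert out["SV"]["adjusted_mean"] == pytest.approx(
        changes[groups == "SV"].mean())


def test_adjusted_difference_negates_under_label_swap(rng):
    groups = np.array(["DIMS"] * 15 + ["SV"] * 15)
    baselines = rng.normal(270, 50, 30)
    changes = rng.normal(0, 5, 30) + (groups == "DIMS") * 9.0
    out = adjusted_group_change(changes, baselines, groups)
    swapped = np.where(groups == "DIMS", "SV", "DIMS")
    out2 = adjusted_group_change(changes, baselines, swapped)
    assert out["difference"]["estimate"] == pytest.approx(
        -out2["difference"]["estimate"])


def test_adjusted_group_change_recovers_planted_difference():
    spec = CohortSpec(seed=11)
    ch = change_from_baseline(simulate_cohort(spec))
    w1 = ch[ch["visit"] == "1w"]
    out = adjusted_group_change(w1["d_sfcht"].to_numpy(),
                                w1["baseline_sfcht"].to_numpy(),
                                w1["group"].to_numpy())
    planted = -3.17 - 6.75  # SV minus DIMS
    d = out["difference"]
    assert abs(d["estimate"] - planted) < 2 * d["sem"]


# ---------------------------------------------------------------------- #
# percent change / correlation


def test_percent_change_worked_example():
    assert percent_change(6.75, 280.95) == 2.4
    assert percent_change(0.0, 123.0) == 0.0
    assert percent_change(10.0, 200.0) == 5.0
    with pytest.raises(ValueError, match="positive"):
        percent_change(5.0, 0.0)


def test_pearson_examples():
    x = np.arange(10.0)
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    xs = np.array([1.0, 2, 3, 4])
    ys = np.array([2.0, 1, 4, 3])
    oracle = (((xs - xs.mean()) * (ys - ys.mean())).sum()
              / np.sqrt(((xs - xs.mean()) ** 2).sum()
                        * ((ys - ys.mean()) ** 2).sum()))
    assert pearson_r(xs, ys) == pytest.approx(oracle)
    with pytest.raises(ValueError, match="variance"):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------- #
# hierarchical regression


def make_regression_frame(rng, n=100, coef_candidate=0.0, noise=1.0):
    age = rng.normal(10, 1.5, n)
    gender = rng.random(n) < 0.5
    cand = rng.normal(0, 10, n)
    y = -0.03 * age - 0.01 * gender + coef_candidate * cand
    y = y + rng.normal(0, noise, n)
    return pd.DataFrame({
        "age": age, "gender": np.where(gender, "M", "F"),
        "d_sfcht_3m": cand, "d_al_12m": y,
    })


def test_orthogonal_candidate_adds_no_variance(rng):
    n = 40
    age = np.tile([9.0, 10.0, 11.0, 12.0], n // 4)
    gender = np.tile(["M", "F"], n // 2)
    y = 0.1 * age + rng.normal(0, 0.1, n)
    # construct a candidate exactly orthogonal to the base block and outcome
    cand = rng.normal(0, 1, n)
    X = np.c_[np.ones(n), age, (gender == "M").astype(float), y]
    cand = cand - X @ np.linalg.lstsq(X, cand, rcond=None)[0]
    df = pd.DataFrame({"age": age, "gender": gender, "d_sfcht_3m": cand,
                       "d_al_12m": y})
    rep = hierarchical_regression(df, outcome="d_al_12m")
    assert rep.delta_r2 == pytest.approx(0.0, abs=1e-10)


def test_exact_linear_outcome_gives_r2_one(rng):
    df = make_regression_frame(rng, coef_candidate=-0.02, noise=0.0)
    rep = hierarchical_regression(df, outcome="d_al_12m")
    assert rep.r2_full == pytest.approx(1.0)


def test_planted_sign_recovered_and_r2_monotone(rng):
    df = make_regression_frame(rng, n=158, coef_candidate=-0.02, noise=0.1)
    rep = hierarchical_regression(df, outcome="d_al_12m")
    assert rep.betas_full["d_sfcht_3m"] < 0
    assert rep.r2_full >= rep.r2_base


def test_collinear_design_rejected(rng):
    df = make_regression_frame(rng)
    df["d_sfcht_3m"] = df["age"] * 2.0  # exact collinearity
    with pytest.raises(ValueError, match="collinear"):
        hierarchical_regression(df, outcome="d_al_12m")
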