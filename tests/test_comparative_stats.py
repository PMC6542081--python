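"""Proportion tests, Mann-Whitney, and the three-step logistic procedure.

Exact oracles: Fisher's p against exhaustive enumeration of margin-fixed
2x2 tables; Mann-Whitney p against exhaustive rank assignments.
"""

import math
import random
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from psyaudit.comparative_stats import (
    PREDICTORS,
    ComparisonError,
    compare_proportions,
    logistic_procedure,
    mann_whitney,
    multicollinearity_table,
    predictor_frame,
    three_step_logistic,
)


def test_compare_proportions_worked_example():
    result = compare_proportions(24, 386, 123, 416)
    assert result.percent_a == 6.2
    assert result.percent_b == 29.6
    assert result.test_used == "chi_square"
    assert result.p_value < 0.001
    assert result.significant


def test_compare_proportions_identical_is_one():
    result = compare_proportions(10, 100, 10, 100)
    assert result.test_used == "chi_square"
    assert result.p_value == pytest.approx(1.0)
    assert not result.significant


def test_compare_proportions_zero_denominator():
    with pytest.raises(ComparisonError):
        compare_proportions(0, 0, 1, 10)


def test_compare_proportions_symmetric():
    rng = random.Random(3)
    for _ in range(20):
        da, db = rng.randint(1, 50), rng.randint(1, 50)
        ca, cb = rng.randint(0, da), rng.randint(0, db)
        ab = compare_proportions(ca, da, cb, db)
        ba = compare_proportions(cb, db, ca, da)
        assert ab.percent_a == ba.percent_b and ab.percent_b == ba.percent_a
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)


def _fisher_oracle(ca, da, cb, db):
    """Two-sided Fisher p by exhaustive margin-fixed table enumeration."""
    row_a, row_b = da, db
    col1 = ca + cb
    total = da + db

    def prob(a):
        # hypergeometric point mass for table [[a, row_a-a], [col1-a, ...]]
        return (
            math.comb(row_a, a)
            * math.comb(row_b, col1 - a)
            / math.comb(total, col1)
        )

    p_obs = prob(ca)
    p = 0.0
    for a in range(max(0, col1 - row_b), min(row_a, col1) + 1):
        if prob(a) <= p_obs * (1 + 1e-12):
            p += prob(a)
    return min(p, 1.0)


@pytest.mark.parametrize("ca,da,cb,db", [(1, 8, 7, 8), (0, 5, 4, 6), (1, 10, 9, 11)])
def test_fisher_p_equals_hypergeometric_enumeration(ca, da, cb, db):
    result = compare_proportions(ca, da, cb, db)
    assert result.test_used == "fisher_exact"
    assert result.p_value == pytest.approx(_fisher_oracle(ca, da, cb, db), rel=1e-9)


def test_chi_square_consistent_with_fisher_on_large_expected():
    """Sanity: with all expected cells >= 20 the two tests are typically
    close and always agree on the p < 0.01 significance call.

    The conservative two-sided Fisher p can exceed the uncorrected
    chi-square p by several percentage points on mid-range tables, so the
    per-table closeness claim is kept to the median.
    """
    from scipy import stats as sps

    rng = random.Random(99)
    diffs = []
    while len(diffs) < 25:
        da, db = rng.randint(80, 200), rng.randint(80, 200)
        ca, cb = rng.randint(25, da - 25), rng.randint(25, db - 25)
        table = np.array([[ca, da - ca], [cb, db - cb]], dtype=float)
        expected = table.sum(1, keepdims=True) @ table.sum(0, keepdims=True) / table.sum()
        if expected.min() < 20:
            continue
        chi_p = sps.chi2_contingency(table, correction=False)[1]
        fisher_p = sps.fisher_exact(table.astype(int))[1]
        assert (chi_p < 0.01) == (fisher_p < 0.01)
        diffs.append(abs(chi_p - fisher_p))
    assert float(np.median(diffs)) < 0.01


def _mw_oracle(a, b):
    """Exact two-sided Mann-Whitney p over all rank assignments."""
    na, nb = len(a), len(b)
    pooled = list(a) + list(b)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    mean_u = na * nb / 2
    count = 0
    total = 0
    for positions in combinations(range(na + nb), na):
        u = ranks[list(positions)].sum() - na * (na + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def test_mann_whitney_identical_samples():
    assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "a,b",
    [
        ([1, 2, 3], [101, 102, 103]),
        ([1, 5, 9], [2, 3, 8]),
        ([1, 2, 3, 4], [5, 6, 7]),
        ([10, 20], [15, 25, 30, 40]),
    ],
)
def test_mann_whitney_equals_exhaustive_enumeration(a, b):
    assert mann_whitney(a, b) == pytest.approx(_mw_oracle(a, b), rel=1e-9)


def test_mann_whitney_rejects_empty():
    with pytest.raises(ComparisonError):
        mann_whitney([], [1.0])


def test_mann_whitney_null_calibration():
    """Under the null the rejection rate at alpha=0.05 is about 5%."""
    rng = np.random.default_rng(2024)
    rejections = 0
    reps = 400
    for _ in range(reps):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        rejections += mann_whitney(a, b) < 0.05
    rate = rejections / reps
    # 99% binomial band around 0.05 at 400 reps
    assert 0.022 <= rate <= 0.078


def _planted_frame(rng, n, beta_ad=1.2):
    """Design with a known antidepressant log-odds coefficient."""
    frame = pd.DataFrame(
        {
            "gender": rng.integers(0, 2, n),
            "age": rng.normal(84.0, 7.0, n),
            "n_psychotropics": rng.integers(2, 6, n).astype(float),
            "antidepressant": rng.integers(0, 2, n),
            "antipsychotic": rng.integers(0, 2, n),
            "anxiolytic_hypnotic": rng.integers(0, 2, n),
            "antiepileptic": rng.integers(0, 2, n),
        }
    )
    logit = -1.0 + beta_ad * frame["antidepressant"]
    frame["has_pi"] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return frame


def test_logistic_recovers_planted_coefficient():
    """Step-3 antidepressant estimate covers the planted log-odds at n=2000."""
    rng = np.random.default_rng(77)
    beta_ad = 1.2
    report = three_step_logistic(_planted_frame(rng, 2000, beta_ad))
    assert "antidepressant" in report.selected
    row = report.step3.loc["antidepressant"]
    assert row["ci_low"] < math.exp(beta_ad) < row["ci_high"]
    # point estimate within a few simulation standard errors
    assert abs(math.log(row["odds_ratio"]) - beta_ad) < 0.35


def test_logistic_bias_shrinks_with_n():
    """Coefficient bias decreases from n=200 to n=5000 (parameter recovery)."""
    beta_ad = 1.0
    errors = {}
    for n in (200, 1000, 5000):
        draws = []
        for rep in range(3):
            rng = np.random.default_rng(1000 * n + rep)
            report = three_step_logistic(_planted_frame(rng, n, beta_ad))
            if "antidepressant" in report.selected:
                draws.append(math.log(report.step3.loc["antidepressant", "odds_ratio"]))
        errors[n] = abs(np.mean(draws) - beta_ad)
    assert errors[5000] < errors[200]


def test_screening_rule_is_disjunction(cohort_2016, kb_extended):
    report = logistic_procedure(cohort_2016, kb_extended)
    screen = pd.concat(
        [report.step1["p_value"], report.step2["p_value"]], axis=1
    ).min(axis=1)
    for name in PREDICTORS:
        assert (name in report.selected) == (screen[name] < 0.25)
    assert set(report.step3.index) == set(report.selected)


def test_reported_ci_contains_or(cohort_2016, kb_extended):
    report = logistic_procedure(cohort_2016, kb_extended)
    for frame in (report.step1, report.step2, report.step3):
        kept = frame[~frame["suppressed"]].dropna()
        assert ((kept["ci_low"] <= kept["odds_ratio"]) & (kept["odds_ratio"] <= kept["ci_high"])).all()


def test_vif_near_one_for_independent_predictors():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
    table = multicollinearity_table(X)
    assert (table["vif"] < 1.05).all()
    assert (table["tolerance"] > 0.95).all()


def test_degenerate_population_raises(make_cohort, kb):
    # every patient interaction-free -> single outcome class
    cohort = make_cohort([["citalopram", "diazepam"]] * 5)
    with pytest.raises(ComparisonError, match="degenerate"):
        logistic_procedure(cohort, kb)


def test_perfect_separation_flagged():
    frame = pd.DataFrame(
        {
            "gender": [0, 0, 0, 0, 1, 1, 1, 1] * 5,
            "age": list(range(40)),
            "n_psychotropics": [2.0] * 40,
            "antidepressant": [0, 1] * 20,
            "antipsychotic": [0] * 40,
            "anxiolytic_hypnotic": [1] * 40,
            "antiepileptic": [0] * 40,
        }
    )
    frame["has_pi"] = frame["gender"]  # separated perfectly by gender
    report = three_step_logistic(frame, predictors=("gender", "age", "antidepressant"))
    assert report.step1.loc["gender", "suppressed"]


def test_predictor_frame_coding(make_cohort, kb, make_patient):
    from psyaudit.cohort_io import Cohort

    cohort = Cohort(
        label="c",
        patients=[
            make_patient(["citalopram", "haloperidol"], gender="M", age=70),
            make_patient(["oxazepam"], gender="F", age=90),
        ],
    )
    frame = predictor_frame(cohort, kb).set_index("patient_id")
    male = frame[frame["gender"] == 1].iloc[0]
    assert male["antidepressant"] == 1 and male["antipsychotic"] == 1
    assert male["has_pi"] == 1  # citalopram-haloperidol is in the KB
    female = frame[frame["gender"] == 0].iloc[0]
    assert female["n_psychotropics"] == 1 and female["has_pi"] == 0
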