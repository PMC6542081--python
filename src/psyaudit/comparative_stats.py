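"""Two-cohort comparison statistics and the three-step logistic procedure.

Proportions are compared with Pearson's chi-square (no continuity
correction), falling back to Fisher's exact test when any expected cell
is below 5.  Continuous variables are compared with the two-sided
Mann-Whitney U test with tie correction.  Statistical significance is
flagged at p < 0.01.

Predictors of having at least one screened interaction, among patients
using two or more psychotropics, are assessed with a logistic regression
in three steps: (1) a univariate model per predictor, (2) the fully
adjusted model with all predictors, (3) a final model over the predictors
with p < 0.25 in either of the first two steps.  Multicollinearity is
screened with variance inflation factors and tolerances from auxiliary
linear regressions of each predictor on the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

from ._rounding import percent
from .cohort_io import Cohort, Patient, category_registrations, distinct_substances
from .formulary import PsychotropicCategory
from .interaction_engine import KnowledgeBase, match_interactions

SIGNIFICANCE_LEVEL = 0.01
SCREENING_P = 0.25
MIN_EXPECTED_CELL = 5.0


class ComparisonError(ValueError):
    """Undefined or degenerate comparison."""


@dataclass(frozen=True)
class ProportionComparison:
    label: str
    count_a: int
    denom_a: int
    count_b: int
    denom_b: int
    percent_a: float
    percent_b: float
    test_used: str  # "chi_square" or "fisher_exact"
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def compare_proportions(
    count_a: int,
    denom_a: int,
    count_b: int,
    denom_b: int,
    label: str = "",
) -> ProportionComparison:
    """Compare two binomial proportions.

    Pearson chi-square without continuity correction on the 2x2 table;
    Fisher's exact two-sided test when any expected cell is below 5.
    """
    for count, denom, side in ((count_a, denom_a, "a"), (count_b, denom_b, "b")):
        if denom <= 0:
            raise ComparisonError(f"zero denominator on side {side}")
        if not 0 <= count <= denom:
            raise ComparisonError(f"count out of range on side {side}: {count}/{denom}")

    table = np.array(
        [[count_a, denom_a - count_a], [count_b, denom_b - count_b]], dtype=float
    )
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total

    if (expected < MIN_EXPECTED_CELL).any() or (col == 0).any():
        test_used = "fisher_exact"
        _, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
    else:
        test_used = "chi_square"
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ProportionComparison(
        label=label,
        count_a=count_a,
        denom_a=denom_a,
        count_b=count_b,
        denom_b=denom_b,
        percent_a=percent(count_a, denom_a),
        percent_b=percent(count_b, denom_b),
        test_used=test_used,
        p_value=float(p),
    )


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value with tie correction.

    Uses the exact null distribution on small tie-free samples and the
    tie-corrected normal approximation (no continuity correction)
    otherwise, so identical samples give p = 1 exactly.
    """
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ComparisonError("Mann-Whitney requires two non-empty samples")
    _, p = sps.mannwhitneyu(
        sample_a, sample_b, alternative="two-sided", use_continuity=False, method="auto"
    )
    return float(p)


PREDICTORS = (
    "gender",
    "age",
    "n_psychotropics",
    "antidepressant",
    "antipsychotic",
    "anxiolytic_hypnotic",
    "antiepileptic",
)

_CATEGORY_PREDICTOR = {
    "antidepressant": PsychotropicCategory.ANTIDEPRESSANT,
    "antipsychotic": PsychotropicCategory.ANTIPSYCHOTIC,
    "anxiolytic_hypnotic": PsychotropicCategory.ANXIOLYTIC_HYPNOTIC,
    "antiepileptic": PsychotropicCategory.ANTIEPILEPTIC,
}


def predictor_frame(cohort: Cohort, kb: KnowledgeBase) -> pd.DataFrame:
    """Patient-level design matrix plus the interaction outcome.

    Dichotomous predictors are 0/1 (gender: male = 1); age and the number
    of distinct psychotropics are continuous.  The outcome ``has_pi`` is 1
    when at least one substance pair matches the knowledge base.
    """
    records = []
    for patient in cohort:
        cats = category_registrations(patient)
        record = {
            "patient_id": patient.id,
            "gender": int(patient.gender == "M"),
            "age": float(patient.age),
            "n_psychotropics": len(distinct_substances(patient)),
            "has_pi": int(match_interactions(patient, kb).n_interactions >= 1),
        }
        for name, category in _CATEGORY_PREDICTOR.items():
            record[name] = int(category in cats)
        records.append(record)
    return pd.DataFrame.from_records(records)


@dataclass
class LogisticReport:
    """Result of the three-step logistic procedure."""

    population_size: int
    outcome_positive: int
    step1: pd.DataFrame
    step2: pd.DataFrame
    step3: pd.DataFrame
    selected: list[str]
    multicollinearity: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def default_population_filter(patient_row: pd.Series) -> bool:
    """Analysis population: patients using two or more psychotropics."""
    return patient_row["n_psychotropics"] >= 2


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """Fit a logit and return per-predictor OR, Wald 95% CI and p.

    A predictor whose estimate does not admit a finite Wald interval
    (perfect separation or non-convergence) is flagged and its estimates
    suppressed.
    """
    design = sm.add_constant(X, has_constant="add")
    rows = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=False, maxiter=200)
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
    except Exception:
        params = pd.Series(np.nan, index=design.columns)
        bse = pd.Series(np.nan, index=design.columns)
        pvalues = pd.Series(np.nan, index=design.columns)
    for name in X.columns:
        beta, se, p = params[name], bse[name], pvalues[name]
        ok = np.isfinite(beta) and np.isfinite(se) and se < 50
        rows.append(
            {
                "predictor": name,
                "odds_ratio": float(np.exp(beta)) if ok else np.nan,
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)) if ok else np.nan,
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)) if ok else np.nan,
                "p_value": float(p) if ok else np.nan,
                "suppressed": not ok,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def multicollinearity_table(X: pd.DataFrame) -> pd.DataFrame:
    """VIF and tolerance from regressing each predictor on the others."""
    rows = []
    for name in X.columns:
        others = sm.add_constant(X.drop(columns=[name]), has_constant="add")
        r2 = sm.OLS(X[name].astype(float), others).fit().rsquared
        tolerance = max(1.0 - r2, 1e-12)
        rows.append({"predictor": name, "vif": 1.0 / tolerance, "tolerance": tolerance})
    return pd.DataFrame(rows).set_index("predictor")


def logistic_procedure(
    cohort: Cohort,
    kb: KnowledgeBase,
    population_filter: Optional[Callable[[pd.Series], bool]] = None,
) -> LogisticReport:
    """Three-step logistic regression of interaction risk.

    Step 1 fits a univariate model per predictor; step 2 the fully
    adjusted model; step 3 refits over predictors with p < 0.25 in at
    least one of the first two steps (the disjunction; recorded in
    ``notes``).
    """
    frame = predictor_frame(cohort, kb)
    if population_filter is None:
        population_filter = default_population_filter
    frame = frame[frame.apply(population_filter, axis=1)].reset_index(drop=True)
    return three_step_logistic(frame)


def three_step_logistic(
    frame: pd.DataFrame, predictors: Sequence[str] = PREDICTORS
) -> LogisticReport:
    """The three-step procedure on a prepared predictor frame.

    ``frame`` must hold the predictor columns plus the 0/1 outcome
    ``has_pi``; rows are the analysis population.
    """
    y = frame["has_pi"].to_numpy(dtype=float)
    if len(frame) == 0 or y.min() == y.max():
        raise ComparisonError(
            "degenerate model: analysis population lacks both outcome classes"
        )
    X = frame[list(predictors)].astype(float)

    step1_rows = [
        _fit_logit(y, X[[name]]).loc[[name]] for name in predictors
    ]
    step1 = pd.concat(step1_rows)
    step2 = _fit_logit(y, X)

    screen_p = pd.concat(
        [step1["p_value"].rename("p1"), step2["p_value"].rename("p2")], axis=1
    ).min(axis=1)
    selected = [name for name in predictors if screen_p[name] < SCREENING_P]
    notes = [
        "step3 selection rule: min(step1 p, step2 p) < 0.25 per predictor",
        "gender coding: male = 1",
        "indicators apply to all cohort members aged >= 65",
    ]
    if selected:
        step3 = _fit_logit(y, X[selected])
    else:
        step3 = step2.iloc[0:0]
        notes.append("no predictor passed the p < 0.25 screen; step 3 empty")

    return LogisticReport(
        population_size=len(frame),
        outcome_positive=int(y.sum()),
        step1=step1,
        step2=step2,
        step3=step3,
        selected=selected,
        multicollinearity=multicollinearity_table(X),
        notes=notes,
    )
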