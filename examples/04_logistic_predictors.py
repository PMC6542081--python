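"""Three-step logistic regression of interaction risk.

Among synthetic residents on two or more psychotropics, models the odds
of having at least one screened interaction from age, gender, the
psychotropic count and the four category indicators.
"""

from psyaudit import (
    CohortConfig,
    default_registry,
    generate_cohort,
    generate_kb_fixture,
    logistic_procedure,
)

registry = default_registry()
cohort = generate_cohort(CohortConfig.year_2016(seed=3), registry)
kb = generate_kb_fixture(extended=True)

report = logistic_procedure(cohort, kb)
print(
    f"analysis population: {report.population_size} residents on >=2"
    f" psychotropics, {report.outcome_positive} with >=1 interaction"
)
print(f"selected for step 3 (p < 0.25 in step 1 or 2): {report.selected}")
print()
print("final (step 3) model, odds ratios with Wald 95% CI:")
for name, row in report.step3.iterrows():
    print(
        f"  {name:<20} OR {row['odds_ratio']:6.2f}"
        f" ({row['ci_low']:.2f}-{row['ci_high']:.2f}) p={row['p_value']:.3g}"
    )
print()
print("multicollinearity screen (VIF < 2 and tolerance > 0.5 are unremarkable):")
for name, row in report.multicollinearity.iterrows():
    print(f"  {name:<20} VIF {row['vif']:.2f}  tolerance {row['tolerance']:.2f}")
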