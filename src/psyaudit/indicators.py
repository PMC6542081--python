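"""Prescribing-quality indicators: polypharmacy, PICP and PIPS.

Three indicator families are computed per patient and aggregated per
cohort:

* **Psychotropic polypharmacy** — concurrent use of three or more
  distinct psychotropic substances (level-5 ATC).
* **PICP** (potentially inappropriate combinations) — two or more
  psychotropics from the same pharmacological subgroup (level-3 ATC), plus
  a drug-property rule for two or more anticholinergic psychotropics.
  A two-or-more-antiepileptics rule is tabulated for completeness but,
  by definition, excluded from the overall PICP flag.
* **PIPS** (potentially inappropriate substances) — any long-acting
  benzodiazepine or anticholinergic psychotropic.

Cohort tables use the same denominator conventions as audit reports:
category shares within a "k or more drugs" stratum are relative to the
stratum count; sub-rows of the combination/PICP/PIPS families are
relative to the family count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, Optional

import pandas as pd

from ._rounding import percent
from .cohort_io import Cohort, Patient, category_registrations, distinct_substances
from .formulary import DrugEntry, PsychotropicCategory

POLYPHARMACY_THRESHOLD = 3

# PICP rule identifiers.  The antiepileptic rule is reported but not part
# of the overall PICP definition.
RULE_2PLUS_ANTIDEPRESSANTS = "2+_antidepressants"
RULE_2PLUS_ANTIPSYCHOTICS = "2+_antipsychotics"
RULE_2PLUS_ANXIOLYTICS_HYPNOTICS = "2+_anxiolytics_hypnotics"
RULE_2PLUS_ANTIEPILEPTICS = "2+_antiepileptics"
RULE_2PLUS_ANTICHOLINERGIC = "2+_anticholinergic"

_CATEGORY_RULE = {
    PsychotropicCategory.ANTIDEPRESSANT: RULE_2PLUS_ANTIDEPRESSANTS,
    PsychotropicCategory.ANTIPSYCHOTIC: RULE_2PLUS_ANTIPSYCHOTICS,
    PsychotropicCategory.ANXIOLYTIC_HYPNOTIC: RULE_2PLUS_ANXIOLYTICS_HYPNOTICS,
    PsychotropicCategory.ANTIEPILEPTIC: RULE_2PLUS_ANTIEPILEPTICS,
}

PICP_RULES = tuple(_CATEGORY_RULE.values()) + (RULE_2PLUS_ANTICHOLINERGIC,)
PICP_DEFINING_RULES = frozenset(PICP_RULES) - {RULE_2PLUS_ANTIEPILEPTICS}

_CATEGORY_ORDER = (
    PsychotropicCategory.ANTIDEPRESSANT,
    PsychotropicCategory.ANTIPSYCHOTIC,
    PsychotropicCategory.ANXIOLYTIC_HYPNOTIC,
    PsychotropicCategory.ANTIEPILEPTIC,
)


def polypharmacy_flag(patient: Patient) -> bool:
    """True iff the patient uses three or more distinct psychotropics."""
    return len(distinct_substances(patient)) >= POLYPHARMACY_THRESHOLD


def picp_rules(patient: Patient) -> set[str]:
    """Identifiers of the combination rules the patient's chart triggers.

    Category rules count distinct level-5 substances within one level-3
    category; the anticholinergic rule counts anticholinergic substances
    across categories (it is a drug-property rule).
    """
    substances = distinct_substances(patient)
    hits: set[str] = set()
    per_category: Counter = Counter(d.category for d in substances)
    for category, rule in _CATEGORY_RULE.items():
        if per_category[category] >= 2:
            hits.add(rule)
    if sum(d.anticholinergic for d in substances) >= 2:
        hits.add(RULE_2PLUS_ANTICHOLINERGIC)
    return hits


def picp_flag(patient: Patient) -> bool:
    """Overall PICP: any defining rule hit (antiepileptic pair excluded)."""
    return bool(picp_rules(patient) & PICP_DEFINING_RULES)


def pips_hits(patient: Patient) -> list[DrugEntry]:
    """Distinct substances carrying an inappropriateness flag.

    Ordered by registry order, i.e. the order substances were added to the
    registry, so reports are stable across runs.
    """
    flagged = [d for d in distinct_substances(patient) if d.is_pips]
    return sorted(flagged, key=lambda d: d.atc.code)


def pips_flag_patient(patient: Patient) -> bool:
    return any(d.is_pips for d in distinct_substances(patient))


def category_pairs(patient: Patient) -> set[FrozenSet[PsychotropicCategory]]:
    """Unordered pairs of categories the patient is registered in."""
    cats = sorted(category_registrations(patient), key=lambda c: c.value)
    return {frozenset(pair) for pair in combinations(cats, 2)}


@dataclass
class IndicatorProfile:
    """Per-patient indicator summary."""

    patient_id: str
    n_substances: int
    polypharmacy: bool
    category_pairs: set[FrozenSet[PsychotropicCategory]]
    picp_rules_hit: set[str]
    picp: bool
    pips_substances: list[DrugEntry] = field(default_factory=list)
    pips: bool = False


def indicator_profile(patient: Patient) -> IndicatorProfile:
    substances = distinct_substances(patient)
    rules = picp_rules(patient)
    hits = pips_hits(patient)
    return IndicatorProfile(
        patient_id=patient.id,
        n_substances=len(substances),
        polypharmacy=len(substances) >= POLYPHARMACY_THRESHOLD,
        category_pairs=category_pairs(patient),
        picp_rules_hit=rules,
        picp=bool(rules & PICP_DEFINING_RULES),
        pips_substances=hits,
        pips=bool(hits),
    )


def _pct(count: int, denom: int) -> Optional[float]:
    return percent(count, denom) if denom else None


def cohort_indicator_table(cohort: Cohort) -> pd.DataFrame:
    """Prescribing table: category use at the >=1, >=2, >=3 thresholds.

    One row per stratum ("all patients" and the three thresholds) and per
    category within the stratum.  ``denominator`` is the cohort size for
    stratum rows and the stratum count for category rows; ``percent`` is
    half-up rounded to one decimal, or missing when the denominator is
    zero (flagged, never divided).
    """
    n = len(cohort)
    counts = {p.id: len(distinct_substances(p)) for p in cohort}
    cats = {p.id: category_registrations(p) for p in cohort}

    rows: list[dict] = []

    def add(stratum: str, label: str, count: int, denom: int) -> None:
        rows.append(
            {
                "stratum": stratum,
                "label": label,
                "count": count,
                "denominator": denom,
                "percent": _pct(count, denom),
            }
        )

    add("all_patients", "all_patients", n, n)
    for category in _CATEGORY_ORDER:
        add(
            "all_patients",
            category.value,
            sum(category in cats[p.id] for p in cohort),
            n,
        )
    for k in (1, 2, 3):
        stratum = f"ge{k}_drugs"
        members = [p for p in cohort if counts[p.id] >= k]
        add(stratum, stratum, len(members), n)
        for category in _CATEGORY_ORDER:
            add(
                stratum,
                category.value,
                sum(category in cats[p.id] for p in members),
                len(members),
            )
    return pd.DataFrame(rows, columns=["stratum", "label", "count", "denominator", "percent"])


def cohort_combination_table(cohort: Cohort) -> pd.DataFrame:
    """Combination / PICP / PIPS table.

    Family rows (combination of categories, PICP, PIPS) are relative to
    the cohort size; sub-rows (category pairs, individual rules, individual
    flagged substances) are relative to their family count — the
    convention that surfaces the most frequent inappropriate prescribing
    within each family.
    """
    n = len(cohort)
    profiles = [indicator_profile(p) for p in cohort]

    rows: list[dict] = []

    def add(family: str, label: str, count: int, denom: int) -> None:
        rows.append(
            {
                "family": family,
                "label": label,
                "count": count,
                "denominator": denom,
                "percent": _pct(count, denom),
            }
        )

    combo = [pr for pr in profiles if pr.category_pairs]
    add("combination", "combination_of_categories", len(combo), n)
    for a, b in combinations(_CATEGORY_ORDER, 2):
        pair = frozenset({a, b})
        add(
            "combination",
            f"{a.value}+{b.value}",
            sum(pair in pr.category_pairs for pr in combo),
            len(combo),
        )

    picp_members = [pr for pr in profiles if pr.picp]
    add("picp", "picp", len(picp_members), n)
    for rule in PICP_RULES:
        add(
            "picp",
            rule,
            sum(rule in pr.picp_rules_hit for pr in profiles),
            len(picp_members),
        )

    pips_members = [pr for pr in profiles if pr.pips]
    add("pips", "pips", len(pips_members), n)
    substance_counts: Counter = Counter()
    for pr in pips_members:
        for drug in pr.pips_substances:
            substance_counts[drug.name] += 1
    for name in sorted(substance_counts):
        add("pips", name, substance_counts[name], len(pips_members))

    return pd.DataFrame(rows, columns=["family", "label", "count", "denominator", "percent"])
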