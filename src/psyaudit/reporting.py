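"""Audit orchestration: build the full report bundle for 1 or 2 cohorts.

The bundle mirrors a prescribing-audit publication: a per-cohort drug
frequency table, the threshold indicator table, the combination/PICP/PIPS
table, the first-ranked interaction classification, the three-step
logistic report, and a metadata record (inputs, rule versions, tie
counts) sufficient to regenerate every table from cohort + knowledge
base + configuration alone.  When two cohorts are given, indicator-level
two-cohort comparisons are added.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from ._rounding import percent
from .cohort_io import Cohort, category_registrations, distinct_substances
from .comparative_stats import (
    ComparisonError,
    LogisticReport,
    compare_proportions,
    logistic_procedure,
    mann_whitney,
)
from .formulary import PsychotropicCategory
from .indicators import (
    cohort_combination_table,
    cohort_indicator_table,
    indicator_profile,
)
from .interaction_engine import KnowledgeBase, match_cohort, mechanism_summary

logger = logging.getLogger(__name__)

RULESET_VERSION = "1.0"


@dataclass
class ReportBundle:
    cohort_labels: list[str]
    drug_frequency: pd.DataFrame
    indicator_tables: dict[str, pd.DataFrame]
    combination_tables: dict[str, pd.DataFrame]
    interaction_tables: dict[str, pd.DataFrame]
    logistic_reports: dict[str, Optional[LogisticReport]]
    comparison: Optional[pd.DataFrame]
    metadata: dict = field(default_factory=dict)


def drug_frequency_table(cohorts: Sequence[Cohort]) -> pd.DataFrame:
    """Patients per substance and cohort (a drug-frequency table)."""
    rows = []
    for cohort in cohorts:
        n = len(cohort)
        tally: Counter = Counter()
        for patient in cohort:
            for drug in distinct_substances(patient):
                tally[drug.name] += 1
        for name in sorted(tally):
            rows.append(
                {
                    "cohort": cohort.label,
                    "drug": name,
                    "count": tally[name],
                    "denominator": n,
                    "percent": percent(tally[name], n) if n else None,
                }
            )
    return pd.DataFrame(rows, columns=["cohort", "drug", "count", "denominator", "percent"])


def _indicator_counts(cohort: Cohort, kb: KnowledgeBase) -> dict[str, int]:
    profiles = [indicator_profile(p) for p in cohort]
    matched = match_cohort(cohort, kb)
    counts = {
        "ge1_drugs": sum(pr.n_substances >= 1 for pr in profiles),
        "ge2_drugs": sum(pr.n_substances >= 2 for pr in profiles),
        "polypharmacy": sum(pr.polypharmacy for pr in profiles),
        "picp": sum(pr.picp for pr in profiles),
        "pips": sum(pr.pips for pr in profiles),
        "ge1_interaction": sum(m.n_interactions >= 1 for m in matched),
    }
    for category in PsychotropicCategory:
        counts[category.value] = sum(
            category in category_registrations(p) for p in cohort
        )
    return counts


def comparison_table(cohort_a: Cohort, cohort_b: Cohort, kb: KnowledgeBase) -> pd.DataFrame:
    """Two-cohort comparison of the headline indicators.

    Proportions by chi-square/Fisher; age and psychotropic count by the
    Mann-Whitney U test (reported with test name ``mann_whitney`` and no
    counts).
    """
    na, nb = len(cohort_a), len(cohort_b)
    counts_a = _indicator_counts(cohort_a, kb)
    counts_b = _indicator_counts(cohort_b, kb)
    rows = []
    for label in counts_a:
        comparison = compare_proportions(
            counts_a[label], na, counts_b[label], nb, label=label
        )
        rows.append(
            {
                "label": label,
                "count_a": comparison.count_a,
                "denom_a": comparison.denom_a,
                "percent_a": comparison.percent_a,
                "count_b": comparison.count_b,
                "denom_b": comparison.denom_b,
                "percent_b": comparison.percent_b,
                "test": comparison.test_used,
                "p_value": comparison.p_value,
                "significant": comparison.significant,
            }
        )
    for label, values in (
        ("age", (lambda c: [p.age for p in c])),
        ("n_psychotropics", (lambda c: [len(distinct_substances(p)) for p in c])),
    ):
        p = mann_whitney(values(cohort_a), values(cohort_b))
        rows.append(
            {
                "label": label,
                "count_a": None,
                "denom_a": na,
                "percent_a": None,
                "count_b": None,
                "denom_b": nb,
                "percent_b": None,
                "test": "mann_whitney",
                "p_value": p,
                "significant": p < 0.01,
            }
        )
    return pd.DataFrame(rows)


def run_audit(
    cohorts: Sequence[Cohort],
    kb: KnowledgeBase,
    out_dir: Optional[Union[str, Path]] = None,
    metadata: Optional[dict] = None,
) -> ReportBundle:
    """Produce the full report bundle for one or two cohorts.

    With ``out_dir`` set, every table is written as TSV together with a
    ``run_metadata.json`` record.  The logistic report is skipped (with a
    logged note) for a cohort whose analysis population is degenerate.
    """
    if not 1 <= len(cohorts) <= 2:
        raise ValueError("run_audit expects one or two cohorts")

    indicator_tables = {}
    combination_tables = {}
    interaction_tables = {}
    logistic_reports: dict[str, Optional[LogisticReport]] = {}
    tie_counts = {}
    for cohort in cohorts:
        indicator_tables[cohort.label] = cohort_indicator_table(cohort)
        combination_tables[cohort.label] = cohort_combination_table(cohort)
        interaction_tables[cohort.label] = mechanism_summary(cohort, kb)
        tie_counts[cohort.label] = sum(m.tie for m in match_cohort(cohort, kb))
        try:
            logistic_reports[cohort.label] = logistic_procedure(cohort, kb)
        except ComparisonError as exc:
            logger.warning("cohort %s: logistic step skipped (%s)", cohort.label, exc)
            logistic_reports[cohort.label] = None

    comparison = (
        comparison_table(cohorts[0], cohorts[1], kb) if len(cohorts) == 2 else None
    )

    meta = {
        "ruleset_version": RULESET_VERSION,
        "cohorts": [
            {
                "label": c.label,
                "n_patients": len(c),
                "excluded_under_65": c.excluded_count,
            }
            for c in cohorts
        ],
        "kb_entries": len(kb),
        "first_ranked_tie_counts": tie_counts,
        "notes": [
            "indicators applied to all patients aged >= 65",
            "same-substance regular+PRN entries deduplicated at ATC level 5",
            "step3 selection: min(step1 p, step2 p) < 0.25",
        ],
    }
    if metadata:
        meta.update(metadata)

    bundle = ReportBundle(
        cohort_labels=[c.label for c in cohorts],
        drug_frequency=drug_frequency_table(cohorts),
        indicator_tables=indicator_tables,
        combination_tables=combination_tables,
        interaction_tables=interaction_tables,
        logistic_reports=logistic_reports,
        comparison=comparison,
        metadata=meta,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_bundle(bundle: ReportBundle, out_dir: Union[str, Path]) -> None:
    """Write every table of the bundle as TSV plus run metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.drug_frequency, out / "drug_frequency.tsv")
    for label in bundle.cohort_labels:
        _write_tsv(bundle.indicator_tables[label], out / f"indicators_{label}.tsv")
        _write_tsv(bundle.combination_tables[label], out / f"combinations_{label}.tsv")
        _write_tsv(bundle.interaction_tables[label], out / f"interactions_{label}.tsv")
        report = bundle.logistic_reports[label]
        if report is not None:
            for step_name, frame in (
                ("step1", report.step1),
                ("step2", report.step2),
                ("step3", report.step3),
                ("multicollinearity", report.multicollinearity),
            ):
                _write_tsv(
                    frame.reset_index(), out / f"logistic_{step_name}_{label}.tsv"
                )
    if bundle.comparison is not None:
        _write_tsv(bundle.comparison, out / "comparison.tsv")
    (out / "run_metadata.json").write_text(
        json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
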