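"""Drug-interaction matching and first-ranked selection.

Patient substance pairs are screened against a curated interaction
knowledge base.  Each knowledge-base entry carries a mechanism
(pharmacodynamic or pharmacokinetic) and three clinical-relevance
attributes as recorded by interaction compendia: recommended action,
documentation and severity.  For ranking, the raw attribute vocabularies
are collapsed to three ordered levels each:

* action: informative < monitor-or-adjust-dose < avoid
  ("monitor" and "adjust dose" collapse to one level)
* documentation: theoretical < case < study
  ("study" and "extensive" collapse to one level)
* severity: mild < moderate < severe

A patient's *first-ranked* interaction — the single most clinically
important one — is the lexicographic maximum over
(action, documentation, severity).  Action dominates because a
contraindication matters regardless of how the evidence is graded;
severity ranks last because compendia label many interactions potentially
severe on thin evidence.
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from ._rounding import percent
from .cohort_io import Cohort, Patient, distinct_substances


class KnowledgeBaseError(ValueError):
    """Malformed interaction knowledge base."""


class Mechanism(enum.Enum):
    PHARMACODYNAMIC = "pharmacodynamic"
    PHARMACOKINETIC = "pharmacokinetic"


RAW_ACTIONS = ("informative", "monitor", "adjust dose", "avoid")
RAW_DOCUMENTATION = ("theoretical", "case", "study", "extensive")
SEVERITIES = ("mild", "moderate", "severe")


class Action(enum.IntEnum):
    """Collapsed recommended action, ordinal 1 < 2 < 3."""

    INFORMATIVE = 1
    MONITOR_OR_ADJUST = 2
    AVOID = 3


class Documentation(enum.IntEnum):
    """Collapsed documentation level, ordinal 1 < 2 < 3."""

    THEORETICAL = 1
    CASE = 2
    STUDY = 3


class Severity(enum.IntEnum):
    MILD = 1
    MODERATE = 2
    SEVERE = 3


_ACTION_COLLAPSE = {
    "informative": Action.INFORMATIVE,
    "monitor": Action.MONITOR_OR_ADJUST,
    "adjust dose": Action.MONITOR_OR_ADJUST,
    "avoid": Action.AVOID,
}
_DOC_COLLAPSE = {
    "theoretical": Documentation.THEORETICAL,
    "case": Documentation.CASE,
    "study": Documentation.STUDY,
    "extensive": Documentation.STUDY,
}
_SEVERITY = {
    "mild": Severity.MILD,
    "moderate": Severity.MODERATE,
    "severe": Severity.SEVERE,
}


@dataclass(frozen=True)
class CollapsedLevels:
    action: Action
    documentation: Documentation
    severity: Severity


@dataclass(frozen=True)
class InteractionEntry:
    """One knowledge-base record for an unordered substance pair."""

    pair: frozenset
    mechanism: Mechanism
    action_raw: str
    documentation_raw: str
    severity: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise KnowledgeBaseError(
                f"interaction pair must be two distinct substances, got {set(self.pair)}"
            )
        if self.action_raw not in _ACTION_COLLAPSE:
            raise KnowledgeBaseError(f"unknown action token {self.action_raw!r}")
        if self.documentation_raw not in _DOC_COLLAPSE:
            raise KnowledgeBaseError(
                f"unknown documentation token {self.documentation_raw!r}"
            )
        if self.severity not in _SEVERITY:
            raise KnowledgeBaseError(f"unknown severity token {self.severity!r}")

    @property
    def sorted_pair(self) -> tuple[str, str]:
        a, b = sorted(self.pair)
        return a, b


def collapse_levels(entry: InteractionEntry) -> CollapsedLevels:
    """Collapse the raw attribute tokens to the three ranking scales."""
    return CollapsedLevels(
        action=_ACTION_COLLAPSE[entry.action_raw],
        documentation=_DOC_COLLAPSE[entry.documentation_raw],
        severity=_SEVERITY[entry.severity],
    )


def rank_key(levels: CollapsedLevels) -> tuple[int, int, int]:
    """Lexicographic importance key: (action, documentation, severity).

    Larger compares as more important; action dominates documentation,
    documentation dominates severity.
    """
    return (int(levels.action), int(levels.documentation), int(levels.severity))


class KnowledgeBase:
    """Validated set of interaction entries, keyed by unordered pair."""

    def __init__(self, entries: Iterable[InteractionEntry] = ()) -> None:
        self._entries: dict[frozenset, InteractionEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: InteractionEntry) -> None:
        if entry.pair in self._entries:
            a, b = entry.sorted_pair
            raise KnowledgeBaseError(f"duplicate interaction pair ({a}, {b})")
        self._entries[entry.pair] = entry

    def get(self, name_a: str, name_b: str) -> Optional[InteractionEntry]:
        return self._entries.get(frozenset({name_a.lower(), name_b.lower()}))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())


KB_COLUMNS = (
    "drug_a",
    "drug_b",
    "mechanism",
    "action",
    "documentation",
    "severity",
    "description",
)


def load_kb(path: Union[str, Path]) -> KnowledgeBase:
    """Load a knowledge base from delimited text.

    Header ``drug_a,drug_b,mechanism,action,documentation,severity,
    description``; tokens case-insensitive; a pair listed in both orders
    is a conflict.
    """
    path = Path(path)
    kb = KnowledgeBase()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not set(KB_COLUMNS) <= set(reader.fieldnames):
            missing = set(KB_COLUMNS) - set(reader.fieldnames or ())
            raise KnowledgeBaseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            mech_token = row["mechanism"].strip().lower()
            try:
                mechanism = Mechanism(mech_token)
            except ValueError:
                raise KnowledgeBaseError(
                    f"{path}:{lineno}: unknown mechanism {row['mechanism']!r}"
                ) from None
            try:
                entry = InteractionEntry(
                    pair=frozenset(
                        {row["drug_a"].strip().lower(), row["drug_b"].strip().lower()}
                    ),
                    mechanism=mechanism,
                    action_raw=row["action"].strip().lower(),
                    documentation_raw=row["documentation"].strip().lower(),
                    severity=row["severity"].strip().lower(),
                    description=row["description"].strip(),
                )
                kb.add(entry)
            except KnowledgeBaseError as exc:
                raise KnowledgeBaseError(f"{path}:{lineno}: {exc}") from None
    return kb


@dataclass
class PatientInteractions:
    """All matched interactions for one patient plus the first-ranked one."""

    patient_id: str
    matches: list[tuple[InteractionEntry, CollapsedLevels]] = field(default_factory=list)
    first_ranked: Optional[tuple[InteractionEntry, CollapsedLevels]] = None
    tie: bool = False  # another match shared the winning collapsed triple

    @property
    def n_interactions(self) -> int:
        return len(self.matches)


def match_interactions(patient: Patient, kb: KnowledgeBase) -> PatientInteractions:
    """Screen all substance pairs of a patient against the knowledge base.

    The first-ranked interaction maximises the lexicographic
    (action, documentation, severity) key; ties on the full collapsed
    triple are broken by the alphabetically first sorted pair, and the
    tie is recorded.
    """
    names = sorted(d.name for d in distinct_substances(patient))
    matches: list[tuple[InteractionEntry, CollapsedLevels]] = []
    for a, b in combinations(names, 2):
        entry = kb.get(a, b)
        if entry is not None:
            matches.append((entry, collapse_levels(entry)))

    result = PatientInteractions(patient_id=patient.id, matches=matches)
    if matches:
        best_rank = max(rank_key(levels) for _, levels in matches)
        candidates = [m for m in matches if rank_key(m[1]) == best_rank]
        result.first_ranked = min(candidates, key=lambda m: m[0].sorted_pair)
        result.tie = len(candidates) > 1
    return result


def match_cohort(cohort: Cohort, kb: KnowledgeBase) -> list[PatientInteractions]:
    return [match_interactions(p, kb) for p in cohort]


def mechanism_summary(cohort: Cohort, kb: KnowledgeBase) -> pd.DataFrame:
    """Classify first-ranked interactions by mechanism, action,
    documentation and severity.

    For each stratum: the number of patients whose first-ranked
    interaction falls in it, its one-decimal percentage of patients with
    any interaction, and the two substances most frequently involved in
    the stratum's first-ranked interactions (count-desc, then name).
    """
    matched = [m for m in match_cohort(cohort, kb) if m.first_ranked is not None]
    denom = len(matched)

    rows: list[dict] = []

    def add(category: str, stratum: str, members: list[PatientInteractions]) -> None:
        tally: Counter = Counter()
        for m in members:
            entry, _ = m.first_ranked  # type: ignore[misc]
            for name in entry.sorted_pair:
                tally[name] += 1
        top = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
        top += [("", 0)] * (2 - len(top))
        rows.append(
            {
                "category": category,
                "stratum": stratum,
                "count": len(members),
                "denominator": denom,
                "percent": percent(len(members), denom) if denom else None,
                "first_substance": top[0][0],
                "first_substance_n": top[0][1],
                "second_substance": top[1][0],
                "second_substance_n": top[1][1],
            }
        )

    add("all", "patients_with_interactions", matched)
    for mech in Mechanism:
        add(
            "mechanism",
            mech.value,
            [m for m in matched if m.first_ranked[0].mechanism is mech],
        )
    for action in reversed(Action):
        add(
            "action",
            action.name.lower(),
            [m for m in matched if m.first_ranked[1].action is action],
        )
    for doc in reversed(Documentation):
        add(
            "documentation",
            doc.name.lower(),
            [m for m in matched if m.first_ranked[1].documentation is doc],
        )
    for sev in reversed(Severity):
        add(
            "severity",
            sev.name.lower(),
            [m for m in matched if m.first_ranked[1].severity is sev],
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "stratum",
            "count",
            "denominator",
            "percent",
            "first_substance",
            "first_substance_n",
            "second_substance",
            "second_substance_n",
        ],
    )
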