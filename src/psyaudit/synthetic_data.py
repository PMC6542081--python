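"""Synthetic nursing-home cohorts and an interaction knowledge-base fixture.

No patient-level data from the audited nursing homes were ever deposited,
so the package ships a generator that emulates the published cohort
structure: an age distribution truncated at 65 years, a configurable
per-patient distribution of the number of distinct psychotropics, and
per-drug marginal prevalences proportional to the published
drug-frequency table for the chosen audit year.  Drugs are sampled
independently given the per-patient count, so category co-occurrence is
emergent from the marginal weights rather than modelled directly — the
published tables report only marginals.

The knowledge-base fixture encodes the interaction pairs inferable from
the published first-ranked-interaction table (mechanism, recommended
action, documentation, severity); an *extended* variant adds a set of
synthetic sedation pairs among frequently co-prescribed anxiolytics-
hypnotics so that synthetic cohorts show realistic interaction
prevalence.  Neither is a substitute for a curated interaction database.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .cohort_io import Cohort, Patient, Prescription
from .formulary import DrugRegistry, default_registry
from .interaction_engine import KB_COLUMNS, KnowledgeBase, load_kb

MIN_AGE = 65


class ConfigError(ValueError):
    """Invalid cohort configuration."""


# Per-drug patient counts from the published drug-frequency table,
# used as default relative prevalence weights.
DRUG_COUNTS_2000 = {
    "clomipramine": 1, "doxepin": 2, "nortriptyline": 6, "paroxetine": 16,
    "amitriptyline": 8, "citalopram": 51, "mianserin": 15, "sertraline": 8,
    "chlorpromazine": 7, "flupentixol": 3, "fluphenazine": 1, "melperone": 5,
    "perphenazine": 3, "sertindole": 1, "chlorprothixene": 2, "haloperidol": 14,
    "levomepromazine": 18, "lithium": 2, "olanzapine": 7, "risperidone": 33,
    "prochlorperazine": 2, "zuclopenthixol": 4, "buspirone": 1,
    "flunitrazepam": 5, "diazepam": 14, "oxazepam": 40, "hydroxyzine": 3,
    "nitrazepam": 11, "zolpidem": 2, "zopiclone": 34, "phenobarbital": 3,
    "phenytoin": 4, "gabapentin": 1, "carbamazepine": 23, "clonazepam": 2,
    "valproic acid": 2,
}

DRUG_COUNTS_2016 = {
    "amitriptyline": 2, "citalopram": 25, "mianserin": 10, "sertraline": 15,
    "bupropion": 4, "escitalopram": 57, "mirtazapine": 89, "moclobemide": 1,
    "venlafaxine": 11, "chlorprothixene": 3, "haloperidol": 27,
    "levomepromazine": 4, "lithium": 1, "olanzapine": 13, "risperidone": 8,
    "prochlorperazine": 1, "zuclopenthixol": 2, "clozapine": 4,
    "quetiapine": 72, "diazepam": 33, "oxazepam": 164, "hydroxyzine": 3,
    "nitrazepam": 2, "zolpidem": 5, "zopiclone": 113, "clomethiazole": 20,
    "melatonin": 6, "midazolam": 19, "gabapentin": 8, "carbamazepine": 6,
    "clonazepam": 1, "valproic acid": 9, "lamotrigine": 4, "levetiracetam": 17,
    "pregabalin": 5,
}

# Per-patient distinct-psychotropic-count distributions calibrated once to
# the published >=1 / >=2 / >=3 prevalences and concurrent-use ranges
# (2000: up to four concurrent psychotropics; 2016: up to six).
COUNT_PMF_2000 = {0: 0.404, 1: 0.352, 2: 0.182, 3: 0.052, 4: 0.010}
COUNT_PMF_2016 = {0: 0.195, 1: 0.245, 2: 0.264, 3: 0.180, 4: 0.080, 5: 0.026, 6: 0.010}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``count_pmf`` is the distribution of the number of distinct
    psychotropics per patient (support 0..6); ``drug_weights`` the
    relative prevalence of each substance; ``prn_fraction`` the
    probability that a prescription is marked as-needed.
    """

    label: str = "synthetic"
    n_patients: int = 400
    male_fraction: float = 0.30
    age_mean: float = 84.5
    age_sd: float = 7.5
    count_pmf: dict[int, float] = field(default_factory=lambda: dict(COUNT_PMF_2016))
    drug_weights: dict[str, float] = field(default_factory=lambda: dict(DRUG_COUNTS_2016))
    prn_fraction: float = 0.3
    seed: int = 0

    @classmethod
    def year_2000(cls, seed: int = 0, n_patients: int = 386) -> "CohortConfig":
        """Defaults emulating the earlier audit timepoint."""
        return cls(
            label="2000",
            n_patients=n_patients,
            male_fraction=0.264,
            age_mean=84.6,
            age_sd=7.2,
            count_pmf=dict(COUNT_PMF_2000),
            drug_weights=dict(DRUG_COUNTS_2000),
            seed=seed,
        )

    @classmethod
    def year_2016(cls, seed: int = 0, n_patients: int = 416) -> "CohortConfig":
        """Defaults emulating the later audit timepoint."""
        return cls(
            label="2016",
            n_patients=n_patients,
            male_fraction=0.339,
            age_mean=84.3,
            age_sd=8.1,
            count_pmf=dict(COUNT_PMF_2016),
            drug_weights=dict(DRUG_COUNTS_2016),
            seed=seed,
        )

    def validate(self, registry: DrugRegistry) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError("male_fraction must be a probability")
        if not 0.0 <= self.prn_fraction <= 1.0:
            raise ConfigError("prn_fraction must be a probability")
        if not self.count_pmf:
            raise ConfigError("count_pmf must be non-empty")
        if any(k < 0 for k in self.count_pmf):
            raise ConfigError("count_pmf support must be non-negative")
        if abs(sum(self.count_pmf.values()) - 1.0) > 1e-9:
            raise ConfigError("count_pmf must sum to 1")
        positive_weights = {n for n, w in self.drug_weights.items() if w > 0}
        if any(w < 0 for w in self.drug_weights.values()) or not positive_weights:
            raise ConfigError("drug_weights must be non-negative with one positive")
        if max(self.count_pmf) > len(positive_weights):
            raise ConfigError(
                f"count_pmf support (max {max(self.count_pmf)}) exceeds the "
                f"{len(positive_weights)} drugs with positive weight"
            )
        for name in self.drug_weights:
            if name not in registry:
                raise ConfigError(f"drug_weights names unknown drug {name!r}")

    def to_json(self, path: Union[str, Path]) -> None:
        data = {
            "label": self.label,
            "n_patients": self.n_patients,
            "male_fraction": self.male_fraction,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "count_pmf": {str(k): v for k, v in self.count_pmf.items()},
            "drug_weights": self.drug_weights,
            "prn_fraction": self.prn_fraction,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CohortConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        data["count_pmf"] = {int(k): float(v) for k, v in data["count_pmf"].items()}
        return cls(**data)


def _truncated_age(rng: np.random.Generator, mean: float, sd: float) -> int:
    # rejection-sample above 64.5 then round, so integer ages are >= 65
    while True:
        age = rng.normal(mean, sd)
        if age > MIN_AGE - 0.5:
            return int(round(age))


def generate_cohort(
    config: CohortConfig, registry: Optional[DrugRegistry] = None
) -> Cohort:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    Ages come from the truncated normal; each patient receives a
    psychotropic count from ``count_pmf`` and that many distinct drugs
    sampled without replacement with probability proportional to
    ``drug_weights``; each prescription is independently marked as-needed
    with probability ``prn_fraction``.
    """
    if registry is None:
        registry = default_registry()
    config.validate(registry)
    rng = np.random.default_rng(config.seed)

    counts = sorted(config.count_pmf)
    count_p = np.array([config.count_pmf[k] for k in counts], dtype=float)
    count_p /= count_p.sum()

    names = sorted(n for n, w in config.drug_weights.items() if w > 0)
    weights = np.array([config.drug_weights[n] for n in names], dtype=float)
    weights /= weights.sum()

    patients = []
    for i in range(config.n_patients):
        gender = "M" if rng.random() < config.male_fraction else "F"
        age = _truncated_age(rng, config.age_mean, config.age_sd)
        k = int(rng.choice(counts, p=count_p))
        chosen = rng.choice(len(names), size=k, replace=False, p=weights) if k else []
        prescriptions = [
            Prescription(
                drug=registry.lookup(names[j]),
                as_needed=bool(rng.random() < config.prn_fraction),
            )
            for j in sorted(chosen)
        ]
        patients.append(
            Patient(
                id=f"{config.label}-{i:04d}",
                age=age,
                gender=gender,
                prescriptions=prescriptions,
            )
        )
    return Cohort(label=config.label, patients=patients, excluded_count=0)


# Interaction pairs inferable from the published first-ranked-interaction
# table: (drug_a, drug_b, mechanism, action, documentation, severity,
# description).
_KB_FIXTURE_ROWS = [
    ("haloperidol", "citalopram", "pharmacodynamic", "avoid", "theoretical", "severe", "QT-prolongation"),
    ("levomepromazine", "haloperidol", "pharmacodynamic", "avoid", "theoretical", "severe", "QT-prolongation"),
    ("citalopram", "risperidone", "pharmacodynamic", "informative", "case", "severe", "priapism/QT-prolongation"),
    ("citalopram", "levomepromazine", "pharmacodynamic", "informative", "theoretical", "severe", "QT-prolongation"),
    ("mirtazapine", "escitalopram", "pharmacodynamic", "informative", "theoretical", "severe", "serotonin syndrome"),
    ("mirtazapine", "oxazepam", "pharmacodynamic", "monitor", "theoretical", "moderate", "sedation"),
    ("escitalopram", "oxazepam", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation"),
    ("citalopram", "zopiclone", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation"),
    ("mirtazapine", "olanzapine", "pharmacodynamic", "informative", "case", "moderate", "sedation"),
    ("mirtazapine", "diazepam", "pharmacodynamic", "monitor", "study", "moderate", "CNS depression"),
    ("zopiclone", "carbamazepine", "pharmacodynamic", "informative", "theoretical", "mild", "sedation"),
    ("carbamazepine", "olanzapine", "pharmacokinetic", "monitor", "study", "moderate", "olanzapine plasma level reduced"),
    ("carbamazepine", "risperidone", "pharmacokinetic", "monitor", "study", "moderate", "risperidone plasma level reduced"),
    ("carbamazepine", "nortriptyline", "pharmacokinetic", "adjust dose", "study", "moderate", "nortriptyline plasma level reduced"),
    ("valproic acid", "carbamazepine", "pharmacokinetic", "monitor", "study", "moderate", "carbamazepine-epoxide increased"),
]

# Synthetic sedation pairs among frequently co-prescribed CNS depressants,
# used only by the extended fixture to give synthetic cohorts realistic
# interaction prevalence.  Not drawn from any published table.
_KB_EXTENDED_ROWS = [
    ("oxazepam", "zopiclone", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
    ("diazepam", "zopiclone", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
    ("diazepam", "oxazepam", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
    ("mirtazapine", "zopiclone", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
    ("quetiapine", "oxazepam", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
    ("quetiapine", "zopiclone", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
    ("escitalopram", "zopiclone", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
    ("citalopram", "oxazepam", "pharmacodynamic", "informative", "theoretical", "moderate", "sedation (synthetic)"),
]


def generate_kb_fixture(
    path: Optional[Union[str, Path]] = None, extended: bool = False
) -> KnowledgeBase:
    """Write (optionally) and return the interaction knowledge-base fixture.

    With ``extended=True`` the synthetic sedation pairs are appended.
    The returned object is the loaded, validated knowledge base; when
    *path* is given, the same content is also written as CSV.
    """
    rows = list(_KB_FIXTURE_ROWS) + (list(_KB_EXTENDED_ROWS) if extended else [])
    if path is not None:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(KB_COLUMNS)
            writer.writerows(rows)
        return load_kb(path)
    kb = KnowledgeBase()
    from .interaction_engine import InteractionEntry, Mechanism

    for a, b, mech, action, doc, sev, desc in rows:
        kb.add(
            InteractionEntry(
                pair=frozenset({a, b}),
                mechanism=Mechanism(mech),
                action_raw=action,
                documentation_raw=doc,
                severity=sev,
                description=desc,
            )
        )
    return kb
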