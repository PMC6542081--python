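"""ATC code handling, psychotropic categories, and the audit drug registry.

The audit classifies drugs with the WHO Anatomical Therapeutic Chemical
(ATC) system.  Five pharmacological subgroups are in scope: antipsychotics
(N05A), anxiolytics (N05B), hypnotics (N05C), antidepressants (N06A) and
antiepileptics (N03A); anxiolytics and hypnotics are collapsed into a
single anxiolytic-hypnotic category because their adverse-effect profiles
in frail elderly patients are comparable.

The registry additionally carries the two substance-level inappropriate-
prescribing flags (PIPS): long-acting benzodiazepines and psychotropics
with clinically relevant anticholinergic effects.
"""

from __future__ import annotations

import csv
import difflib
import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union


class FormularyError(ValueError):
    """Base error for registry and ATC problems."""


class AtcValidationError(FormularyError):
    """Raised for a syntactically invalid ATC code."""


class UnknownDrugError(FormularyError, KeyError):
    """Raised when a drug name cannot be resolved in the registry."""


# An ATC code is a prefix of the full 7-character pattern
# letter, two digits, letter, letter, two digits; valid truncation
# lengths are 1, 3, 4, 5 and 7 (the five ATC levels).
_ATC_FULL = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_ATC_LEVEL_LEN = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
_ATC_PREFIX = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    7: _ATC_FULL,
}


@dataclass(frozen=True, order=True)
class AtcCode:
    """A validated ATC code at any hierarchy level, stored uppercase."""

    code: str

    def __post_init__(self) -> None:
        code = self.code.strip().upper()
        pattern = _ATC_PREFIX.get(len(code))
        if pattern is None or not pattern.match(code):
            raise AtcValidationError(f"malformed ATC code: {self.code!r}")
        object.__setattr__(self, "code", code)

    @property
    def level(self) -> int:
        """ATC level (1-5) implied by the code length."""
        for level, length in _ATC_LEVEL_LEN.items():
            if length == len(self.code):
                return level
        raise AssertionError("unreachable: validated length")

    def truncate(self, level: int) -> "AtcCode":
        """Prefix of this code at the requested level (must not extend)."""
        length = _ATC_LEVEL_LEN[level]
        if length > len(self.code):
            raise AtcValidationError(
                f"cannot truncate {self.code} (level {self.level}) to level {level}"
            )
        return AtcCode(self.code[:length])

    def __str__(self) -> str:
        return self.code


class PsychotropicCategory(enum.Enum):
    """The four audit categories; anxiolytics and hypnotics are one."""

    ANTIDEPRESSANT = "antidepressant"
    ANTIPSYCHOTIC = "antipsychotic"
    ANXIOLYTIC_HYPNOTIC = "anxiolytic_hypnotic"
    ANTIEPILEPTIC = "antiepileptic"


class PipsFlag(enum.Enum):
    """Substance-level inappropriateness flag."""

    LONG_ACTING_BENZODIAZEPINE = "long_acting_benzodiazepine"
    ANTICHOLINERGIC = "anticholinergic"
    NONE = "none"


# category <- level-3 subgroup prefix.  Lithium (N05AN) falls under N05A
# and is therefore categorised with the antipsychotics.
_CATEGORY_PREFIXES = {
    "N06A": PsychotropicCategory.ANTIDEPRESSANT,
    "N05A": PsychotropicCategory.ANTIPSYCHOTIC,
    "N05B": PsychotropicCategory.ANXIOLYTIC_HYPNOTIC,
    "N05C": PsychotropicCategory.ANXIOLYTIC_HYPNOTIC,
    "N03A": PsychotropicCategory.ANTIEPILEPTIC,
}


def category_of(atc: Union[AtcCode, str]) -> Optional[PsychotropicCategory]:
    """Map an ATC code to its psychotropic category, or None.

    The code may be at level 3 or deeper; classification only inspects the
    4-character pharmacological-subgroup prefix, so a level-5 substance
    code and its level-3 truncation always agree.
    """
    if not isinstance(atc, AtcCode):
        atc = AtcCode(atc)
    if len(atc.code) < 4:
        return None
    return _CATEGORY_PREFIXES.get(atc.code[:4])


@dataclass(frozen=True)
class DrugEntry:
    """A registry row: canonical substance name, level-5 ATC code, flags."""

    name: str
    atc: AtcCode
    long_acting_benzodiazepine: bool = False
    anticholinergic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.strip().lower())
        if not self.name:
            raise FormularyError("drug name must be non-empty")
        if self.atc.level != 5:
            raise FormularyError(
                f"registry entry {self.name!r} needs a level-5 ATC code, got {self.atc}"
            )

    @property
    def category(self) -> Optional[PsychotropicCategory]:
        return category_of(self.atc)

    @property
    def pips_flag(self) -> PipsFlag:
        if self.long_acting_benzodiazepine:
            return PipsFlag.LONG_ACTING_BENZODIAZEPINE
        if self.anticholinergic:
            return PipsFlag.ANTICHOLINERGIC
        return PipsFlag.NONE

    @property
    def is_pips(self) -> bool:
        return self.pips_flag is not PipsFlag.NONE


class DrugRegistry:
    """Case-insensitive name-keyed registry of psychotropic substances.

    Entries keep insertion order, which defines the "registry order" used
    when listing a patient's inappropriate substances.
    """

    def __init__(self, entries: Iterable[DrugEntry] = ()) -> None:
        self._entries: dict[str, DrugEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: DrugEntry) -> None:
        if entry.name in self._entries:
            raise FormularyError(f"duplicate registry entry for {entry.name!r}")
        if entry.category is None:
            raise FormularyError(
                f"registry accepts only psychotropics; {entry.name!r} has ATC {entry.atc}"
            )
        self._entries[entry.name] = entry

    def lookup(self, name: str) -> DrugEntry:
        key = name.strip().lower()
        try:
            return self._entries[key]
        except KeyError:
            near = difflib.get_close_matches(key, self._entries, n=3)
            hint = f"; nearest names: {', '.join(near)}" if near else ""
            raise UnknownDrugError(f"unknown drug name {name!r}{hint}") from None

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._entries

    def __iter__(self) -> Iterator[DrugEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def order_index(self, entry: DrugEntry) -> int:
        return list(self._entries).index(entry.name)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DrugRegistry":
        """Load a registry from ``name,atc,long_acting_benzo,anticholinergic``."""
        registry = cls()
        with open(path, newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            required = {"name", "atc", "long_acting_benzo", "anticholinergic"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                missing = required - set(reader.fieldnames or ())
                raise FormularyError(
                    f"registry file {path}: missing columns {sorted(missing)}"
                )
            for row in reader:
                registry.add(
                    DrugEntry(
                        name=row["name"],
                        atc=AtcCode(row["atc"]),
                        long_acting_benzodiazepine=_parse_bool(
                            row["long_acting_benzo"], path, "long_acting_benzo"
                        ),
                        anticholinergic=_parse_bool(
                            row["anticholinergic"], path, "anticholinergic"
                        ),
                    )
                )
        return registry

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(["name", "atc", "long_acting_benzo", "anticholinergic"])
            for e in self:
                writer.writerow(
                    [
                        e.name,
                        e.atc.code,
                        int(e.long_acting_benzodiazepine),
                        int(e.anticholinergic),
                    ]
                )


def _parse_bool(token: str, path: object, column: str) -> bool:
    token = token.strip()
    if token not in {"0", "1"}:
        raise FormularyError(f"registry file {path}: {column} must be 0/1, got {token!r}")
    return token == "1"


def pips_flag(entry: DrugEntry) -> PipsFlag:
    """The inappropriateness flag recorded for a resolved registry entry."""
    return entry.pips_flag


def default_registry() -> DrugRegistry:
    """The registry shipped with the package.

    Covers every psychotropic substance prescribed in the audited cohorts,
    mapped to its WHO level-5 ATC code, with the long-acting-benzodiazepine
    and anticholinergic flags of the substance-level rule lists.  Editable:
    export with :meth:`DrugRegistry.to_csv`, amend, reload with
    :meth:`DrugRegistry.from_csv`.
    """
    source = resources.files("psyaudit.data").joinpath("default_registry.csv")
    with resources.as_file(source) as path:
        return DrugRegistry.from_csv(path)
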