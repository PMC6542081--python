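"""Knowledge-base loading, level collapsing and first-ranked selection.

First-ranked selection is validated against a brute-force sort over all
matched pairs under the full lexicographic comparator on many random
patients.
"""

import random
from itertools import combinations

import pytest

from psyaudit.interaction_engine import (
    Action,
    Documentation,
    InteractionEntry,
    KnowledgeBaseError,
    Mechanism,
    Severity,
    collapse_levels,
    load_kb,
    match_interactions,
    mechanism_summary,
    rank_key,
)
from psyaudit.cohort_io import Cohort, distinct_substances
from psyaudit._rounding import percent

KB_HEADER = "drug_a,drug_b,mechanism,action,documentation,severity,description\n"


def write_kb(tmp_path, rows):
    path = tmp_path / "kb.csv"
    path.write_text(KB_HEADER + "".join(r + "\n" for r in rows), encoding="utf-8")
    return path


def entry(a, b, action="informative", doc="theoretical", sev="mild",
          mech=Mechanism.PHARMACODYNAMIC):
    return InteractionEntry(
        pair=frozenset({a, b}),
        mechanism=mech,
        action_raw=action,
        documentation_raw=doc,
        severity=sev,
    )


def test_fixture_kb_loads_with_expected_content(kb):
    assert len(kb) >= 10
    hc = kb.get("haloperidol", "citalopram")
    assert hc is not None
    assert collapse_levels(hc).action is Action.AVOID
    vc = kb.get("valproic acid", "carbamazepine")
    assert vc.mechanism is Mechanism.PHARMACOKINETIC
    assert collapse_levels(vc).documentation is Documentation.STUDY


def test_unknown_level_token_names_row(tmp_path):
    path = write_kb(tmp_path, ["a,b,pharmacodynamic,sometimes,case,mild,x"])
    with pytest.raises(KnowledgeBaseError, match=":2"):
        load_kb(path)


def test_duplicate_unordered_pair_conflicts(tmp_path):
    path = write_kb(
        tmp_path,
        [
            "a,b,pharmacodynamic,avoid,case,mild,x",
            "B,A,pharmacokinetic,monitor,study,severe,y",
        ],
    )
    with pytest.raises(KnowledgeBaseError, match="duplicate"):
        load_kb(path)


def test_self_pair_rejected():
    with pytest.raises(KnowledgeBaseError):
        entry("a", "a")


@pytest.mark.parametrize(
    "raw,collapsed",
    [
        ("monitor", Action.MONITOR_OR_ADJUST),
        ("adjust dose", Action.MONITOR_OR_ADJUST),
        ("informative", Action.INFORMATIVE),
        ("avoid", Action.AVOID),
    ],
)
def test_action_collapse(raw, collapsed):
    assert collapse_levels(entry("a", "b", action=raw)).action is collapsed


@pytest.mark.parametrize(
    "raw,collapsed",
    [
        ("study", Documentation.STUDY),
        ("extensive", Documentation.STUDY),
        ("case", Documentation.CASE),
        ("theoretical", Documentation.THEORETICAL),
    ],
)
def test_documentation_collapse(raw, collapsed):
    assert collapse_levels(entry("a", "b", doc=raw)).documentation is collapsed


def test_collapse_identity_on_uncollapsed_tokens():
    lv = collapse_levels(entry("a", "b", action="avoid", doc="theoretical", sev="mild"))
    assert (lv.action, lv.documentation, lv.severity) == (
        Action.AVOID,
        Documentation.THEORETICAL,
        Severity.MILD,
    )


def test_collapse_order_preserving():
    """Collapsing is surjective and monotone w.r.t. the raw orderings."""
    raw_actions = ["informative", "monitor", "adjust dose", "avoid"]
    collapsed = [collapse_levels(entry("a", "b", action=r)).action for r in raw_actions]
    assert collapsed == sorted(collapsed)
    assert set(collapsed) == set(Action)
    raw_docs = ["theoretical", "case", "study", "extensive"]
    collapsed_docs = [collapse_levels(entry("a", "b", doc=r)).documentation for r in raw_docs]
    assert collapsed_docs == sorted(collapsed_docs)
    assert set(collapsed_docs) == set(Documentation)


def test_rank_action_dominates_documentation_and_severity():
    high_action = collapse_levels(entry("a", "b", action="avoid", doc="theoretical", sev="mild"))
    low_action = collapse_levels(entry("a", "b", action="monitor", doc="study", sev="severe"))
    assert rank_key(high_action) > rank_key(low_action)


def test_rank_documentation_dominates_severity():
    better_doc = collapse_levels(entry("a", "b", action="monitor", doc="study", sev="mild"))
    worse_doc = collapse_levels(entry("a", "b", action="monitor", doc="case", sev="severe"))
    assert rank_key(better_doc) > rank_key(worse_doc)
    assert rank_key(better_doc) == rank_key(better_doc)


def test_match_interactions_worked_example(make_patient, kb):
    patient = make_patient(["haloperidol", "citalopram", "mirtazapine", "oxazepam"])
    result = match_interactions(patient, kb)
    pairs = {m[0].sorted_pair for m in result.matches}
    assert ("citalopram", "haloperidol") in pairs
    assert ("mirtazapine", "oxazepam") in pairs
    assert result.first_ranked[0].sorted_pair == ("citalopram", "haloperidol")
    assert result.first_ranked[1].action is Action.AVOID


def test_single_drug_no_matches(make_patient, kb):
    result = match_interactions(make_patient(["citalopram"]), kb)
    assert result.matches == [] and result.first_ranked is None


def test_match_count_bounded_by_pairs(make_patient, kb_extended, registry):
    rng = random.Random(7)
    names = [e.name for e in registry]
    for _ in range(50):
        patient = make_patient(rng.sample(names, rng.randint(0, 6)))
        result = match_interactions(patient, kb_extended)
        n = len(distinct_substances(patient))
        assert len(result.matches) <= n * (n - 1) // 2


def test_match_set_equals_exhaustive_pair_scan(make_patient, kb_extended, registry):
    rng = random.Random(11)
    names = [e.name for e in registry]
    for _ in range(100):
        sample = rng.sample(names, 5)
        patient = make_patient(sample)
        result = match_interactions(patient, kb_extended)
        oracle = {
            frozenset({a, b})
            for a, b in combinations(sample, 2)
            if kb_extended.get(a, b) is not None
        }
        assert {m[0].pair for m in result.matches} == oracle


def test_first_ranked_equals_brute_force_max(make_patient, kb_extended, registry):
    """Lexicographic-maximum property on 1000 random patients."""
    rng = random.Random(20251)
    names = [e.name for e in registry]
    ties = 0
    for _ in range(1000):
        patient = make_patient(rng.sample(names, rng.randint(2, 7)))
        result = match_interactions(patient, kb_extended)
        if not result.matches:
            assert result.first_ranked is None
            continue
        ranked = sorted(
            result.matches, key=lambda m: (rank_key(m[1]), m[0].sorted_pair)
        )
        best_rank = rank_key(ranked[-1][1])
        assert rank_key(result.first_ranked[1]) == best_rank
        tied = [m for m in result.matches if rank_key(m[1]) == best_rank]
        assert result.first_ranked[0].sorted_pair == min(
            m[0].sorted_pair for m in tied
        )
        assert result.tie == (len(tied) > 1)
        ties += result.tie
    assert ties > 0  # the extended KB produces genuine ties


def test_mechanism_summary_all_pharmacodynamic(make_cohort, kb):
    cohort = make_cohort([["mirtazapine", "oxazepam"], ["citalopram", "zopiclone"]])
    table = mechanism_summary(cohort, kb).set_index(["category", "stratum"])
    assert table.loc[("mechanism", "pharmacodynamic"), "percent"] == 100.0
    assert table.loc[("mechanism", "pharmacokinetic"), "count"] == 0


def test_mechanism_summary_printed_share_convention():
    # 135 pharmacodynamic first-ranked interactions among 146 patients
    assert percent(135, 146) == 92.5


def test_mechanism_summary_substance_tally(make_cohort, kb):
    cohort = make_cohort(
        [["mirtazapine", "oxazepam"]] * 6
        + [["escitalopram", "oxazepam"]] * 3
        + [["valproic acid", "carbamazepine"]] * 1
    )
    table = mechanism_summary(cohort, kb).set_index(["category", "stratum"])
    row = table.loc[("all", "patients_with_interactions")]
    # hand count: oxazepam in 9 first-ranked pairs, mirtazapine in 6
    assert row["first_substance"] == "oxazepam" and row["first_substance_n"] == 9
    assert row["second_substance"] == "mirtazapine" and row["second_substance_n"] == 6
    assert row["count"] == 10
    moderate = table.loc[("severity", "moderate")]
    assert moderate["count"] == 10


def test_mechanism_summary_empty_cohort(kb):
    table = mechanism_summary(Cohort(label="empty"), kb)
    assert (table["count"] == 0).all()
    assert table["percent"].isna().all()
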