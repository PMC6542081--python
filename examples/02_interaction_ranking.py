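"""First-ranked interaction selection for one polymedicated resident.

Screens all substance pairs against the bundled knowledge-base fixture
and shows the lexicographic hierarchy at work: recommended action
dominates documentation, which dominates severity.
"""

from psyaudit import (
    Patient,
    Prescription,
    default_registry,
    generate_kb_fixture,
    match_interactions,
)

registry = default_registry()
kb = generate_kb_fixture()  # pairs inferable from the published table

resident = Patient(
    id="example-2",
    age=80,
    gender="M",
    prescriptions=[
        Prescription(drug=registry.lookup(name), as_needed=False)
        for name in ("haloperidol", "citalopram", "mirtazapine", "oxazepam")
    ],
)

result = match_interactions(resident, kb)
print(f"matched pairs ({len(result.matches)}):")
for entry, levels in result.matches:
    a, b = entry.sorted_pair
    print(
        f"  {a} + {b}: action={levels.action.name.lower()},"
        f" documentation={levels.documentation.name.lower()},"
        f" severity={levels.severity.name.lower()} ({entry.description})"
    )
entry, levels = result.first_ranked
print(f"first-ranked: {' + '.join(entry.sorted_pair)} -> {entry.description}")
print()
print(
    "citalopram + haloperidol wins because its recommended action is"
    " 'avoid'; action outranks the better-documented or more severe"
    " alternatives lower in the hierarchy."
)
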