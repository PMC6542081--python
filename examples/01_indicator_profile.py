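"""Per-patient prescribing-quality indicators on a tiny hand-built chart.

Builds one resident's medication list and prints the three indicator
families: polypharmacy (>= 3 distinct psychotropics), PICP (>= 2 from the
same category, or >= 2 anticholinergics) and PIPS (long-acting
benzodiazepines / anticholinergic psychotropics).
"""

from psyaudit import (
    Patient,
    Prescription,
    default_registry,
    indicator_profile,
)

registry = default_registry()

resident = Patient(
    id="example-1",
    age=87,
    gender="F",
    prescriptions=[
        Prescription(drug=registry.lookup("oxazepam"), as_needed=False),
        Prescription(drug=registry.lookup("oxazepam"), as_needed=True),  # PRN duplicate
        Prescription(drug=registry.lookup("zopiclone"), as_needed=False),
        Prescription(drug=registry.lookup("diazepam"), as_needed=True),
        Prescription(drug=registry.lookup("mirtazapine"), as_needed=False),
    ],
)

profile = indicator_profile(resident)
print(f"distinct psychotropics : {profile.n_substances}")
print(f"polypharmacy (>=3)     : {profile.polypharmacy}")
print(f"PICP rules hit         : {sorted(profile.picp_rules_hit)}")
print(f"PICP overall           : {profile.picp}")
print(f"PIPS substances        : {[d.name for d in profile.pips_substances]}")
print()
print(
    "The PRN oxazepam row collapses into the regular one (4 distinct"
    " substances), three anxiolytics-hypnotics trigger the same-category"
    " combination rule, and diazepam is flagged as a long-acting"
    " benzodiazepine."
)
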